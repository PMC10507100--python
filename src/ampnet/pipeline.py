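"""End-to-end orchestration: simulate -> diversity -> networks -> chemistry/RDA.

One declarative config drives every stage; each stochastic stage derives its
seed deterministically from the master seed, so a fixed config yields
byte-identical ledger tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_tables as iot
from .io_tables import (
    CROPS, FIELDS, FeatureTable, SampleMetadata, TaxonomyTable,
    aggregate_relative_abundance, drop_group_zero_svs, subset_by_group,
    write_chem_table, write_feature_table, write_metadata, write_taxonomy,
)
from .synthetic import generate_chemistry, generate_community
from .diversity import (
    bray_curtis_matrix, nmds_ordinate, permanova, rarefy_even_depth,
    shannon_index, tukey_kramer,
)
from .composition import clr_ensemble, phi_matrix, write_phi_long
from .network import (
    build_conetwork, build_node_ledger, compare_networks, node_taxon_summary,
    write_edge_list, write_graphml,
)
from .chem_analysis import (
    broadcast_chemistry, cluster_samples_complete_linkage,
    feature_parameter_association, percent_normalize_chem, rda_fit,
)

logger = logging.getLogger(__name__)

#: marker-specific defaults printed by the study: phi edge threshold,
#: core-nSV degree fraction, major-taxon abundance threshold
MARKER_DEFAULTS = {
    "18S": {"phi_threshold": 0.12, "core_fraction": 0.10, "abundance_threshold": 0.005},
    "16S": {"phi_threshold": 0.08, "core_fraction": 0.05, "abundance_threshold": 0.01},
}

_STAGES = ("simulate", "chemistry", "rarefy", "nmds", "permanova", "clr")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(master_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] >> 1)


@dataclass
class PipelineConfig:
    """Everything a run needs; no hidden defaults outside this object."""

    preset: str = "eukaryote"          # simulate preset; ignored when paths given
    seed: int = 0                      # master seed
    phi_threshold: float = 0.12
    core_fraction: float = 0.10
    abundance_threshold: float = 0.005
    M: int = 128                       # Monte-Carlo clr instances
    prior: float = 0.5                 # Dirichlet pseudo-count
    n_permutations: int = 999
    n_starts: int = 20                 # NMDS restarts
    # simulate parameters
    n_sv: int = 50
    n_modules: int = 5
    module_size: int = 5
    module_latent_sd: float = 1.0
    within_module_noise_sd: float = 0.05
    group_effect_sd: float = 0.75
    depth_range: tuple[int, int] = (20_000, 60_000)
    chem_noise_sd: float = 0.05
    # optional input paths (skip simulation when all four are set)
    feature_table: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    chemistry: str | None = None
    orientation: str = "svs-rows"

    REQUIRED = ("preset", "seed", "phi_threshold", "core_fraction", "abundance_threshold")

    @classmethod
    def default(cls, preset: str, seed: int = 0) -> "PipelineConfig":
        marker = {"eukaryote": "18S", "prokaryote": "16S"}[preset]
        d = MARKER_DEFAULTS[marker]
        return cls(preset=preset, seed=seed, **d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        missing = [k for k in cls.REQUIRED if k not in d]
        if missing:
            raise ValueError(f"config missing required key(s): {missing}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        cfg.depth_range = tuple(cfg.depth_range)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["depth_range"] = list(d["depth_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @property
    def marker(self) -> str:
        return {"eukaryote": "18S", "prokaryote": "16S"}[self.preset]


def _load_inputs(cfg: PipelineConfig):
    if cfg.feature_table is not None:
        ft = iot.read_feature_table(cfg.feature_table, cfg.marker, cfg.orientation)
        meta, tax = iot.read_metadata_taxonomy(cfg.metadata, cfg.taxonomy)
        iot.join_validate(ft, meta)
        chem = iot.read_chem_table(cfg.chemistry)
        return ft, tax, meta, chem, None
    ft, tax, meta, truth = generate_community(
        n_sv=cfg.n_sv, n_modules=cfg.n_modules, module_size=cfg.module_size,
        module_latent_sd=cfg.module_latent_sd,
        within_module_noise_sd=cfg.within_module_noise_sd,
        group_effect_sd=cfg.group_effect_sd, depth_range=cfg.depth_range,
        seed=stage_seed(cfg.seed, "simulate"), preset=cfg.preset,
    )
    chem = generate_chemistry(
        meta, noise_sd=cfg.chem_noise_sd, seed=stage_seed(cfg.seed, "chemistry")
    )
    return ft, tax, meta, chem, truth


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage into ``out_dir`` and return it.

    Any stage failure leaves an INCOMPLETE marker naming the stage, so
    partial output directories are never mistaken for finished runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    log_lines: list[str] = []

    def note(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    try:
        import networkx, scipy, skbio, sklearn  # noqa: PLC0415
        note(f"versions: numpy={np.__version__} scipy={scipy.__version__} "
             f"pandas={pd.__version__} networkx={networkx.__version__} "
             f"sklearn={sklearn.__version__} skbio={skbio.__version__}")
        note(f"master seed: {cfg.seed}; stage seeds: "
             + ", ".join(f"{s}={stage_seed(cfg.seed, s)}" for s in _STAGES))
        cfg.to_yaml(out / "config.yaml")

        stage = "inputs"
        ft, tax, meta, chem, truth = _load_inputs(cfg)
        write_feature_table(ft, out / "feature_table.tsv")
        write_taxonomy(tax, out / "taxonomy.tsv")
        write_metadata(meta, out / "metadata.tsv")
        write_chem_table(chem, out / "chemistry.tsv")
        if truth is not None:
            truth.to_json(out / "truth.json")
        note(f"inputs: {ft.n_samples} samples x {ft.n_svs} SVs ({ft.marker})")

        stage = "relative_abundance"
        for rank in ("phylum", "family", "genus"):
            rel = aggregate_relative_abundance(ft, tax, rank, cfg.abundance_threshold)
            rel.proportions.to_csv(
                out / f"relabund_{rank}.tsv", sep="\t", index_label="sample_id"
            )

        stage = "alpha_diversity"
        rare = rarefy_even_depth(ft, seed=stage_seed(cfg.seed, "rarefy"))
        sh = pd.DataFrame({
            "shannon": [shannon_index(rare.counts.loc[s]) for s in rare.sample_ids]
        }, index=pd.Index(rare.sample_ids, name="sample_id"))
        sh = sh.join(meta.table[["field", "crop", "stage"]])
        sh.to_csv(out / "shannon.tsv", sep="\t")
        by_group = {
            f"{f}:{c}": sh.loc[(sh.field == f) & (sh.crop == c), "shannon"].to_numpy()
            for f in FIELDS for c in CROPS
        }
        tukey_kramer(by_group).to_csv(out / "shannon_tukey.tsv", sep="\t", index=False)
        note(f"alpha diversity on {rare.n_samples} rarefied samples "
             f"(depth {int(rare.counts.sum(axis=1).iloc[0])})")

        stage = "beta_diversity"
        bc = bray_curtis_matrix(rare)
        pd.DataFrame(bc.data, index=bc.ids, columns=bc.ids).to_csv(
            out / "bray_curtis.tsv", sep="\t", index_label="sample_id"
        )
        nmds = nmds_ordinate(bc, n_starts=cfg.n_starts,
                             seed=stage_seed(cfg.seed, "nmds"))
        nmds.coordinates.to_csv(out / "nmds_coordinates.tsv", sep="\t",
                                index_label="sample_id")
        groups = {s: f"{meta.table.loc[s, 'field']}:{meta.table.loc[s, 'crop']}"
                  for s in bc.ids}
        perm = permanova(bc, groups, n_permutations=cfg.n_permutations,
                         seed=stage_seed(cfg.seed, "permanova"))
        (out / "permanova.json").write_text(json.dumps({
            "pseudo_F": perm.pseudo_F, "R2": perm.R2, "p_value": perm.p_value,
            "n_permutations": perm.n_permutations, "method": perm.method,
            "seed": perm.seed,
        }, indent=1, sort_keys=True))
        note(f"PERMANOVA: R2={perm.R2:.3f} p={perm.p_value:.4g} "
             f"({perm.method}); NMDS stress={nmds.stress:.4f}")

        stage = "chemistry"
        pct = percent_normalize_chem(chem)
        pct.to_csv(out / "chem_percent.tsv", sep="\t", index=False)
        z = cluster_samples_complete_linkage(pct)
        pd.DataFrame(z, columns=["cluster_a", "cluster_b", "height", "size"]).to_csv(
            out / "chem_dendrogram.tsv", sep="\t", index=False
        )

        stage = "networks"
        nets = {}
        for f in FIELDS:
            for c in CROPS:
                sub = subset_by_group(ft, meta, f, c)
                sub = drop_group_zero_svs(sub)
                clr = clr_ensemble(sub, M=cfg.M, prior=cfg.prior,
                                   seed=stage_seed(cfg.seed, "clr"))
                phi = phi_matrix(clr)
                tag = f"{f}_{c}"
                write_phi_long(phi, out / f"phi_{tag}.tsv")
                net = build_conetwork(phi, cfg.phi_threshold, (f, c))
                nets[(f, c)] = net
                write_graphml(net, out / f"network_{tag}.graphml")
                write_edge_list(net, out / f"network_{tag}_edges.tsv")
                note(f"network {tag}: {len(net.nodes)} nSVs, {net.n_edges} edges, "
                     f"{len(net.components)} clusters")
        comparison = compare_networks(nets, cfg.core_fraction)
        build_node_ledger(nets, comparison, tax).to_csv(
            out / "node_ledger.tsv", sep="\t", index=False
        )
        pies = {
            f"{f}_{c}": node_taxon_summary(nets[(f, c)], tax)
            for f in FIELDS for c in CROPS
        }
        (out / "network_summary.json").write_text(json.dumps({
            "n_common": len(comparison.common),
            "common": sorted(comparison.common),
            "crop_specific": {c: sorted(s) for c, s in comparison.crop_specific.items()},
            "field_specific": {f: sorted(s) for f, s in comparison.field_specific.items()},
            "core": {f"{g[0]}_{g[1]}": sorted(s) for g, s in comparison.core.items()},
            "phylum_fractions": pies,
        }, indent=1, sort_keys=True))
        note(f"classification: {len(comparison.common)} common nSVs; "
             + "; ".join(f"{c}-specific={len(s)}"
                         for c, s in comparison.crop_specific.items()))

        stage = "rda"
        full = drop_group_zero_svs(ft)
        clr_full = clr_ensemble(full, mode="point_estimate",
                                prior=cfg.prior).point_estimate()
        chem_per_sample = broadcast_chemistry(chem, meta)
        rda = rda_fit(clr_full, chem_per_sample)
        rda.site_scores.to_csv(out / "rda_site_scores.tsv", sep="\t",
                               index_label="sample_id")
        rda.feature_scores.to_csv(out / "rda_feature_scores.tsv", sep="\t",
                                  index_label="sv_id")
        rda.biplot_vectors.to_csv(out / "rda_biplot.tsv", sep="\t",
                                  index_label="parameter")
        assoc = feature_parameter_association(
            clr_full, chem_per_sample, top_k=5, abundance=full.counts.sum(axis=0)
        )
        assoc.to_csv(out / "feature_parameter_association.tsv", sep="\t", index=False)
        note(f"RDA: constrained fraction = {rda.constrained_fraction:.3f}")

        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    except Exception as exc:
        (out / "INCOMPLETE").write_text(f"failed at stage {stage!r}: {exc}\n")
        raise
    return out
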