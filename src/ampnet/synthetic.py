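"""Synthetic multi-domain soil community generator with planted modules.

Emulates the 36-sample design of a two-field, two-crop (maize/cabbage),
three-stage rotation survey: 2 fields x 2 crops x 3 stages x 3 replicates.
Per-sample basis abundances are log-normal; groups of SVs ("modules") share a
per-sample latent log-factor, so module members co-vary proportionally and are
recoverable by phi-proportionality networks. Observed counts are multinomial
draws at realistic sequencing depths. Ground truth (module membership, group
effects, seeds) is retained for recovery-based tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tables import (
    CHEM_PARAMS, CROPS, FIELDS, STAGES, NA_SENTINEL,
    FeatureTable, SampleMetadata, TaxonomyTable,
)

#: phylum pools used for taxonomy labelling, with sampling weights
PHYLUM_POOLS = {
    "eukaryote": (
        ("Ascomycota", 0.30), ("Basidiomycota", 0.15), ("Cercozoa", 0.20),
        ("Ciliophora", 0.10), ("Mucoromycota", 0.10), (NA_SENTINEL, 0.15),
    ),
    "prokaryote": (
        ("Pseudomonadota", 0.30), ("Acidobacteriota", 0.20),
        ("Actinomycetota", 0.20), ("Gemmatimonadota", 0.10),
        ("Planctomycetota", 0.10), (NA_SENTINEL, 0.10),
    ),
}

MARKER_OF_PRESET = {"eukaryote": "18S", "prokaryote": "16S"}

#: baseline values of the 12 soil parameters (field-realistic magnitudes;
#: CEC cmol(+)/kg, N and ions mg/100 g dry soil, EC mS/cm, Humus %, WC fraction)
CHEM_BASELINES = {
    "CEC": 20.0, "pH_H2O": 6.5, "pH_KCl": 5.8, "NO3_N": 10.0, "NH4_N": 5.0,
    "K2O": 40.0, "MgO": 60.0, "CaO": 300.0, "EC": 0.3, "Tr_P2O5": 50.0,
    "Humus": 4.0, "WC": 0.25,
}

#: default shift structure: fertiliser-driven N and EC in (early) maize soils,
#: green-manure humus in field_1, water and nutrient ions in field_2, higher pH
#: under cabbage
DEFAULT_CHEM_EFFECTS = {
    "NO3_N": {"maize": 8.0, "early": 4.0},
    "NH4_N": {"maize": 4.0, "early": 2.0},
    "EC": {"maize": 0.2},
    "Humus": {"field_1": 2.0},
    "WC": {"field_2": 0.10},
    "K2O": {"field_2": 15.0},
    "MgO": {"field_2": 20.0},
    "CaO": {"field_2": 80.0},
    "Tr_P2O5": {"field_2": 20.0},
    "CEC": {"field_2": 5.0},
    "pH_H2O": {"cabbage": 0.4},
    "pH_KCl": {"cabbage": 0.4},
}


@dataclass
class SyntheticTruth:
    """Ground truth of a generated community.

    ``module_assignments`` maps sv_id to a module id (or None for background
    SVs); ``group_effects`` maps sv_id to its per-group log-fold shift, with
    groups keyed ``"field:crop"``. ``basis_log`` holds the exact per-sample
    log basis abundances (not serialised) for noise-free oracle checks.
    """

    module_assignments: dict[str, int | None]
    module_latent_sd: float
    within_module_noise_sd: float
    group_effects: dict[str, dict[str, float]]
    depth_range: tuple[int, int]
    seed: int
    basis_log: pd.DataFrame | None = dc_field(default=None, repr=False, compare=False)

    def same_module_pairs(self) -> set[frozenset]:
        """All unordered SV pairs planted in the same module."""
        by_mod: dict[int, list[str]] = {}
        for sv, m in self.module_assignments.items():
            if m is not None:
                by_mod.setdefault(m, []).append(sv)
        pairs: set[frozenset] = set()
        for members in by_mod.values():
            pairs.update(frozenset(p) for p in combinations(sorted(members), 2))
        return pairs

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_assignments": self.module_assignments,
            "module_latent_sd": self.module_latent_sd,
            "within_module_noise_sd": self.within_module_noise_sd,
            "group_effects": self.group_effects,
            "depth_range": list(self.depth_range),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            module_assignments=d["module_assignments"],
            module_latent_sd=d["module_latent_sd"],
            within_module_noise_sd=d["within_module_noise_sd"],
            group_effects=d["group_effects"],
            depth_range=tuple(d["depth_range"]),
            seed=d["seed"],
        )


def _design_metadata() -> SampleMetadata:
    rows = []
    i = 0
    for field in FIELDS:
        for crop in CROPS:
            for stage in STAGES:
                for rep in (1, 2, 3):
                    i += 1
                    rows.append((f"s{i:02d}", field, crop, stage, rep))
    df = pd.DataFrame(rows, columns=["sample_id", "field", "crop", "stage", "replicate"])
    return SampleMetadata(df.set_index("sample_id"))


def _taxonomy(sv_ids: list[str], preset: str, rng: np.random.Generator) -> TaxonomyTable:
    pool = PHYLUM_POOLS[preset]
    phyla = [p for p, _ in pool]
    weights = np.array([w for _, w in pool])
    domain = "Eukaryota" if preset == "eukaryote" else "Bacteria"
    chosen = rng.choice(len(phyla), size=len(sv_ids), p=weights / weights.sum())
    rows = []
    for sv, k in zip(sv_ids, chosen):
        ph = phyla[k]
        if ph == NA_SENTINEL:
            rows.append((sv, domain, NA_SENTINEL, NA_SENTINEL, NA_SENTINEL,
                         NA_SENTINEL, NA_SENTINEL))
        else:
            sub = int(rng.integers(1, 4))
            rows.append((sv, domain, ph, f"{ph}_c{sub}", f"{ph}_o{sub}",
                         f"{ph}_f{sub}", f"{ph}_g{sub}"))
    df = pd.DataFrame(
        rows, columns=["sv_id", "domain", "phylum", "class", "order", "family", "genus"]
    ).set_index("sv_id")
    return TaxonomyTable(df)


def generate_community(
    n_sv: int = 50,
    n_modules: int = 5,
    module_size: int = 5,
    module_latent_sd: float = 1.0,
    within_module_noise_sd: float = 0.05,
    baseline_sd: float = 1.0,
    group_effect_sd: float = 0.75,
    depth_range: tuple[int, int] = (20_000, 60_000),
    seed: int = 0,
    preset: str = "eukaryote",
    overdispersion: float = 0.0,
) -> tuple[FeatureTable, TaxonomyTable, SampleMetadata, SyntheticTruth]:
    """Generate a 36-sample community with planted proportional modules.

    For SV i in sample s of group g the log basis abundance is

        log a(s,i) = b_i + delta(i,g) + lambda(s, m(i)) + eps(s,i)

    with per-SV baseline ``b_i ~ N(0, baseline_sd)``, per-group log-fold shift
    ``delta ~ N(0, group_effect_sd)``, a latent factor ``lambda ~ N(0,
    module_latent_sd)`` shared by all members of module m(i) within sample s,
    and idiosyncratic noise eps with sd ``within_module_noise_sd`` for module
    members and sd ``module_latent_sd`` for background SVs (so background SVs
    fluctuate at the same scale but independently). Observed counts are
    multinomial at a depth drawn uniformly from ``depth_range``; a positive
    ``overdispersion`` adds Dirichlet-multinomial extra-multinomial noise with
    concentration ``1/overdispersion``.
    """
    if n_modules * module_size > n_sv:
        raise ValueError(
            f"cannot pack {n_modules} modules of size {module_size} into {n_sv} SVs"
        )
    if preset not in PHYLUM_POOLS:
        raise ValueError(f"preset must be one of {sorted(PHYLUM_POOLS)}")
    lo, hi = depth_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid depth_range {depth_range}")

    rng = np.random.default_rng(seed)
    meta = _design_metadata()
    sv_ids = [f"SV_{i + 1}" for i in range(n_sv)]

    # module membership: a random subset of SVs, packed into disjoint modules
    member_idx = rng.permutation(n_sv)[: n_modules * module_size]
    assignment: dict[str, int | None] = {sv: None for sv in sv_ids}
    for m in range(n_modules):
        for j in member_idx[m * module_size:(m + 1) * module_size]:
            assignment[sv_ids[j]] = m

    baseline = rng.normal(0.0, baseline_sd, size=n_sv)
    groups = [f"{f}:{c}" for f in FIELDS for c in CROPS]
    delta = rng.normal(0.0, group_effect_sd, size=(len(groups), n_sv))
    group_effects = {
        sv: {g: float(delta[gi, i]) for gi, g in enumerate(groups)}
        for i, sv in enumerate(sv_ids)
    }

    mod_of = np.array([-1 if assignment[sv] is None else assignment[sv] for sv in sv_ids])
    in_module = mod_of >= 0
    group_of_sample = {
        s: f"{meta.table.loc[s, 'field']}:{meta.table.loc[s, 'crop']}"
        for s in meta.sample_ids
    }

    log_basis = np.empty((len(meta.sample_ids), n_sv))
    counts = np.empty((len(meta.sample_ids), n_sv), dtype=np.int64)
    for si, s in enumerate(meta.sample_ids):
        lam = rng.normal(0.0, module_latent_sd, size=n_modules)
        eps = np.where(
            in_module,
            rng.normal(0.0, within_module_noise_sd, size=n_sv),
            rng.normal(0.0, module_latent_sd, size=n_sv),
        )
        gi = groups.index(group_of_sample[s])
        la = baseline + delta[gi] + np.where(in_module, lam[np.maximum(mod_of, 0)], 0.0) + eps
        log_basis[si] = la
        p = np.exp(la - la.max())
        p /= p.sum()
        if overdispersion > 0:
            p = rng.dirichlet(p / overdispersion)
        depth = int(rng.integers(lo, hi + 1))
        counts[si] = rng.multinomial(depth, p)

    basis_df = pd.DataFrame(log_basis, index=meta.sample_ids, columns=sv_ids)
    truth = SyntheticTruth(
        module_assignments=assignment,
        module_latent_sd=module_latent_sd,
        within_module_noise_sd=within_module_noise_sd,
        group_effects=group_effects,
        depth_range=(lo, hi),
        seed=seed,
        basis_log=basis_df,
    )
    lengths = pd.Series(
        rng.integers(390, 441, size=n_sv), index=sv_ids, name="length"
    )
    ft = FeatureTable(
        pd.DataFrame(counts, index=meta.sample_ids, columns=sv_ids),
        marker=MARKER_OF_PRESET[preset],
        sv_lengths=lengths,
    )
    tax = _taxonomy(sv_ids, preset, rng)
    return ft, tax, meta, truth


def generate_chemistry(
    meta: SampleMetadata,
    effect_map: dict[str, dict[str, float]] | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the 12-row (field x crop x stage) soil-chemistry table.

    Each cell value is ``baseline + sum(matching shifts) + noise`` where
    ``effect_map`` keys shifts by field, crop, stage or ``"field:crop"`` group
    label, and the Gaussian noise sd is ``noise_sd`` times the parameter
    baseline (chemistry parameters span three orders of magnitude, so relative
    noise keeps all of them realistic). Values are clipped at 0 and water
    content (WC, a fraction) to [0, 1].
    """
    effect_map = DEFAULT_CHEM_EFFECTS if effect_map is None else effect_map
    unknown = set(effect_map) - set(CHEM_PARAMS)
    if unknown:
        raise ValueError(f"unknown chemistry parameter(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    cells = [
        (f, c, st)
        for f in FIELDS for c in CROPS for st in STAGES
        if meta.table[(meta.table.field == f) & (meta.table.crop == c)
                      & (meta.table.stage == st)].shape[0] > 0
    ]
    rows = []
    for f, c, st in cells:
        row: dict[str, object] = {"field": f, "crop": c, "stage": st}
        keys = {f, c, st, f"{f}:{c}"}
        for p in CHEM_PARAMS:
            base = CHEM_BASELINES[p]
            shift = sum(v for k, v in effect_map.get(p, {}).items() if k in keys)
            val = base + shift + rng.normal(0.0, noise_sd * base)
            val = max(val, 0.0)
            if p == "WC":
                val = min(val, 1.0)
            row[p] = val
        rows.append(row)
    return pd.DataFrame(rows, columns=["field", "crop", "stage", *CHEM_PARAMS])
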