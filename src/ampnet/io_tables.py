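"""Tabular I/O, validation, filtering and aggregation for amplicon SV tables.

All on-disk formats are plain TSV with a header row (UTF-8). A feature table
stores read counts of sequence variants (SVs, i.e. ASVs); internally it is
always oriented samples x SVs regardless of the on-disk orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FIELDS = ("field_1", "field_2")
CROPS = ("maize", "cabbage")
STAGES = ("early", "middle", "late")
RANKS = ("domain", "phylum", "class", "order", "family", "genus")
NA_SENTINEL = "NA"

#: the twelve measured soil parameters (heatmap/RDA predictors)
CHEM_PARAMS = (
    "CEC", "pH_H2O", "pH_KCl", "NO3_N", "NH4_N", "K2O",
    "MgO", "CaO", "EC", "Tr_P2O5", "Humus", "WC",
)


@dataclass
class FeatureTable:
    """Non-negative integer SV read-count matrix, samples x SVs.

    Parameters
    ----------
    counts : pandas.DataFrame
        Integer counts; index = sample ids, columns = SV ids.
    marker : str
        Amplicon marker, ``"16S"`` (prokaryotes) or ``"18S"`` (eukaryotes).
    sv_lengths : pandas.Series, optional
        SV sequence lengths in bp, indexed by SV id.
    """

    counts: pd.DataFrame
    marker: str = "16S"
    sv_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.marker not in ("16S", "18S"):
            raise ValueError(f"marker must be '16S' or '18S', got {self.marker!r}")
        c = self.counts
        if c.index.has_duplicates:
            dups = sorted(c.index[c.index.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dups}")
        if c.columns.has_duplicates:
            dups = sorted(c.columns[c.columns.duplicated()].unique())
            raise ValueError(f"duplicate SV ids: {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr), atol=0):
                bad = np.argwhere(arr != np.round(arr))[0]
                raise ValueError(
                    "non-integer count at sample "
                    f"{c.index[bad[0]]!r}, SV {c.columns[bad[1]]!r}"
                )
            self.counts = c = c.astype(np.int64)
            arr = c.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {c.index[bad[0]]!r}, SV {c.columns[bad[1]]!r}"
            )
        totals = arr.sum(axis=1)
        if (totals == 0).any():
            empty = list(c.index[totals == 0])
            raise ValueError(f"samples with zero total reads: {empty}")
        self.counts = c = c.rename_axis(index=None, columns=None)
        if self.sv_lengths is not None:
            self.sv_lengths = self.sv_lengths.reindex(c.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_svs(self) -> int:
        return self.counts.shape[1]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.counts.copy(), self.marker,
            None if self.sv_lengths is None else self.sv_lengths.copy(),
        )


@dataclass
class SampleMetadata:
    """Per-sample design factors: field, crop, growth stage and replicate."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = {"field", "crop", "stage", "replicate"} - set(t.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        for col, allowed in (("field", FIELDS), ("crop", CROPS), ("stage", STAGES)):
            bad = sorted(set(t[col]) - set(allowed))
            if bad:
                raise ValueError(f"unknown {col} value(s) {bad}; allowed: {list(allowed)}")
        if t.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def groups(self) -> list[tuple[str, str]]:
        """The field x crop sample groups present, in canonical order."""
        present = {(r.field, r.crop) for r in self.table.itertuples()}
        return [(f, c) for f in FIELDS for c in CROPS if (f, c) in present]

    def samples_in_group(self, field: str, crop: str) -> list[str]:
        t = self.table
        return list(t.index[(t["field"] == field) & (t["crop"] == crop)])


@dataclass
class TaxonomyTable:
    """SV -> six-rank lineage (domain..genus); unassigned ranks hold ``"NA"``."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = set(RANKS) - set(t.columns)
        if missing:
            raise ValueError(f"taxonomy missing rank columns: {sorted(missing)}")
        t = t[list(RANKS)].astype("string")
        # empty / missing cells become the explicit sentinel, never dropped
        self.table = t.fillna(NA_SENTINEL).replace("", NA_SENTINEL).astype(str)

    def rank_of(self, sv_ids, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.table[rank].reindex(sv_ids).fillna(NA_SENTINEL)


@dataclass
class RelAbundanceTable:
    """Per-sample relative abundance at one taxonomic rank, minor taxa pooled."""

    rank: str
    proportions: pd.DataFrame  # samples x taxa, includes "minor" bin column if pooled
    threshold: float
    minor_taxa: list[str] = dc_field(default_factory=list)

    MINOR = "minor"


# ---------------------------------------------------------------------------
# readers / writers

def read_feature_table(
    path: str | Path,
    marker: str,
    orientation: str = "svs-rows",
    lengths_path: str | Path | None = None,
) -> FeatureTable:
    """Read an SV count table from TSV.

    ``orientation="svs-rows"`` (the default, matching the usual export: first
    column SV ids, one column per sample) or ``"samples-rows"``.
    """
    if orientation not in ("svs-rows", "samples-rows"):
        raise ValueError(f"orientation must be 'svs-rows' or 'samples-rows', got {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "svs-rows":
        df = df.T
    lengths = None
    if lengths_path is not None:
        ls = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = ls.iloc[:, 0].astype(int)
        lengths.index = lengths.index.astype(str)
    return FeatureTable(df, marker=marker, sv_lengths=lengths)


def write_feature_table(ft: FeatureTable, path: str | Path, orientation: str = "svs-rows") -> None:
    df = ft.counts.T if orientation == "svs-rows" else ft.counts
    label = "sv_id" if orientation == "svs-rows" else "sample_id"
    df.to_csv(path, sep="\t", index_label=label)


def read_metadata_taxonomy(
    meta_path: str | Path, tax_path: str | Path
) -> tuple[SampleMetadata, TaxonomyTable]:
    """Read sample metadata and taxonomy TSVs (first column = id)."""
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    meta.index = meta.index.astype(str)
    meta["replicate"] = meta["replicate"].astype(int)
    tax = pd.read_csv(tax_path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    tax.index = tax.index.astype(str)
    return SampleMetadata(meta), TaxonomyTable(tax)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    tax.table.to_csv(path, sep="\t", index_label="sv_id")


def read_chem_table(path: str | Path) -> pd.DataFrame:
    """Read a soil-chemistry TSV: columns field, crop, stage + the 12 parameters."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CHEM_PARAMS) - set(df.columns)
    if missing:
        raise ValueError(f"chemistry table missing parameter columns: {sorted(missing)}")
    return df


def write_chem_table(chem: pd.DataFrame, path: str | Path) -> None:
    chem.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# operations

def join_validate(ft: FeatureTable, meta: SampleMetadata) -> None:
    """Check that every sample in the feature table has metadata."""
    missing = set(ft.sample_ids) - set(meta.sample_ids)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")


def filter_by_length(ft: FeatureTable, min_len: int) -> FeatureTable:
    """Drop SVs strictly shorter than ``min_len`` bp.

    The boundary is strict: an SV of exactly ``min_len`` is retained. If the
    table carries no length annotation the table is returned unchanged with a
    logged warning.
    """
    if ft.sv_lengths is None:
        logger.warning("filter_by_length: no SV lengths available; table returned unchanged")
        return ft
    keep = ft.sv_lengths >= min_len
    keep = keep.fillna(True)
    kept_cols = [sv for sv, k in keep.items() if k]
    return FeatureTable(ft.counts[kept_cols], ft.marker, ft.sv_lengths[kept_cols])


def subset_by_group(
    ft: FeatureTable,
    meta: SampleMetadata,
    field: str,
    crop: str,
    drop_empty_svs: bool = False,
) -> FeatureTable:
    """Return the samples of one field x crop group.

    SVs with zero total count within the group are flagged via a warning;
    they are retained unless ``drop_empty_svs`` is set (log-ratio analyses
    must drop them, plain count summaries need not).
    """
    if field not in FIELDS:
        raise ValueError(f"unknown field {field!r}; allowed: {list(FIELDS)}")
    if crop not in CROPS:
        raise ValueError(f"unknown crop {crop!r}; allowed: {list(CROPS)}")
    samples = [s for s in meta.samples_in_group(field, crop) if s in set(ft.sample_ids)]
    if not samples:
        raise ValueError(f"group ({field}, {crop}) has no samples in the table")
    sub = ft.counts.loc[samples]
    empty = list(sub.columns[sub.sum(axis=0) == 0])
    if empty:
        logger.warning(
            "group (%s, %s): %d SV(s) have zero total count%s",
            field, crop, len(empty), " - dropped" if drop_empty_svs else "",
        )
        if drop_empty_svs:
            sub = sub.drop(columns=empty)
    lengths = None if ft.sv_lengths is None else ft.sv_lengths.reindex(sub.columns)
    return FeatureTable(sub, ft.marker, lengths)


def drop_group_zero_svs(ft: FeatureTable) -> FeatureTable:
    """Remove SVs whose total count is zero (required before clr/phi)."""
    keep = ft.counts.columns[ft.counts.sum(axis=0) > 0]
    lengths = None if ft.sv_lengths is None else ft.sv_lengths.reindex(keep)
    return FeatureTable(ft.counts[keep], ft.marker, lengths)


def aggregate_relative_abundance(
    ft: FeatureTable,
    tax: TaxonomyTable,
    rank: str,
    threshold: float,
) -> RelAbundanceTable:
    """Per-sample proportions summed by taxon at ``rank``; minor taxa pooled.

    A taxon is *major* when its share of the grand-total reads exceeds
    ``threshold`` (e.g. 0.005 for eukaryotes, 0.01 for prokaryotes); all
    others are pooled into a single ``minor`` bin. The ``"NA"`` category is a
    taxon like any other and may itself be major.
    """
    if rank not in ("phylum", "family", "genus"):
        raise ValueError(f"rank must be phylum/family/genus, got {rank!r}")
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    labels = tax.rank_of(ft.sv_ids, rank)
    props = ft.counts.div(ft.counts.sum(axis=1), axis=0)
    by_taxon = props.T.groupby(labels.values).sum().T
    grand_share = ft.counts.sum(axis=0).groupby(labels.values).sum()
    grand_share = grand_share / grand_share.sum()
    major = [t for t in grand_share.index if grand_share[t] > threshold]
    minor = [t for t in grand_share.index if t not in set(major)]
    major_sorted = sorted(major, key=lambda t: (-grand_share[t], t))
    out = by_taxon[major_sorted].copy()
    if minor:
        out[RelAbundanceTable.MINOR] = by_taxon[minor].sum(axis=1)
    return RelAbundanceTable(rank=rank, proportions=out, threshold=threshold,
                             minor_taxa=sorted(minor))
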