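"""Soil-chemistry normalization/clustering and redundancy analysis (RDA).

The chemistry heatmap preprocessing expresses each parameter as the
percentage each (field, crop, stage) cell contributes to the parameter's
column total; samples are then clustered by complete linkage (farthest
neighbor) on Euclidean distances. RDA regresses the centered clr community
matrix on (standardized) chemistry and decomposes the fitted values; biplot
vectors are parameter/site-score correlations scaled by axis importance, so
longer arrows mean stronger association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .io_tables import CHEM_PARAMS, SampleMetadata

logger = logging.getLogger(__name__)


def _numeric_part(chem: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in CHEM_PARAMS if c in chem.columns]
    if cols:
        return chem[list(cols)]
    return chem.select_dtypes("number")


def percent_normalize_chem(chem: pd.DataFrame) -> pd.DataFrame:
    """Per parameter, each cell value as percent of the column total.

    Every normalized column sums to 100. Input values must be non-negative;
    an all-zero parameter column cannot be normalized and raises.
    """
    num = _numeric_part(chem)
    arr = num.to_numpy(dtype=float)
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(f"negative chemistry value in parameter {num.columns[j]!r}")
    totals = arr.sum(axis=0)
    if (totals == 0).any():
        bad = [str(c) for c, t in zip(num.columns, totals) if t == 0]
        raise ValueError(f"all-zero parameter column(s): {bad}")
    pct = pd.DataFrame(arr / totals * 100.0, index=num.index, columns=num.columns)
    id_cols = [c for c in chem.columns if c not in set(num.columns)]
    if id_cols:
        pct = pd.concat([chem[id_cols], pct], axis=1)
    return pct


def cluster_samples_complete_linkage(pct: pd.DataFrame) -> np.ndarray:
    """Complete-linkage (farthest-neighbor) agglomeration on Euclidean distances.

    Returns the scipy linkage matrix: one merge per row, columns
    (cluster_a, cluster_b, height, size); merge heights are non-decreasing.
    """
    num = _numeric_part(pct)
    if num.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    return linkage(num.to_numpy(dtype=float), method="complete", metric="euclidean")


def broadcast_chemistry(chem: pd.DataFrame, meta: SampleMetadata) -> pd.DataFrame:
    """Expand the 12 cell-level chemistry rows to one row per sample.

    Chemistry is measured on composite (field, crop, stage) cells; each cell's
    values are broadcast to that cell's replicates so the matrix aligns with
    the community samples.
    """
    key_cols = ["field", "crop", "stage"]
    merged = meta.table.reset_index().merge(chem, on=key_cols, how="left")
    if merged[list(_numeric_part(chem).columns)].isna().any().any():
        missing = merged.loc[
            merged[_numeric_part(chem).columns[0]].isna(), "sample_id"
        ].tolist()
        raise ValueError(f"no chemistry cell for sample(s): {missing}")
    return merged.set_index("sample_id")[list(_numeric_part(chem).columns)]


@dataclass
class RdaResult:
    site_scores: pd.DataFrame      # samples x axes
    feature_scores: pd.DataFrame   # features x axes
    biplot_vectors: pd.DataFrame   # parameters x axes
    eigenvalues: np.ndarray        # per constrained axis, non-increasing
    constrained_fraction: float    # sum(eigenvalues) / total variance


def rda_fit(
    clr_point: pd.DataFrame,
    chem: pd.DataFrame,
    standardize: bool = True,
) -> RdaResult:
    """Redundancy analysis of a clr community matrix on chemistry.

    The centered response is regressed on centered (optionally standardized)
    predictors by least squares; an SVD of the fitted values yields the
    constrained axes. Eigenvalues are variances on each constrained axis;
    ``constrained_fraction`` is the share of total community variance the
    chemistry explains.
    """
    x = _numeric_part(chem).loc[clr_point.index]
    n, p = x.shape
    if p >= n:
        raise ValueError(f"more parameters ({p}) than samples allow (n={n})")
    xc = x.to_numpy(dtype=float) - x.to_numpy(dtype=float).mean(axis=0)
    if standardize:
        sd = xc.std(axis=0, ddof=1)
        const = sd == 0
        if const.any():
            logger.warning("constant chemistry column(s) kept unscaled: %s",
                           [str(c) for c, z in zip(x.columns, const) if z])
        xc = xc / np.where(sd == 0, 1.0, sd)
    if np.linalg.matrix_rank(xc) < p:
        logger.warning("rank-deficient chemistry matrix; fitting on its column space")
    y = clr_point.to_numpy(dtype=float)
    yc = y - y.mean(axis=0)
    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    yhat = xc @ beta
    u, s, vt = np.linalg.svd(yhat, full_matrices=False)
    tol = s.max(initial=0.0) * max(yhat.shape) * np.finfo(float).eps
    r = int((s > tol).sum())
    r = max(r, 1)
    u, s, vt = u[:, :r], s[:r], vt[:r]
    eig = s ** 2 / (n - 1)
    total_var = (yc ** 2).sum() / (n - 1)
    site = u * s
    axes = [f"RDA{i + 1}" for i in range(r)]
    site_df = pd.DataFrame(site, index=clr_point.index, columns=axes)
    feat_df = pd.DataFrame(vt.T, index=clr_point.columns, columns=axes)
    # biplot arrows: parameter/site-score correlations weighted by axis share
    bip = np.zeros((p, r))
    importance = np.sqrt(eig / eig.sum())
    for j in range(p):
        xj = xc[:, j]
        if xj.std() == 0:
            continue
        for a in range(r):
            sa = site[:, a]
            if sa.std() == 0:
                continue
            bip[j, a] = np.corrcoef(xj, sa)[0, 1] * importance[a]
    bip_df = pd.DataFrame(bip, index=list(x.columns), columns=axes)
    return RdaResult(site_df, feat_df, bip_df, eig, float(eig.sum() / total_var))


def feature_parameter_association(
    clr_point: pd.DataFrame,
    chem: pd.DataFrame,
    top_k: int = 5,
    abundance: pd.Series | None = None,
    max_features: int = 350,
) -> pd.DataFrame:
    """Rank features by |Pearson correlation| with each chemistry parameter.

    When per-feature total abundances are supplied, the candidate set is
    restricted to the ``max_features`` most abundant features (the study's
    top-350 rule). Constant features or parameters are excluded as undefined.
    Returns a tidy frame (parameter, feature, score, rank) with the top_k
    features per parameter.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    x = _numeric_part(chem).loc[clr_point.index]
    feats = clr_point
    if abundance is not None:
        keep = abundance.reindex(feats.columns).sort_values(ascending=False)
        feats = feats[list(keep.index[:max_features])]
    fa = feats.to_numpy(dtype=float)
    fa_sd = fa.std(axis=0)
    rows = []
    for param in x.columns:
        xv = x[param].to_numpy(dtype=float)
        if xv.std() == 0:
            logger.warning("parameter %s is constant; associations undefined", param)
            continue
        usable = fa_sd > 0
        scores = np.full(fa.shape[1], np.nan)
        xm = xv - xv.mean()
        fm = fa[:, usable] - fa[:, usable].mean(axis=0)
        scores[usable] = (xm @ fm) / (
            np.sqrt((xm ** 2).sum()) * np.sqrt((fm ** 2).sum(axis=0))
        )
        order = np.argsort(-np.abs(scores))
        rank = 0
        for idx in order:
            if np.isnan(scores[idx]):
                continue
            rank += 1
            if rank > top_k:
                break
            rows.append((str(param), feats.columns[idx], float(scores[idx]), rank))
    return pd.DataFrame(rows, columns=["parameter", "feature", "score", "rank"])
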