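"""Monte-Carlo centered log-ratio transformation and phi-proportionality.

The clr transform maps a composition to log abundance minus the sample's mean
log abundance, removing the arbitrary scale of sequencing depth. Zero counts
make the log undefined, so each sample is replaced by M Monte-Carlo instances
drawn from a Dirichlet posterior with a small uniform prior; every downstream
statistic is computed per instance and aggregated.

Proportionality between features i and j is measured by

    phi(i -> j) = Var_samples(clr_i - clr_j) / Var_samples(clr_i)

which is near 0 when the two features co-vary proportionally and near 2 for
independent features of equal variance. phi is invariant to the log base
(a variance ratio) and to per-sample count scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tables import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class ClrEnsemble:
    """Stack of clr instances: values has shape (M, n_samples, n_features)."""

    values: np.ndarray
    sample_ids: list[str]
    sv_ids: list[str]
    prior: float
    mode: str  # "montecarlo" or "point_estimate"
    seed: int

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    def point_estimate(self) -> pd.DataFrame:
        """Mean clr across instances as a samples x features frame."""
        return pd.DataFrame(
            self.values.mean(axis=0), index=self.sample_ids, columns=self.sv_ids
        )


def clr_ensemble(
    ft: FeatureTable,
    M: int = 128,
    prior: float = 0.5,
    seed: int = 0,
    mode: str = "montecarlo",
) -> ClrEnsemble:
    """clr-transform one sample group's counts.

    ``montecarlo`` draws M Dirichlet(counts + prior) proportion vectors per
    sample (ALDEx2-style, prior 0.5 by default); ``point_estimate`` uses the
    single composition (counts + prior) / sum. Features that are all-zero in
    the group must be removed first (their log-ratios are meaningless).
    """
    if mode not in ("montecarlo", "point_estimate"):
        raise ValueError(f"mode must be 'montecarlo' or 'point_estimate', got {mode!r}")
    if prior <= 0:
        raise ValueError(f"prior must be positive, got {prior}")
    counts = ft.counts.to_numpy(dtype=float)
    zero_cols = counts.sum(axis=0) == 0
    if zero_cols.any():
        bad = [sv for sv, z in zip(ft.sv_ids, zero_cols) if z]
        raise ValueError(
            f"features with all-zero counts must be removed before clr: {bad[:5]}"
            + ("..." if len(bad) > 5 else "")
        )
    if mode == "point_estimate":
        comp = counts + prior
        logp = np.log(comp)
        clr = logp - logp.mean(axis=1, keepdims=True)
        return ClrEnsemble(clr[None, :, :], ft.sample_ids, ft.sv_ids, prior, mode, seed)
    if M < 1:
        raise ValueError(f"montecarlo mode needs M >= 1, got {M}")
    rng = np.random.default_rng(seed)
    n, p = counts.shape
    values = np.empty((M, n, p))
    for si in range(n):
        draws = rng.dirichlet(counts[si] + prior, size=M)
        logp = np.log(draws)
        values[:, si, :] = logp - logp.mean(axis=1, keepdims=True)
    return ClrEnsemble(values, ft.sample_ids, ft.sv_ids, prior, mode, seed)


@dataclass
class PhiMatrix:
    """Symmetric phi-proportionality matrix (diagonal 0, undefined rows NaN)."""

    values: pd.DataFrame
    symmetrization: str
    aggregation: str
    undefined_svs: list[str] = dc_field(default_factory=list)


def phi_from_matrix(x: np.ndarray, symmetrization: str = "max") -> np.ndarray:
    """phi on a single (n_samples x n_features) log-ratio matrix.

    Directional phi(i->j) = Var(x_i - x_j) / Var(x_i) with unbiased sample
    variance, computed via the covariance identity Var(x_i - x_j) =
    V_i + V_j - 2 C_ij; symmetrized by max (default), min or mean of the two
    directions. Zero-variance features yield NaN rows/columns.
    """
    if symmetrization not in ("max", "min", "mean"):
        raise ValueError(f"symmetrization must be max/min/mean, got {symmetrization!r}")
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3:
        raise ValueError(f"need at least 3 samples, got {x.shape[0]}")
    c = np.cov(x, rowvar=False, ddof=1)
    v = np.diag(c).copy()
    var_diff = v[:, None] + v[None, :] - 2.0 * c
    np.clip(var_diff, 0.0, None, out=var_diff)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_dir = var_diff / v[:, None]
        phi_dir[v == 0, :] = np.nan
    if symmetrization == "max":
        phi = np.fmax(phi_dir, phi_dir.T)
    elif symmetrization == "min":
        phi = np.fmin(phi_dir, phi_dir.T)
    else:
        phi = 0.5 * (phi_dir + phi_dir.T)
    phi[v == 0, :] = np.nan
    phi[:, v == 0] = np.nan
    np.fill_diagonal(phi, 0.0)
    return phi


def phi_matrix(
    clr: ClrEnsemble,
    symmetrization: str = "max",
    aggregation: str = "mean",
) -> PhiMatrix:
    """Aggregate per-instance phi matrices across the Monte-Carlo ensemble.

    Default: max-symmetrized directional phi per instance, mean across
    instances (an edge then requires both directions to be proportional in
    the average instance).
    """
    if aggregation not in ("mean", "max"):
        raise ValueError(f"aggregation must be mean/max, got {aggregation!r}")
    agg = None
    for m in range(clr.n_instances):
        phi = phi_from_matrix(clr.values[m], symmetrization)
        if agg is None:
            agg = phi
        elif aggregation == "mean":
            agg = agg + phi
        else:
            agg = np.fmax(agg, phi)
    if aggregation == "mean":
        agg = agg / clr.n_instances
    # undefined features have NaN everywhere off the (zeroed) diagonal
    all_nan_off_diag = np.isnan(agg).sum(axis=1) >= agg.shape[1] - 1
    undefined = [sv for sv, bad in zip(clr.sv_ids, all_nan_off_diag) if bad]
    if undefined:
        logger.warning("phi undefined for %d zero-variance feature(s): %s",
                       len(undefined), undefined[:5])
    df = pd.DataFrame(agg, index=clr.sv_ids, columns=clr.sv_ids)
    return PhiMatrix(df, symmetrization, aggregation, undefined)


def write_phi_long(phi: PhiMatrix, path: str | Path) -> None:
    """Export phi as long-form TSV (sv_a, sv_b, phi), upper triangle only."""
    vals = phi.values
    ids = list(vals.index)
    rows = []
    arr = vals.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if not np.isnan(arr[i, j]):
                rows.append((ids[i], ids[j], arr[i, j]))
    pd.DataFrame(rows, columns=["sv_a", "sv_b", "phi"]).to_csv(path, sep="\t", index=False)
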