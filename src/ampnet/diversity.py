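"""Alpha/beta diversity: rarefaction, Shannon index with Tukey-Kramer tests,
Bray-Curtis distances, nonmetric multidimensional scaling and PERMANOVA.

NMDS is implemented as SMACOF iterative majorization with Kruskal's primary
approach to ties (monotone regression over pairs ordered by dissimilarity,
tied dissimilarities sub-ordered by current configuration distance), reporting
Kruskal stress-1. PERMANOVA follows the one-way distance-based partition of
sums of squares, with exact enumeration of distinct labelings when the
permutation space is small and seeded sampling otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import squareform, pdist
from scipy.stats import studentized_range
from skbio import DistanceMatrix
from sklearn.isotonic import IsotonicRegression
from sympy.utilities.iterables import multiset_permutations

from .io_tables import FeatureTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# rarefaction / alpha diversity

def rarefy_even_depth(
    ft: FeatureTable, depth: int | None = None, seed: int = 0
) -> FeatureTable:
    """Subsample every sample without replacement to an even depth.

    ``depth`` defaults to the minimum sample total. Samples shallower than
    ``depth`` are dropped with a warning; a single draw is taken (no
    averaging over repeated rarefactions).
    """
    totals = ft.counts.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"all samples have fewer than {depth} reads")
    if (~keep).any():
        logger.warning(
            "rarefy_even_depth: dropping %d sample(s) below depth %d: %s",
            int((~keep).sum()), depth, list(totals.index[~keep]),
        )
    rng = np.random.default_rng(seed)
    sub = ft.counts.loc[keep]
    out = np.empty_like(sub.to_numpy())
    for i, (_, row) in enumerate(sub.iterrows()):
        out[i] = rng.multivariate_hypergeometric(row.to_numpy(), depth)
    counts = pd.DataFrame(out, index=sub.index, columns=sub.columns)
    return FeatureTable(counts, ft.marker, ft.sv_lengths)


def shannon_index(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i of one sample (natural log
    by default; pass ``base`` for log2/log10)."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def tukey_kramer(values: dict[str, list[float] | np.ndarray]) -> pd.DataFrame:
    """All-pairs Tukey-Kramer test on group means.

    Uses the pooled within-group variance and the studentized range
    distribution; unequal group sizes are handled with the Kramer harmonic
    form ``SE = sqrt((MSW/2) (1/n_i + 1/n_j))``. Returns a tidy table with
    one row per pair: difference of means, q statistic and p-value. With zero
    pooled variance, equal means give p = 1 and unequal means are flagged
    ``degenerate`` with p below the machine floor.
    """
    groups = list(values)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = {g: np.asarray(values[g], dtype=float) for g in groups}
    for g, a in arrs.items():
        if a.size < 2:
            raise ValueError(f"group {g!r} needs at least 2 values")
    k = len(groups)
    n_total = sum(a.size for a in arrs.values())
    df = n_total - k
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs.values())
    msw = ssw / df
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrs[groups[i]], arrs[groups[j]]
            diff = a.mean() - b.mean()
            se = math.sqrt((msw / 2.0) * (1.0 / a.size + 1.0 / b.size))
            degenerate = False
            if se == 0.0:
                if diff == 0.0:
                    q, p = 0.0, 1.0
                else:
                    q, p = math.inf, float(np.nextafter(0, 1))
                    degenerate = True
            else:
                q = abs(diff) / se
                p = float(studentized_range.sf(q, k, df))
            rows.append((groups[i], groups[j], diff, se, q, p, degenerate))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "difference", "se", "q", "p", "degenerate"]
    )


# ---------------------------------------------------------------------------
# beta diversity

def bray_curtis_matrix(ft: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, BC(a,b) = 1 - 2 sum min / (sum a + sum b)."""
    x = ft.counts.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if (x.sum(axis=1) == 0).any():
        raise ValueError("sample with zero total reads")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, ids=ft.sample_ids)


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame  # samples x k
    stress: float              # Kruskal stress-1 of the best start
    stress_history: list[float]
    n_starts: int
    converged: bool
    seed: int


def _kruskal_disparities(delta: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Monotone regression of configuration distances on dissimilarities.

    Pairs are ordered by dissimilarity with ties sub-ordered by current
    distance (Kruskal's primary approach: no monotonicity is forced inside a
    tie block beyond what the data order already satisfies).
    """
    order = np.lexsort((dist, delta))
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(np.arange(order.size), dist[order])
    disp = np.empty_like(dist)
    disp[order] = fitted
    return disp


def _smacof_single(
    delta: np.ndarray, init: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, list[float], bool]:
    n = init.shape[0]
    iu = np.triu_indices(n, k=1)
    x = init - init.mean(axis=0)
    history: list[float] = []
    converged = False
    prev = np.inf
    for _ in range(max_iter):
        dist_mat = squareform(pdist(x))
        dist = dist_mat[iu]
        disp = _kruskal_disparities(delta[iu], dist)
        # scale so the majorized raw stress is comparable across iterations
        ssd = (disp ** 2).sum()
        if ssd == 0:
            stress = 0.0
            history.append(stress)
            converged = True
            break
        disp = disp * math.sqrt((dist ** 2).sum() / ssd)
        # Guttman transform
        dhat = squareform(disp)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist_mat > 0, dhat / np.where(dist_mat > 0, dist_mat, 1.0), 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = b.dot(x) / n
        x -= x.mean(axis=0)
        new_dist = pdist(x)
        num = ((new_dist - disp) ** 2).sum()
        den = (new_dist ** 2).sum()
        stress = math.sqrt(num / den) if den > 0 else 0.0
        history.append(stress)
        if prev - stress < tol:
            converged = True
            break
        prev = stress
    return x, history[-1] if history else math.inf, history, converged


def _classical_mds(delta: np.ndarray, k: int) -> np.ndarray:
    n = delta.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j.dot(delta ** 2).dot(j)
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:k]
    return v[:, idx] * np.sqrt(np.maximum(w[idx], 0.0))


def nmds_ordinate(
    d: DistanceMatrix | np.ndarray,
    k: int = 2,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> NmdsResult:
    """Nonmetric MDS minimizing Kruskal stress-1 over ``n_starts`` starts.

    The first start is initialized from classical (metric) scaling, the rest
    from seeded random configurations; the best converged configuration is
    kept and rotated (orthogonal Procrustes) onto the first converged one so
    repeated runs agree up to numerical noise.
    """
    if isinstance(d, DistanceMatrix):
        labels = list(d.ids)
        delta = d.data.copy()
    else:
        delta = np.asarray(d, dtype=float)
        labels = [str(i) for i in range(delta.shape[0])]
    n = delta.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} points, got {n}")
    rng = np.random.default_rng(seed)
    best = None
    reference = None
    any_converged = False
    for start in range(n_starts):
        init = _classical_mds(delta, k) if start == 0 else rng.normal(size=(n, k))
        if init.shape[1] < k:  # degenerate classical solution
            init = np.hstack([init, rng.normal(size=(n, k - init.shape[1])) * 1e-6])
        x, stress, history, converged = _smacof_single(delta, init, max_iter, tol)
        if converged and reference is None:
            reference = x
        any_converged = any_converged or converged
        if best is None or stress < best[1]:
            best = (x, stress, history, converged)
    x, stress, history, _ = best
    if reference is not None and x is not reference:
        r, _ = orthogonal_procrustes(x, reference)
        x = x.dot(r)
    coords = pd.DataFrame(x, index=labels, columns=[f"NMDS{i + 1}" for i in range(k)])
    return NmdsResult(coords, stress, history, n_starts, any_converged, seed)


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int
    method: str  # "exact" or "sampled"


def _ss_partition(d2: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return ss_total, ss_within


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total, ss_within = _ss_partition(d2, codes, k)
    ss_between = ss_total - ss_within
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, ss_between / ss_total


def permanova(
    d: DistanceMatrix | np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
    exact_limit: int = 10_000,
) -> PermanovaResult:
    """One-way PERMANOVA (adonis-style) on a distance matrix.

    ``groups`` maps each sample label to its group (dict / Series / aligned
    sequence). When the number of distinct label arrangements is at most
    ``exact_limit`` the p-value is computed by full enumeration (count of
    arrangements with F >= observed over the total, the observed arrangement
    included); otherwise by seeded sampling with the +1 correction
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations)``.
    """
    if isinstance(d, DistanceMatrix):
        labels = list(d.ids)
        dm = d.data
    else:
        dm = np.asarray(d, dtype=float)
        labels = list(range(dm.shape[0]))
    n = dm.shape[0]
    if isinstance(groups, dict):
        glist = [groups[s] for s in labels]
    elif isinstance(groups, pd.Series):
        glist = [groups[s] for s in labels]
    else:
        glist = list(groups)
        if len(glist) != n:
            raise ValueError("groups length does not match distance matrix")
    uniq = sorted(set(glist), key=str)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least two groups")
    if n - k <= 0:
        raise ValueError(f"residual degrees of freedom n-k = {n - k} <= 0")
    codes = np.array([uniq.index(g) for g in glist])
    d2 = dm ** 2
    f_obs, r2 = _pseudo_f(d2, codes, k)

    counts = np.bincount(codes, minlength=k)
    n_distinct = math.factorial(n)
    for c in counts:
        n_distinct //= math.factorial(int(c))
    if n_distinct <= exact_limit:
        ge = 0
        total = 0
        for perm in multiset_permutations(list(codes)):
            f_p, _ = _pseudo_f(d2, np.array(perm), k)
            total += 1
            if f_p >= f_obs - 1e-12:
                ge += 1
        return PermanovaResult(f_obs, r2, ge / total, total, seed, "exact")

    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_permutations):
        f_p, _ = _pseudo_f(d2, rng.permutation(codes), k)
        if f_p >= f_obs - 1e-12:
            ge += 1
    p = (1 + ge) / (1 + n_permutations)
    return PermanovaResult(f_obs, r2, p, n_permutations, seed, "sampled")
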