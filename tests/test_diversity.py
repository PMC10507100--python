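import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import norm, chi, tukey_hsd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import permanova as skbio_permanova
from skbio import DistanceMatrix

from ampnet import (
    bray_curtis_matrix,
    nmds_ordinate,
    permanova,
    rarefy_even_depth,
    shannon_index,
    tukey_kramer,
)
from ampnet.io_tables import FeatureTable


def make_ft(rows, samples=None):
    arr = np.asarray(rows)
    idx = samples or [f"s{i}" for i in range(arr.shape[0])]
    cols = [f"SV_{j}" for j in range(arr.shape[1])]
    return FeatureTable(pd.DataFrame(arr, index=idx, columns=cols))


class TestRarefaction:
    def test_single_supported_sv(self):
        ft = make_ft([[4, 0, 0], [3, 3, 3]])
        out = rarefy_even_depth(ft, depth=2, seed=0)
        assert list(out.counts.loc["s0"]) == [2, 0, 0]

    def test_even_depth_and_reproducibility(self, community):
        ft = community[0]
        out1 = rarefy_even_depth(ft, seed=5)
        out2 = rarefy_even_depth(ft, seed=5)
        depth = int(ft.counts.sum(axis=1).min())
        assert (out1.counts.sum(axis=1) == depth).all()
        pd.testing.assert_frame_equal(out1.counts, out2.counts)

    def test_shallow_samples_dropped(self, caplog):
        ft = make_ft([[100, 100], [1, 1]])
        with caplog.at_level("WARNING"):
            out = rarefy_even_depth(ft, depth=50, seed=0)
        assert out.sample_ids == ["s0"]

    def test_all_samples_too_shallow_rejected(self):
        ft = make_ft([[1, 1], [2, 0]])
        with pytest.raises(ValueError, match="fewer than"):
            rarefy_even_depth(ft, depth=100)


class TestShannon:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([5, 5, 5, 5], math.log(4)),
            ([10, 0, 0], 0.0),
            ([1, 2, 3], 1.011404),  # direct -sum p ln p
        ],
    )
    def test_closed_forms(self, counts, expected):
        assert shannon_index(counts) == pytest.approx(expected, abs=1e-6)

    def test_upper_bound_uniform_only(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = rng.integers(1, 50, size=8)
            assert shannon_index(c) <= math.log(8) + 1e-12
        assert shannon_index([3] * 8) == pytest.approx(math.log(8))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([0, 0])


def studentized_range_sf_oracle(q, k, df):
    """Independent double-quadrature of the studentized range survival function."""

    def p_range_lt(x):
        f = lambda z: norm.pdf(z) * (norm.cdf(z) - norm.cdf(z - x)) ** (k - 1)
        val, _ = integrate.quad(f, -8, 8)
        return k * val

    # u = s/sigma, with s the pooled sd estimate on df degrees of freedom
    g = lambda u: chi.pdf(u * math.sqrt(df), df) * math.sqrt(df) * p_range_lt(q * u)
    cdf, _ = integrate.quad(g, 0, 8, limit=200)
    return 1.0 - cdf


class TestTukeyKramer:
    def test_identical_groups_give_p_one(self):
        res = tukey_kramer({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        row = res.iloc[0]
        assert row.q == 0 and row.p == pytest.approx(1.0)

    def test_growing_gap_shrinks_p(self):
        base = [0.0, 1.0, 2.0]
        ps = [
            tukey_kramer({"a": base, "b": [x + v for v in base]}).iloc[0].p
            for x in (1.0, 2.0, 4.0)
        ]
        assert ps[0] > ps[1] > ps[2]

    def test_matches_quadrature_oracle(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [5.0, 6.0, 7.0]}
        res = tukey_kramer(groups)
        for row in res.itertuples():
            expected = studentized_range_sf_oracle(row.q, k=3, df=6)
            assert row.p == pytest.approx(expected, abs=1e-3)

    def test_matches_scipy_tukey_hsd(self):
        groups = {"a": [1.0, 2.0, 2.5], "b": [2.0, 3.5, 4.0], "c": [5.0, 6.0, 8.0]}
        res = tukey_kramer(groups)
        ref = tukey_hsd(*groups.values())
        got = {(r.group_a, r.group_b): r.p for r in res.itertuples()}
        keys = list(groups)
        for i in range(3):
            for j in range(i + 1, 3):
                assert got[(keys[i], keys[j])] == pytest.approx(
                    ref.pvalue[i, j], abs=1e-9
                )

    def test_zero_variance_unequal_means_flagged(self):
        res = tukey_kramer({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        row = res.iloc[0]
        assert row.degenerate and row.p < 1e-300


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        ft = make_ft([[3, 1, 0], [3, 1, 0], [0, 0, 7]])
        bc = bray_curtis_matrix(ft)
        assert bc["s0", "s1"] == pytest.approx(0.0)
        assert bc["s0", "s2"] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        bc = bray_curtis_matrix(make_ft([[2, 0, 1], [1, 1, 0]]))
        assert bc["s0", "s1"] == pytest.approx(0.6)  # 1 - 2*1/5

    def test_semimetric_bounds(self, community):
        bc = bray_curtis_matrix(community[0])
        d = bc.data
        assert np.allclose(d, d.T, atol=1e-12)
        assert np.allclose(np.diag(d), 0)
        assert d.min() >= 0 and d.max() <= 1


class TestNmds:
    def test_three_points_embed_exactly(self):
        d = np.array([[0, 1, 1.5], [1, 0, 2], [1.5, 2, 0]])
        res = nmds_ordinate(d, n_starts=4, seed=0)
        assert res.stress <= 1e-6

    def test_planar_points_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 2))
        d = squareform(pdist(pts))
        res = nmds_ordinate(d, n_starts=8, seed=0)
        assert res.stress < 0.01
        assert res.converged

    def test_stress_non_increasing_within_start(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 3))
        d = squareform(pdist(pts))
        res = nmds_ordinate(d, k=2, n_starts=5, seed=3)
        h = res.stress_history
        assert all(b <= a + 1e-9 for a, b in zip(h, h[1:]))

    def test_monotone_transform_leaves_stress(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 4))
        d = squareform(pdist(pts))
        s1 = nmds_ordinate(d, n_starts=8, seed=0).stress
        s2 = nmds_ordinate(d ** 2, n_starts=8, seed=0).stress  # strictly monotone map
        assert s2 == pytest.approx(s1, abs=0.02)


class TestPermanova:
    def fixture_d(self):
        x = np.array([0.0, 1.0, 10.0, 11.0])
        return np.abs(np.subtract.outer(x, x)), ["A", "A", "B", "B"]

    def test_exact_fixture(self):
        d, g = self.fixture_d()
        res = permanova(d, g)
        assert res.pseudo_F == pytest.approx(200.0)
        assert res.R2 == pytest.approx(100.0 / 101.0)
        assert res.p_value == pytest.approx(1.0 / 3.0)
        assert res.method == "exact"

    def test_invariant_to_sample_order(self):
        d, g = self.fixture_d()
        perm = [2, 0, 3, 1]
        res = permanova(d[np.ix_(perm, perm)], [g[i] for i in perm])
        assert res.pseudo_F == pytest.approx(200.0)

    def test_sampled_p_converges_to_exact(self):
        d, g = self.fixture_d()
        exact = permanova(d, g).p_value
        sampled = permanova(d, g, n_permutations=9999, seed=1, exact_limit=1)
        assert sampled.method == "sampled"
        assert sampled.p_value == pytest.approx(exact, abs=0.02)

    def test_pseudo_f_matches_skbio(self, community):
        ft, _, meta, _ = community
        bc = bray_curtis_matrix(ft)
        groups = [
            f"{meta.table.loc[s, 'field']}:{meta.table.loc[s, 'crop']}" for s in bc.ids
        ]
        mine = permanova(bc, groups, n_permutations=99, seed=0)
        ref = skbio_permanova(DistanceMatrix(bc.data, ids=bc.ids), groups,
                              permutations=9)
        assert mine.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_too_few_residual_df_rejected(self):
        d = np.array([[0, 1], [1, 0]], dtype=float)
        with pytest.raises(ValueError):
            permanova(d, ["A", "B"])
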