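import numpy as np
import pandas as pd
import pytest

from ampnet import (
    cluster_samples_complete_linkage,
    feature_parameter_association,
    generate_chemistry,
    generate_community,
    percent_normalize_chem,
    rda_fit,
)
from ampnet.chem_analysis import broadcast_chemistry
from ampnet.composition import clr_ensemble
from ampnet.io_tables import drop_group_zero_svs


class TestPercentNormalize:
    def test_simple_column(self):
        chem = pd.DataFrame({"CEC": [2.0, 3.0, 5.0]})
        pct = percent_normalize_chem(chem)
        assert list(pct["CEC"]) == pytest.approx([20.0, 30.0, 50.0])

    def test_columns_sum_to_hundred(self, design_metadata):
        chem = generate_chemistry(design_metadata, seed=1)
        pct = percent_normalize_chem(chem)
        sums = pct.select_dtypes("number").sum(axis=0)
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_idempotent_up_to_scale(self):
        chem = pd.DataFrame({"CEC": [2.0, 3.0, 5.0]})
        once = percent_normalize_chem(chem)
        twice = percent_normalize_chem(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            percent_normalize_chem(pd.DataFrame({"CEC": [1.0, -1.0]}))

    def test_all_zero_column_named(self):
        with pytest.raises(ValueError, match="pH_H2O"):
            percent_normalize_chem(pd.DataFrame({"CEC": [1.0, 2.0], "pH_H2O": [0.0, 0.0]}))


class TestCompleteLinkage:
    def test_identical_rows_merge_first_at_zero(self):
        x = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
        z = cluster_samples_complete_linkage(x)
        assert z[0, 2] == pytest.approx(0.0)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}

    def test_hand_agglomeration_1d(self):
        x = pd.DataFrame([[0.0], [1.0], [10.0]])
        z = cluster_samples_complete_linkage(x)
        assert z[0, 2] == pytest.approx(1.0)   # {0,1} merge
        assert z[1, 2] == pytest.approx(10.0)  # farthest neighbor: max(9, 10)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.normal(size=(15, 4)))
        z = cluster_samples_complete_linkage(x)
        assert (np.diff(z[:, 2]) >= -1e-12).all()


def brute_force_first_eigenvalue(xc, yc):
    """Eigendecomposition oracle for the first constrained axis."""
    h = xc @ np.linalg.pinv(xc.T @ xc) @ xc.T
    yhat = h @ yc
    cov = yhat.T @ yhat / (yc.shape[0] - 1)
    return float(np.max(np.linalg.eigvalsh(cov)))


class TestRda:
    def test_noiseless_linear_response_fully_constrained(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"CEC": rng.normal(size=12), "WC": rng.normal(size=12)})
        b = rng.normal(size=(2, 5))
        y = pd.DataFrame(x.to_numpy() @ b, columns=[f"SV_{i}" for i in range(5)])
        res = rda_fit(y, x)
        assert res.constrained_fraction >= 0.999

    def test_fixture_eigenvalue_matches_brute_force(self):
        y = pd.DataFrame([[1.0, 0.5], [2.0, 0.2], [0.5, 1.5], [3.0, 0.1]],
                         columns=["SV_1", "SV_2"])
        x = pd.DataFrame({"CEC": [1.0, 2.0, 0.0, 3.5]})
        res = rda_fit(y, x, standardize=True)
        xc = x.to_numpy() - x.to_numpy().mean(axis=0)
        xc = xc / xc.std(axis=0, ddof=1)
        yc = y.to_numpy() - y.to_numpy().mean(axis=0)
        assert res.eigenvalues[0] == pytest.approx(
            brute_force_first_eigenvalue(xc, yc), abs=1e-10
        )

    def test_orthogonal_chemistry_explains_little(self):
        rng = np.random.default_rng(1)
        n, p = 200, 3
        x = pd.DataFrame(rng.normal(size=(n, p)), columns=["CEC", "WC", "Humus"])
        y = pd.DataFrame(rng.normal(size=(n, 10)),
                         columns=[f"SV_{i}" for i in range(10)])
        res = rda_fit(y, x)
        # expectation for pure noise is roughly p/(n-1)
        assert res.constrained_fraction < 3 * p / n

    def test_eigenvalues_non_negative_non_increasing(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.normal(size=(20, 4)), columns=["CEC", "WC", "Humus", "EC"])
        y = pd.DataFrame(rng.normal(size=(20, 8)),
                         columns=[f"SV_{i}" for i in range(8)])
        res = rda_fit(y, x)
        assert (res.eigenvalues >= 0).all()
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert 0 <= res.constrained_fraction <= 1

    def test_shift_invariance_when_standardized(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.normal(size=(15, 2)), columns=["CEC", "WC"])
        y = pd.DataFrame(rng.normal(size=(15, 6)),
                         columns=[f"SV_{i}" for i in range(6)])
        a = rda_fit(y, x)
        b = rda_fit(y, x + 100.0)
        assert np.allclose(a.eigenvalues, b.eigenvalues, atol=1e-10)

    def test_more_parameters_than_samples_rejected(self):
        x = pd.DataFrame(np.eye(3), columns=["CEC", "WC", "Humus"])
        y = pd.DataFrame(np.eye(3), columns=["SV_1", "SV_2", "SV_3"])
        with pytest.raises(ValueError, match="parameters"):
            rda_fit(y, x)

    def test_water_content_loads_on_field_axis(self, design_metadata):
        # plant a field_2 water shift as the only field-structured parameter;
        # the generated communities differ by group, so the RDA axis that
        # separates fields must carry WC's largest loading
        ft, _, meta, _ = generate_community(seed=9)
        chem = generate_chemistry(
            meta,
            effect_map={"WC": {"field_2": 0.3}, "NO3_N": {"maize": 8.0}},
            noise_sd=0.0, seed=0,
        )
        clr = clr_ensemble(drop_group_zero_svs(ft), mode="point_estimate").point_estimate()
        res = rda_fit(clr, broadcast_chemistry(chem, meta))
        site = res.site_scores
        is_f2 = meta.table.loc[site.index, "field"] == "field_2"
        sep = (site[is_f2.values].mean() - site[~is_f2.values].mean()).abs()
        field_axis = sep.idxmax()
        assert res.biplot_vectors.loc["WC"].abs().idxmax() == field_axis
        assert res.biplot_vectors[field_axis].abs().idxmax() == "WC"


class TestFeatureParameterAssociation:
    def test_identical_and_negated_profiles_rank_first(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"CEC": rng.normal(size=10)})
        feats = pd.DataFrame({
            "SV_same": x["CEC"],
            "SV_neg": -x["CEC"],
            "SV_noise": rng.normal(size=10),
        })
        res = feature_parameter_association(feats, x, top_k=3)
        top = res[res["rank"] == 1].iloc[0]
        assert top.feature in ("SV_same", "SV_neg")
        scores = dict(zip(res.feature, res.score))
        assert scores["SV_same"] == pytest.approx(1.0)
        assert scores["SV_neg"] == pytest.approx(-1.0)

    def test_constant_feature_excluded(self):
        x = pd.DataFrame({"CEC": [1.0, 2.0, 3.0, 4.0]})
        feats = pd.DataFrame({"SV_const": [5.0] * 4, "SV_var": [1.0, 2.0, 2.5, 4.0]})
        res = feature_parameter_association(feats, x, top_k=2)
        assert "SV_const" not in set(res.feature)

    def test_abundance_restriction(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame({"CEC": rng.normal(size=8)})
        feats = pd.DataFrame(rng.normal(size=(8, 5)),
                             columns=[f"SV_{i}" for i in range(5)])
        abundance = pd.Series([5, 4, 3, 2, 1], index=feats.columns)
        res = feature_parameter_association(feats, x, top_k=5,
                                            abundance=abundance, max_features=2)
        assert set(res.feature) <= {"SV_0", "SV_1"}

    def test_planted_module_coupling_recovered(self, design_metadata):
        # features built directly from a chemistry parameter occupy the top
        # ranks for that parameter
        rng = np.random.default_rng(2)
        chem = generate_chemistry(design_metadata, noise_sd=0.05, seed=3)
        per_sample = broadcast_chemistry(chem, design_metadata)
        coupled = per_sample["Humus"].to_numpy()
        feats = {f"SV_c{i}": coupled * (1 + 0.1 * i) for i in range(3)}
        feats.update({f"SV_r{i}": rng.normal(size=len(coupled)) for i in range(10)})
        res = feature_parameter_association(
            pd.DataFrame(feats, index=per_sample.index), per_sample, top_k=3
        )
        top_humus = set(res[res.parameter == "Humus"].feature)
        assert top_humus == {"SV_c0", "SV_c1", "SV_c2"}
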