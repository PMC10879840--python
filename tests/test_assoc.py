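"""Standardization, VIF, BH correction, EMM contrasts and the two
association procedures."""

import logging

import numpy as np
import pandas as pd
import pytest

from owlmhc import simdata
from owlmhc.assoc import (
    back_transform,
    emm_contrasts,
    run_divergence_analysis,
    run_supertype_analysis,
    standardize_predictors,
    vif_check,
    _max_abs_z_p,
)
from owlmhc.glmm import MixedGLM


class TestStandardize:
    def test_constant_predictor_named_in_error(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="'x'"):
            standardize_predictors(df, ["x"])

    def test_gelman_scheme_gives_sd_half(self):
        df = pd.DataFrame({"x": np.random.default_rng(0).normal(3, 2, 500)})
        out, meta = standardize_predictors(df, ["x"])
        assert out["x"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["x"].std() == pytest.approx(0.5)

    def test_back_transform_round_trip(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 5.0, 9.0]})
        out, meta = standardize_predictors(df, ["x"])
        restored = back_transform(out.set_index(pd.Index(range(4)))["x"], {})
        x2 = out["x"] * meta["x"][1] + meta["x"][0]
        np.testing.assert_allclose(x2, df["x"])
        assert restored.equals(out["x"])  # empty meta leaves values alone


class TestVIF:
    def test_orthogonal_predictors_unit_vif(self):
        rng = np.random.default_rng(0)
        # orthogonalize against the intercept too, so R^2_j is exactly 0
        q, _ = np.linalg.qr(np.column_stack([np.ones(40), rng.normal(size=(40, 3))]))
        vifs = vif_check(pd.DataFrame(q[:, 1:], columns=list("abc")))
        np.testing.assert_allclose(vifs, 1.0, atol=1e-9)

    def test_duplicated_predictor_rejected(self):
        x = np.random.default_rng(0).normal(size=30)
        df = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValueError, match="collinear"):
            vif_check(df)

    @pytest.mark.parametrize("r", [0.3, 0.6, 0.9])
    def test_two_correlated_predictors_closed_form(self, r):
        rng = np.random.default_rng(2)
        n = 200_000
        a = rng.normal(size=n)
        b = r * a + np.sqrt(1 - r**2) * rng.normal(size=n)
        vifs = vif_check(pd.DataFrame({"a": a, "b": b}))
        assert vifs["a"] == pytest.approx(1 / (1 - r**2), rel=0.02)


class TestBenjaminiHochberg:
    def test_step_up_example_vs_brute_force(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.01, 0.02, 0.04]
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        # independent brute-force step-up: p_(i) * m / i with cumulative min
        m = len(p)
        order = np.argsort(p)
        stepped = np.array(p)[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(stepped[::-1])[::-1]
        brute = np.empty(m)
        brute[order] = np.minimum(stepped, 1)
        np.testing.assert_allclose(adj, brute)
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.04])

    def test_adjusted_never_smaller_than_raw_and_monotone(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=12))
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        assert (adj >= p - 1e-15).all()
        assert (np.diff(adj) >= -1e-15).all()


class TestEMM:
    @staticmethod
    def _balanced_2x2(seed=0, per=150):
        """Balanced logistic 2x2 with known cell probabilities."""
        rng = np.random.default_rng(seed)
        cells = [(0, 0, 0.8), (0, 1, 0.6), (1, 0, 0.6), (1, 1, 0.3)]
        rows = []
        for a, b, p in cells:
            for _ in range(per):
                t = 6
                rows.append((a, b, t, rng.binomial(t, p)))
        df = pd.DataFrame(rows, columns=["fa", "fb", "trials", "y"])
        df["fa:fb"] = df["fa"] * df["fb"]
        df["const"] = 1.0
        return df

    def _fit(self, df):
        X = df[["const", "fa", "fb", "fa:fb"]]
        return MixedGLM(df["y"], X, family="binomial", trials=df["trials"]).fit()

    def test_emms_equal_cell_means_on_link_scale(self):
        df = self._balanced_2x2()
        res = self._fit(df)
        emm, _ = emm_contrasts(res, ("fa", "fb"))
        for (a, b), grp in df.groupby(["fa", "fb"]):
            p_hat = grp["y"].sum() / grp["trials"].sum()
            logit = np.log(p_hat / (1 - p_hat))
            assert emm.loc[f"fa={a},fb={b}", "emm"] == pytest.approx(logit, abs=1e-6)

    def test_odds_ratio_matches_contingency(self):
        df = self._balanced_2x2()
        res = self._fit(df)
        _, contr = emm_contrasts(res, ("fa", "fb"))
        row = contr[contr["contrast"] == "(fa=0,fb=0) - (fa=1,fb=1)"].iloc[0]
        g00 = df[(df.fa == 0) & (df.fb == 0)]
        g11 = df[(df.fa == 1) & (df.fb == 1)]
        p00 = g00["y"].sum() / g00["trials"].sum()
        p11 = g11["y"].sum() / g11["trials"].sum()
        or_hand = (p00 / (1 - p00)) / (p11 / (1 - p11))
        assert row["odds_ratio"] == pytest.approx(or_hand, rel=1e-6)

    def test_null_contrast_probability_one(self):
        corr = np.eye(3)
        assert _max_abs_z_p(0.0, corr) == 1.0
        # large z -> tiny p; adjustment exceeds the unadjusted two-sided p
        from scipy.stats import norm

        z = 2.0
        p_adj = _max_abs_z_p(z, corr)
        p_raw = 2 * norm.sf(z)
        assert p_raw < p_adj < min(1.0, 3 * p_raw) + 1e-9


class TestDivergenceAnalysis:
    def test_recovers_injected_negative_effect(self, small_breeding):
        nests, div_df = small_breeding
        avg = run_divergence_analysis(nests, div_df, "MHC-Ia",
                                      random_structure="couple")
        assert avg.coef.loc["f_div", "beta"] < 0
        assert "f_div" in avg.coef.index and len(avg.selection_table) == 13

    def test_crossfostered_mode_has_quartet_terms(self, small_breeding):
        nests, div_df = small_breeding
        avg = run_divergence_analysis(nests, div_df, "MHC-Ia",
                                      dataset_mode="crossfostered",
                                      random_structure="couple")
        assert {"gf_div", "gm_div", "sf_div", "sm_div"} <= set(avg.coef.index)
        assert len(avg.selection_table) <= 169

    def test_aliasing_guard_drops_social_terms(self, caplog):
        div = pd.Series(np.random.default_rng(3).gamma(4, 1.2, 200),
                        index=[f"ind{i:04d}" for i in range(200)])
        nests = simdata.simulate_breeding(div, simdata.EffectConfig(), 80,
                                          seed=2, crossfoster_plan="none")
        nests["crossfoster"] = "full"  # social == genetic but flagged full
        div_df = pd.DataFrame({"sample_id": div.index, "locus": "L",
                               "functional_divergence": div.to_numpy()})
        with caplog.at_level(logging.WARNING, logger="owlmhc.assoc"):
            avg = run_divergence_analysis(nests, div_df, "L",
                                          dataset_mode="crossfostered",
                                          random_structure="couple")
        assert any("social terms dropped" in r.message for r in caplog.records)
        assert "sf_div" not in avg.coef.index

    def test_too_few_records_refused(self, small_breeding):
        nests, div_df = small_breeding
        with pytest.raises(ValueError, match="underpowered"):
            run_divergence_analysis(nests.head(10), div_df, "MHC-Ia")


@pytest.fixture(scope="module")
def st_data():
        rng = np.random.default_rng(8)
        ids = [f"ind{i:04d}" for i in range(300)]
        div = pd.Series(rng.gamma(4, 1.2, 300), index=ids)
        presence = pd.DataFrame(
            rng.binomial(1, [0.45, 0.3, 0.2], size=(300, 3)),
            index=ids, columns=["ST1", "ST2", "ST3"],
        )
        eff = simdata.EffectConfig(
            supertype_effects={"ST2": (0.0, 0.0, 1.8)}
        )
        nests = simdata.simulate_breeding(
            div, eff, 220, seed=4, crossfoster_plan="none",
            supertype_presence=presence,
        )
        return nests, presence


class TestSupertypeAnalysis:
    def test_injected_interaction_detected_and_contrasted(self, st_data):
        nests, presence = st_data
        tests = run_supertype_analysis(nests, presence, ["ST1", "ST2", "ST3"],
                                       random_structure="couple")
        by_st = {t.supertype: t for t in tests}
        assert "f_st:m_st" in by_st["ST2"].significant_terms
        assert by_st["ST2"].contrasts is not None
        assert by_st["ST2"].emm.shape[0] == 4

    def test_adjusted_p_at_least_raw(self, st_data):
        nests, presence = st_data
        tests = run_supertype_analysis(nests, presence, ["ST1", "ST2", "ST3"],
                                       random_structure="couple")
        for t in tests:
            ok = t.terms.dropna(subset=["p_raw"])
            assert (ok["p_adj"] >= ok["p_raw"] - 1e-12).all()

    def test_null_supertypes_mostly_quiet(self, st_data):
        nests, presence = st_data
        tests = run_supertype_analysis(nests, presence, ["ST1", "ST3"],
                                       random_structure="couple")
        assert all(not t.significant_terms for t in tests)
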