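import warnings

import numpy as np
import pandas as pd
import pytest

from dyadcoord.errors import ImputationError, ModelSpecError
from dyadcoord.models import (
    ModelSpec,
    center_predictors,
    fit_lmm,
    impute_subscale_mean,
    pairwise_contrasts,
    simple_slopes,
)

warnings.filterwarnings("ignore", module="statsmodels")


def make_table(rng, n=60, b_gaze=0.4, b_coord=-0.3, b_gc=0.25, b_lsas_gaze=0.0,
               tau=0.5, sigma=0.4):
    """Balanced 2x2 study table from the random-intercept generative form."""
    gaze = np.repeat(np.concatenate([np.zeros(n // 2), np.ones(n - n // 2)]), 2)
    coord = np.tile([0.0, 1.0], n)
    pid = np.repeat([f"p{i:03d}" for i in range(n)], 2)
    lsas = np.repeat(rng.normal(0, 20, n), 2)
    u = np.repeat(rng.normal(0, tau, n), 2)
    y = (0.5 + b_gaze * gaze + b_coord * coord + b_gc * gaze * coord
         + b_lsas_gaze * lsas * gaze + u + rng.normal(0, sigma, 2 * n))
    return pd.DataFrame({"participant_id": pid, "gaze_code": gaze,
                         "coord_code": coord, "lsas": lsas, "rho_z": y})


class TestImputation:
    ITEMS = {"performance": ["p1", "p2", "p3"], "social": ["s1", "s2"]}

    def test_no_missing_is_identity(self):
        df = pd.DataFrame({"p1": [1.0], "p2": [2.0], "p3": [3.0],
                           "s1": [4.0], "s2": [5.0]})
        pd.testing.assert_frame_equal(impute_subscale_mean(df, self.ITEMS), df)

    def test_missing_item_gets_subscale_mean(self):
        df = pd.DataFrame({"p1": [2.0], "p2": [4.0], "p3": [np.nan],
                           "s1": [1.0], "s2": [1.0]})
        out = impute_subscale_mean(df, self.ITEMS)
        assert out.loc[0, "p3"] == 3.0
        assert out[self.ITEMS["performance"]].iloc[0].sum() == 9.0

    def test_whole_subscale_missing_raises(self):
        df = pd.DataFrame({"p1": [2.0], "p2": [4.0], "p3": [1.0],
                           "s1": [np.nan], "s2": [np.nan]})
        with pytest.raises(ImputationError):
            impute_subscale_mean(df, self.ITEMS)


class TestCenterPredictors:
    def test_centres_to_zero_mean(self, rng):
        df = pd.DataFrame({"lsas": rng.normal(50, 20, 100)})
        out, centers = center_predictors(df, ["lsas"])
        assert abs(out["lsas_c"].mean()) < 1e-9
        assert centers["lsas"] == pytest.approx(df["lsas"].mean())

    def test_already_centred_unchanged(self, rng):
        x = rng.normal(0, 1, 50)
        x -= x.mean()
        df = pd.DataFrame({"v": x})
        out, _ = center_predictors(df, ["v"])
        np.testing.assert_allclose(out["v_c"], x, atol=1e-12)

    def test_binary_code_centres_to_proportions(self):
        df = pd.DataFrame({"g": [0, 0, 0, 1]})
        out, centers = center_predictors(df, ["g"])
        assert centers["g"] == 0.25
        np.testing.assert_allclose(out["g_c"], [-0.25, -0.25, -0.25, 0.75])

    def test_non_numeric_rejected(self):
        with pytest.raises(TypeError):
            center_predictors(pd.DataFrame({"g": ["a", "b"]}), ["g"])


class TestFitLmm:
    def test_intercept_only_recovers_grand_mean(self, rng):
        df = make_table(rng)
        res = fit_lmm(df, ModelSpec("rho_z", "1"))
        assert res.params["Intercept"] == pytest.approx(df["rho_z"].mean(), abs=1e-6)

    def test_parameter_recovery_two_se(self, rng):
        hits = 0
        truth = {"gaze_code": 0.4, "coord_code": -0.3, "gaze_code:coord_code": 0.25}
        n_rep = 20
        for _ in range(n_rep):
            df = make_table(rng)
            res = fit_lmm(df, ModelSpec("rho_z", "gaze_code * coord_code"))
            t = res.terms.set_index("term")
            hits += sum(abs(t.loc[k, "estimate"] - v) <= 2 * t.loc[k, "se"]
                        for k, v in truth.items())
        assert hits / (n_rep * len(truth)) >= 0.85

    def test_zero_variance_outcome_flagged_singular(self, rng):
        df = make_table(rng)
        df["rho_z"] = 1.0
        res = fit_lmm(df, ModelSpec("rho_z", "gaze_code"))
        assert res.singular

    def test_zero_between_variance_matches_ols(self, rng):
        df = make_table(rng, tau=0.0)
        res = fit_lmm(df, ModelSpec("rho_z", "gaze_code * coord_code"))
        assert res.re_var < 0.05
        X = np.column_stack([np.ones(len(df)), df.gaze_code, df.coord_code,
                             df.gaze_code * df.coord_code])
        beta = np.linalg.lstsq(X, df.rho_z.to_numpy(), rcond=None)[0]
        got = res.terms["estimate"].to_numpy()
        order = ["Intercept", "gaze_code", "coord_code", "gaze_code:coord_code"]
        got = res.params[order].to_numpy()
        np.testing.assert_allclose(got, beta, atol=5e-4)

    def test_centring_leaves_top_interaction_unchanged(self, rng):
        df = make_table(rng, b_lsas_gaze=0.004)
        df, _ = center_predictors(df, ["lsas"])
        raw = fit_lmm(df, ModelSpec("rho_z", "lsas * gaze_code * coord_code"))
        cen = fit_lmm(df, ModelSpec("rho_z", "lsas_c * gaze_code * coord_code"))
        a = raw.params["lsas:gaze_code:coord_code"]
        b = cen.params["lsas_c:gaze_code:coord_code"]
        assert a == pytest.approx(b, rel=1e-4)
        assert raw.params["Intercept"] != pytest.approx(cen.params["Intercept"], abs=1e-6)

    def test_questionnaire_exclusivity_enforced(self, rng):
        df = make_table(rng)
        df["aq"] = 1.0
        df["aq_c"] = 0.0
        df["lsas_c"] = df["lsas"]
        spec = ModelSpec("rho_z", "lsas_c * gaze_code + aq_c")
        with pytest.raises(ModelSpecError):
            fit_lmm(df, spec)


class TestSimpleSlopes:
    def test_zero_interaction_gives_equal_slopes(self, rng):
        df = make_table(rng, n=200, b_lsas_gaze=0.0)
        df, _ = center_predictors(df, ["lsas"])
        res = fit_lmm(df, ModelSpec("rho_z", "lsas_c + gaze_code"))
        with pytest.raises(ModelSpecError):
            simple_slopes(res, "lsas_c", "gaze_code")  # no interaction term
        res2 = fit_lmm(df, ModelSpec("rho_z", "lsas_c * gaze_code"))
        # interaction is estimated ~0: slopes nearly identical
        ss = simple_slopes(res2, "lsas_c", "gaze_code")
        inter = res2.params["lsas_c:gaze_code"]
        assert np.diff(ss["estimate"])[0] == pytest.approx(inter, abs=1e-10)

    def test_factor_moderator_matches_subset_refits(self, rng):
        df = make_table(rng, n=80, b_lsas_gaze=0.005)
        df, _ = center_predictors(df, ["lsas"])
        res = fit_lmm(df, ModelSpec("rho_z", "lsas_c * gaze_code"))
        ss = simple_slopes(res, "lsas_c", "gaze_code").set_index("moderator_value")
        for level in (0.0, 1.0):
            sub = df[df["gaze_code"] == level]
            sub_res = fit_lmm(sub, ModelSpec("rho_z", "lsas_c"))
            assert ss.loc[level, "estimate"] == pytest.approx(
                sub_res.params["lsas_c"], abs=1e-4)

    def test_continuous_moderator_default_levels(self, rng):
        df = make_table(rng, n=80, b_lsas_gaze=0.005)
        df, _ = center_predictors(df, ["lsas"])
        res = fit_lmm(df, ModelSpec("rho_z", "gaze_code * lsas_c"))
        ss = simple_slopes(res, "gaze_code", "lsas_c")
        assert list(ss["level"]) == ["low (M-SD)", "medium (M)", "high (M+SD)"]
        m, s = df["lsas_c"].mean(), df["lsas_c"].std()
        np.testing.assert_allclose(ss["moderator_value"], [m - s, m, m + s])

    def test_absent_moderator_is_spec_error(self, rng):
        df = make_table(rng)
        res = fit_lmm(df, ModelSpec("rho_z", "gaze_code * coord_code"))
        with pytest.raises(ModelSpecError):
            simple_slopes(res, "gaze_code", "lsas")


class TestPairwiseContrasts:
    def test_single_factor_contrast_equals_coefficient(self, rng):
        df = make_table(rng)
        res = fit_lmm(df, ModelSpec("rho_z", "gaze_code"))
        pc = pairwise_contrasts(res, ["gaze_code"])
        assert len(pc) == 1
        assert pc.loc[0, "estimate"] == pytest.approx(-res.params["gaze_code"], abs=1e-10)
        # k = 2: the studentised-range adjustment reduces to the plain t test
        assert pc.loc[0, "p_adjusted"] == pytest.approx(pc.loc[0, "p_unadjusted"],
                                                        abs=1e-6)

    def test_identical_cell_means_give_null_contrasts(self, rng):
        df = make_table(rng, b_gaze=0.0, b_coord=0.0, b_gc=0.0, tau=0.3, sigma=0.05)
        df["rho_z"] = 1.0 + (df["rho_z"] - df["rho_z"]) # exactly constant
        res = fit_lmm(df, ModelSpec("rho_z", "gaze_code * coord_code"))
        pc = pairwise_contrasts(res, ["gaze_code", "coord_code"])
        np.testing.assert_allclose(pc["estimate"], 0.0, atol=1e-8)

    def test_absent_factor_is_spec_error(self, rng):
        df = make_table(rng)
        res = fit_lmm(df, ModelSpec("rho_z", "gaze_code"))
        with pytest.raises(ModelSpecError):
            pairwise_contrasts(res, ["coord_code"])

    def test_familywise_error_controlled_under_null(self):
        rng = np.random.default_rng(99)
        n_rep, fwe = 300, 0
        for _ in range(n_rep):
            df = make_table(rng, n=20, b_gaze=0.0, b_coord=0.0, b_gc=0.0)
            res = fit_lmm(df, ModelSpec("rho_z", "gaze_code * coord_code"))
            pc = pairwise_contrasts(res, ["gaze_code", "coord_code"])
            if (pc["p_adjusted"] < 0.05).any():
                fwe += 1
        # nominal 5% family-wise rate, Monte-Carlo slack for 300 replicates
        assert fwe / n_rep <= 0.08
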