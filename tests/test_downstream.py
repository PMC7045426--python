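"""Validation battery: dichotomization, group tests, logistic fits, pooling."""

import numpy as np
import pandas as pd
import pytest

from scaleimpute import (
    CovariateSpec,
    MissingnessPlan,
    ampute,
    compare_analyses,
    dichotomize_score,
    fit_logistic,
    group_tests,
    impute_mi,
    logistic_on_dataset,
    pooled_logistic_mi,
)


class TestDichotomize:
    def test_boundary_is_high_class(self):
        assert dichotomize_score([30], 30)[0] == 1

    def test_below_cutoff(self):
        assert dichotomize_score([29], 30)[0] == 0

    def test_all_below_gives_all_zero(self):
        out = dichotomize_score([10, 15, 20], 30)
        assert (out == 0).all()


class TestGroupTests:
    def test_identical_groups_t_zero(self, tiny_scale):
        from scaleimpute import SurveyDataset

        items = pd.DataFrame(
            {"item_01": [1, 2, 3] * 2, "item_02": [2, 3, 4] * 2, "item_03": [1, 1, 1] * 2}
        )
        covs = pd.DataFrame(
            {"g": pd.Categorical(["a"] * 3 + ["b"] * 3, categories=["a", "b"])}
        )
        ds = SurveyDataset(ids=np.arange(6), items=items, covariates=covs, scale=tiny_scale)
        tbl = group_tests(ds, ["g"])
        assert tbl["statistic"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert not tbl["significant"].iloc[0]

    def test_pooled_t_hand_value(self, tiny_scale):
        """Totals {3+..} arranged so groups of totals are {1,2,3} vs {4,5,6}
        scaled into range; pooled t with df=4 equals -3.674 by hand."""
        from scaleimpute import SurveyDataset

        # item rows sum to totals 4,5,6 vs 7,8,9 == {1..3}+3 vs {4..6}+3;
        # the shift leaves t unchanged
        items = pd.DataFrame(
            {
                "item_01": [1, 1, 2, 2, 3, 3],
                "item_02": [2, 2, 2, 3, 3, 3],
                "item_03": [1, 2, 2, 2, 2, 3],
            }
        )
        covs = pd.DataFrame(
            {"g": pd.Categorical(["a"] * 3 + ["b"] * 3, categories=["a", "b"])}
        )
        ds = SurveyDataset(ids=np.arange(6), items=items, covariates=covs, scale=tiny_scale)
        tbl = group_tests(ds, ["g"])
        assert tbl["test"].iloc[0] == "t"
        assert tbl["statistic"].iloc[0] == pytest.approx(-3.674, abs=1e-3)

    def test_f_equals_t_squared_for_two_groups(self, rses_small):
        from scipy import stats as sps

        totals = rses_small.total_scores().to_numpy(dtype=float)
        gender = rses_small.covariates["gender"]
        tbl = group_tests(rses_small, ["gender"])
        t = tbl["statistic"].iloc[0]
        f, _ = sps.f_oneway(
            totals[(gender == "female").to_numpy()], totals[(gender == "male").to_numpy()]
        )
        assert f == pytest.approx(t**2, abs=1e-10)

    def test_multi_level_uses_f(self, rses_small):
        tbl = group_tests(rses_small, ["record"])
        assert (tbl["test"] == "F").all()
        assert len(tbl) == 4


class TestLogistic:
    @staticmethod
    def _from_2x2(n11, n10, n01, n00):
        """exposed events / exposed non-events / unexposed events / unexposed."""
        y = np.concatenate(
            [np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]
        )
        x = np.concatenate(
            [np.ones(n11 + n10), np.zeros(n01 + n00)]
        )
        return y, pd.DataFrame({"exposed": x})

    def test_closed_form_2x2_odds_ratio(self):
        y, X = self._from_2x2(10, 10, 5, 20)
        fit = fit_logistic(y, X)
        assert fit["or"].iloc[0] == pytest.approx(4.0, abs=1e-8)

    def test_random_2x2_tables_match_closed_form(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = rng.integers(5, 40, size=4)
            y, X = self._from_2x2(*n)
            fit = fit_logistic(y, X)
            expected = (n[0] * n[3]) / (n[1] * n[2])
            assert fit["or"].iloc[0] == pytest.approx(expected, rel=1e-8)

    def test_null_predictor_or_near_one(self):
        rng = np.random.default_rng(7)
        n = 100_000
        y = rng.integers(0, 2, size=n)
        X = pd.DataFrame({"noise": rng.integers(0, 2, size=n).astype(float)})
        fit = fit_logistic(y, X)
        assert abs(np.log(fit["or"].iloc[0])) < 0.05

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            fit_logistic(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))

    def test_separation_raises(self):
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        X = pd.DataFrame({"x": [0, 0, 0, 1, 1, 1.0]})
        with pytest.raises(RuntimeError):
            fit_logistic(y, X)

    def test_recovers_generating_signs(self, rses_preset):
        """Covariates generated with effects >= 0.3 trait SD must come out of
        the logistic model with log-ORs of the generating sign."""
        ds = rses_preset.generate(n=3500, seed=77)
        fit = logistic_on_dataset(
            ds, ["record", "communication"], rses_preset.covariates
        )
        # both effects are negative (worse record / rarer communication ->
        # lower self-esteem -> lower odds of total >= 30)
        assert (fit["coef"] < 0).all()


@pytest.fixture(scope="module")
def mi_fit(rses_preset):
    ds = rses_preset.generate(n=1200, seed=42)
    amp = ampute(
        ds,
        MissingnessPlan(
            mechanism="MAR", target_rate=0.2,
            driver_slopes=dict(rses_preset.mar_driver_slopes), seed=3,
        ),
        rses_preset.covariates,
    )
    completed = impute_mi(amp, rses_preset.covariates, m=5, n_iter=5, seed=11)
    preds = ["gender", "record", "communication"]
    pooled = pooled_logistic_mi(completed, preds, rses_preset.covariates)
    single = logistic_on_dataset(ds, preds, rses_preset.covariates)
    return completed, pooled, single


class TestPooledLogistic:
    def test_pooled_se_at_least_within_average(self, mi_fit, rses_preset):
        completed, pooled, _ = mi_fit
        preds = list(pooled["predictor"])
        per_fit = [
            logistic_on_dataset(d, preds, rses_preset.covariates)
            for d in completed.datasets
        ]
        for name in preds:
            within = np.mean(
                [
                    float(f.loc[f["predictor"] == name, "se"].iloc[0]) ** 2
                    for f in per_fit
                ]
            )
            se = float(pooled.loc[pooled["predictor"] == name, "se"].iloc[0])
            assert se**2 >= within - 1e-12

    def test_ci_brackets_or(self, mi_fit):
        _, pooled, _ = mi_fit
        assert (pooled["ci_low"] <= pooled["or"]).all()
        assert (pooled["or"] <= pooled["ci_high"]).all()

    def test_identical_imputations_degenerate_to_single_fit(self, rses_preset):
        from scaleimpute import CompletedData

        ds = rses_preset.generate(n=800, seed=42)
        completed = CompletedData(method="mi", datasets=[ds, ds, ds])
        preds = ["gender", "record"]
        pooled = pooled_logistic_mi(completed, preds, rses_preset.covariates)
        single = logistic_on_dataset(ds, preds, rses_preset.covariates)
        for name in preds:
            p = pooled.loc[pooled["predictor"] == name].iloc[0]
            s = single.loc[single["predictor"] == name].iloc[0]
            assert p["or"] == pytest.approx(s["or"], rel=1e-10)
            assert p["se"] == pytest.approx(s["se"], rel=1e-10)  # B = 0


class TestCompareAnalyses:
    def test_identical_arm_gives_zero_deltas(self, rses_small, rses_preset):
        groups = group_tests(rses_small, ["gender", "record"])
        logit = logistic_on_dataset(
            rses_small, ["gender", "record"], rses_preset.covariates
        )
        g, l = compare_analyses(
            groups, logit, {("hotdeck", 0.1): groups}, {("hotdeck", 0.1): logit}
        )
        assert np.allclose(g["delta_mean"], 0)
        assert np.allclose(g["delta_sd"], 0)
        assert np.allclose(l["delta_or"], 0)
        assert l["sign_agrees"].all()

    def test_hand_set_mean_delta(self, rses_small, rses_preset):
        groups = group_tests(rses_small, ["gender"])
        logit = logistic_on_dataset(rses_small, ["gender"], rses_preset.covariates)
        shifted = groups.copy()
        shifted["mean"] = shifted["mean"] + 0.04
        g, _ = compare_analyses(
            groups, logit, {("mi", 0.2): shifted}, {("mi", 0.2): logit}
        )
        assert np.allclose(g["delta_mean"], 0.04)

    def test_mismatched_covariates_rejected(self, rses_small, rses_preset):
        groups = group_tests(rses_small, ["gender", "record"])
        logit = logistic_on_dataset(rses_small, ["gender"], rses_preset.covariates)
        partial = group_tests(rses_small, ["gender"])
        with pytest.raises(ValueError):
            compare_analyses(groups, logit, {("mi", 0.1): partial}, {})
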