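"""Statistical operations against independent oracles and known limits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from qtsalvage import (
    CohortSimParams,
    cohen_kappa,
    fit_linear_log_lge,
    fit_logistic_msi,
    generate_cohort,
    paired_qtc_test,
    roc_youden,
    spearman,
    univariate_screen,
)
from qtsalvage.errors import (
    DegenerateTestError,
    InvalidParameterError,
    RankDeficiencyError,
    SeparationError,
    SingleClassError,
)


class TestPairedTest:
    def test_identical_arrays(self):
        r = paired_qtc_test([430.0, 450.0, 470.0], [430.0, 450.0, 470.0])
        assert r.t == 0.0 and r.p == 1.0

    def test_constant_nonzero_shift_degenerate(self):
        a = np.array([400.0, 420.0, 440.0])
        with pytest.raises(DegenerateTestError):
            paired_qtc_test(a, a + 25.0)

    def test_length_mismatch(self):
        with pytest.raises(InvalidParameterError):
            paired_qtc_test([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_power_at_programmed_shift(self, rng):
        # admission vs peak with a 70 ms mean shift, SD 40 ms, n = 50
        rejections = 0
        reps = 300
        for _ in range(reps):
            a = rng.normal(435.0, 39.0, 50)
            b = a + rng.normal(70.0, 40.0, 50)
            if paired_qtc_test(a, b).p < 0.05:
                rejections += 1
        assert rejections / reps > 0.99


class TestSpearman:
    def test_monotone_invariance(self, rng):
        x = rng.normal(size=50)
        r, _ = spearman(x, np.exp(x))
        assert r == pytest.approx(1.0)
        r2, _ = spearman(x, -x)
        assert r2 == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        x = np.array([3.1, 1.2, 4.5, 4.5, 2.0, 6.6, 0.3, 5.1])
        y = np.array([10.0, 4.0, 8.0, 12.0, 4.0, 15.0, 2.0, 9.0])
        r, _ = spearman(x, y)
        oracle = sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateTestError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestScreen:
    def test_candidate_equal_to_outcome_included(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=50)})
        df["x"] = df["y"]
        res = univariate_screen(df, "y", ["x"], model="linear")
        assert res.selected == ("x",)

    def test_empty_candidates(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=20)})
        assert univariate_screen(df, "y", [], model="linear").selected == ()

    def test_nonfinite_rows_dropped(self, rng):
        y = rng.normal(size=30)
        x = 2.0 * y + rng.normal(0, 0.1, 30)
        x[3] = np.nan
        df = pd.DataFrame({"y": y, "x": x})
        res = univariate_screen(df, "y", ["x"], model="linear")
        assert res.selected == ("x",) and res.n_dropped == 1

    def test_logistic_screen(self, rng):
        x = rng.normal(size=200)
        y = (x + rng.normal(0, 0.5, 200) > 0).astype(int)
        noise = rng.normal(size=200)
        df = pd.DataFrame({"y": y, "x": x, "z": noise})
        res = univariate_screen(df, "y", ["x", "z"], model="logistic")
        assert "x" in res.selected and "z" not in res.selected


class TestLinearModel:
    def test_noiseless_r2_is_one(self, rng):
        x = rng.normal(size=40)
        df = pd.DataFrame({"x": x, "lge_g": np.exp(1.0 + 0.5 * x)})
        m = fit_linear_log_lge(df, ["x"])
        assert m.r_squared == pytest.approx(1.0)
        assert m["x"]["estimate"] == pytest.approx(0.5, abs=1e-9)
        assert m.r_squared_adj <= m.r_squared

    def test_duplicated_column_rank_deficiency(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"x": x, "x2": x, "lge_g": np.exp(x)})
        with pytest.raises(RankDeficiencyError) as exc:
            fit_linear_log_lge(df, ["x", "x2"])
        assert set(exc.value.columns) & {"x", "x2"}

    def test_zero_lge_rows_dropped(self, rng):
        x = rng.normal(size=40)
        lge = np.exp(0.8 * x)
        lge[:5] = 0.0
        m = fit_linear_log_lge(pd.DataFrame({"x": x, "lge_g": lge}), ["x"])
        assert m.nobs == 35 and m.n_dropped == 5

    def test_ci_brackets_estimate(self, rng):
        x = rng.normal(size=60)
        df = pd.DataFrame({"x": x, "lge_g": np.exp(1 + 0.4 * x + rng.normal(0, 0.3, 60))})
        m = fit_linear_log_lge(df, ["x"])
        info = m["x"]
        assert info["ci"][0] <= info["estimate"] <= info["ci"][1]


class TestLogisticModel:
    def test_direction_on_programmed_cohort(self):
        df, _ = generate_cohort(CohortSimParams(n=200, seed=4))
        m = fit_logistic_msi(df, ["dqtc_ai_ma_day6"])
        # higher anterior-inferior dispersion -> higher odds of poor salvage
        assert m["dqtc_ai_ma_day6"]["estimate"] > 1.0
        assert m.outcome_coding == "event = MSI < 0.6"

    def test_single_class_rejected(self, rng):
        df = pd.DataFrame({"msi": np.full(30, 0.9), "x": rng.normal(size=30)})
        with pytest.raises(SingleClassError):
            fit_logistic_msi(df, ["x"])

    def test_complete_separation_flagged(self):
        n = 40
        x = np.arange(n, dtype=float)
        msi = np.where(x < n / 2, 0.9, 0.3)  # outcome perfectly separated by x
        with pytest.raises(SeparationError):
            fit_logistic_msi(pd.DataFrame({"msi": msi, "x": x}), ["x"])

    def test_null_covariate_ci_coverage(self, rng):
        covered = 0
        reps = 100
        for _ in range(reps):
            x = rng.normal(size=150)
            msi = rng.uniform(0.2, 1.0, 150)  # independent of x
            m = fit_logistic_msi(pd.DataFrame({"msi": msi, "x": x}), ["x"])
            lo, hi = m["x"]["ci"]
            covered += lo <= 1.0 <= hi
        assert covered / reps >= 0.88  # nominal 95% Wald coverage


class TestRocYouden:
    def test_perfect_separation(self):
        r = roc_youden([1.0, 2.0, 3.0, 10.0, 11.0, 12.0], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0 and r.youden_j == pytest.approx(1.0)
        assert r.sensitivity_at_cutoff == 1.0 and r.specificity_at_cutoff == 1.0

    def test_independent_score_auc_half(self, rng):
        scores = rng.normal(size=1000)
        y = rng.random(1000) < 0.4
        r = roc_youden(scores, y)
        assert abs(r.auc - 0.5) < 0.05

    def test_toy_set_matches_exhaustive_search(self):
        scores = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([0, 0, 1, 0, 1, 1])
        r = roc_youden(scores, y)
        best_j, best_t = -np.inf, None
        for t in np.unique(scores):
            sens = np.mean(scores[y == 1] >= t)
            spec = np.mean(scores[y == 0] < t)
            j = sens + spec - 1
            if j > best_j:
                best_j, best_t = j, t
        assert r.youden_j == pytest.approx(best_j)
        assert r.cutoff == best_t

    def test_auc_equals_rescaled_mann_whitney(self, rng):
        scores = np.round(rng.normal(size=200), 1)  # ties on purpose
        y = rng.random(200) < 0.5
        r = roc_youden(scores, y)
        u = sps.mannwhitneyu(scores[y], scores[~y]).statistic
        assert r.auc == pytest.approx(u / (y.sum() * (~y).sum()), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            roc_youden([1.0, 2.0], [1, 1])


class TestKappa:
    def test_identical_ratings(self):
        assert cohen_kappa([1, 2, 3, 1], [1, 2, 3, 1]) == pytest.approx(1.0)

    def test_independence_pattern_zero(self):
        assert cohen_kappa(["+", "+", "-", "-"], ["+", "-", "+", "-"]) == pytest.approx(0.0)

    def test_random_independent_near_zero(self, rng):
        a = rng.integers(0, 2, 5000)
        b = rng.integers(0, 2, 5000)
        assert abs(cohen_kappa(a, b)) < 0.05

    def test_single_shared_category_undefined(self):
        with pytest.raises(DegenerateTestError):
            cohen_kappa([1, 1, 1], [1, 1, 1])

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.integers(0, 3, 200)
        b = np.where(rng.random(200) < 0.7, a, rng.integers(0, 3, 200))
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)
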