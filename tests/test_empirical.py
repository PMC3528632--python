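"""Subject-level estimators: logistic ML fit, concordance, moments, predictions."""

import math
import warnings

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from cstat.empirical import (
    SeparationWarning,
    SubjectData,
    concordance,
    empirical_c_of_model,
    evaluate_dataset,
    fit_logistic,
    group_moments,
    predicted_c_formula1,
    predicted_c_formula2,
    read_subject_csv,
    sample_skewness,
)

from conftest import brute_force_concordance


def _statsmodels_fit(x, y):
    res = sm.Logit(np.asarray(y, float), sm.add_constant(np.asarray(x, float))).fit(
        disp=0, method="newton", tol=1e-12
    )
    return res.params  # (intercept, slope)


class TestSubjectData:
    def test_validates_shapes_and_labels(self):
        with pytest.raises(ValueError, match="equal length"):
            SubjectData([1, 2, 3], [0, 1])
        with pytest.raises(ValueError, match="only 0 and 1"):
            SubjectData([1, 2], [0, 2])
        with pytest.raises(ValueError, match="at least 2"):
            SubjectData([1], [0])
        with pytest.raises(ValueError, match="non-finite"):
            SubjectData([1, math.nan], [0, 1])

    def test_counts(self):
        d = SubjectData([1, 2, 3], [0, 1, 1])
        assert d.n == 3 and d.n_affected == 2


class TestFitLogistic:
    def test_balanced_independent_outcome_gives_null_fit(self):
        fit = fit_logistic(SubjectData([-1, -1, 1, 1], [0, 1, 0, 1]))
        assert fit.converged
        assert fit.slope == pytest.approx(0.0, abs=1e-8)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)

    def test_matches_independent_ml_oracle_on_fixture(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [0, 0, 1, 0, 1, 1]
        fit = fit_logistic(SubjectData(x, y))
        b0, b1 = _statsmodels_fit(x, y)
        assert fit.converged and not fit.separation_detected
        assert fit.intercept == pytest.approx(b0, abs=1e-6)
        assert fit.slope == pytest.approx(b1, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_oracle_on_random_datasets(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        x = rng.normal(0, 1.5, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(int)
        fit = fit_logistic(SubjectData(x, y))
        b0, b1 = _statsmodels_fit(x, y)
        assert fit.intercept == pytest.approx(b0, abs=1e-6)
        assert fit.slope == pytest.approx(b1, abs=1e-6)

    def test_two_point_separation_flagged(self):
        with pytest.warns(SeparationWarning):
            fit = fit_logistic(SubjectData([0, 1], [0, 1]))
        assert fit.separation_detected

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(SubjectData([1, 2, 3], [1, 1, 1]))
        with pytest.raises(ValueError, match="constant covariate"):
            fit_logistic(SubjectData([2, 2, 2, 2], [0, 1, 0, 1]))

    def test_slope_recovers_discriminant_identity_at_large_n(self):
        """Binormal equal-variance data with (muA-muU)/sigma^2 = beta yields slope -> beta."""
        rng = np.random.default_rng(7)
        n = 100_000
        beta_true = 1.0
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-beta_true * x))).astype(int)
        fit = fit_logistic(SubjectData(x, y))
        # SE from the inverse observed information at the estimate
        p = fit.predict_proba(x)
        X = np.column_stack([np.ones(n), x])
        cov = np.linalg.inv((X * (p * (1 - p))[:, None]).T @ X)
        se = math.sqrt(cov[1, 1])
        assert abs(fit.slope - beta_true) < 3 * se


class TestConcordance:
    @pytest.mark.parametrize(
        ("y", "scores", "expected"),
        [
            ((0, 1), (0.2, 0.8), 1.0),
            ((0, 1), (0.5, 0.5), 0.5),
            ((0, 0, 1, 1), (1, 3, 2, 4), 0.75),
        ],
    )
    def test_small_cases(self, y, scores, expected):
        assert concordance(SubjectData(range(len(y)), y), scores) == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        y = np.zeros(n, dtype=int)
        y[: int(rng.integers(1, n))] = 1
        rng.shuffle(y)
        # coarse integer scores force plenty of ties
        scores = rng.integers(0, 6, n).astype(float)
        d = SubjectData(rng.normal(size=n), y)
        assert concordance(d, scores) == brute_force_concordance(y, scores)

    @given(st.integers(0, 2**31 - 1))
    def test_complement_under_score_negation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        y = np.r_[1, 0, (rng.random(n - 2) < 0.5).astype(int)]
        scores = rng.integers(0, 8, n).astype(float)
        d = SubjectData(rng.normal(size=n), y)
        assert concordance(d, scores) + concordance(d, -scores) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        n = 60
        y = np.r_[np.ones(20, int), np.zeros(40, int)]
        scores = rng.normal(size=n)
        d = SubjectData(rng.normal(size=n), y)
        base = concordance(d, scores)
        assert concordance(d, np.exp(scores)) == pytest.approx(base, abs=1e-15)
        assert concordance(d, 3 * scores - 11) == pytest.approx(base, abs=1e-15)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            concordance(SubjectData([1, 2], [1, 1]), [0.1, 0.2])


class TestEmpiricalCOfModel:
    def test_perfectly_ordered_data(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparationWarning)
            c, fit = empirical_c_of_model(SubjectData([1, 2, 3, 4], [0, 0, 1, 1]))
        assert c == 1.0

    def test_null_fit_gives_half(self):
        c, fit = empirical_c_of_model(SubjectData([-1, -1, 1, 1], [0, 1, 0, 1]))
        assert c == pytest.approx(0.5)

    def test_equals_concordance_on_x_when_slope_positive(self, rng):
        n = 300
        x = rng.normal(0, 2, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-0.8 * x))).astype(int)
        d = SubjectData(x, y)
        c, fit = empirical_c_of_model(d)
        assert fit.slope > 0
        assert c == pytest.approx(concordance(d, x), abs=1e-15)


class TestGroupMoments:
    def test_hand_computed_example(self):
        m = group_moments(SubjectData([0, 2, 1, 3], [0, 0, 1, 1]))
        assert m.mean_unaffected == 1.0 and m.mean_affected == 2.0
        assert m.var_unaffected == pytest.approx(2.0)
        assert m.var_affected == pytest.approx(2.0)
        assert m.n_affected == 2 and m.n_unaffected == 2
        # groups of size 2: variance defined, skewness not
        assert math.isnan(m.skew_affected) and math.isnan(m.skew_unaffected)
        assert m.var_combined == pytest.approx(np.var([0, 2, 1, 3], ddof=1))

    def test_symmetric_group_has_zero_skewness(self):
        m = group_moments(SubjectData([-2, -1, 0, 1, 2, 5, 6, 7], [1, 1, 1, 1, 1, 0, 0, 0]))
        assert m.skew_affected == pytest.approx(0.0, abs=1e-12)

    def test_skewness_matches_reference_convention(self):
        # frozen from R e1071::skewness (default) and (type = 1)
        v = np.array([1.0, 2, 2, 3, 7])
        assert sample_skewness(v, "b1") == pytest.approx(0.8372974, abs=1e-6)
        assert sample_skewness(v, "g1") == pytest.approx(1.170159, abs=1e-6)

    def test_gamma_skewness_at_large_n(self, rng):
        k = 4.0
        n = 100_000
        x = np.r_[rng.gamma(k, 1.0, n), rng.normal(10, 1, 10)]
        y = np.r_[np.ones(n, int), np.zeros(10, int)]
        m = group_moments(SubjectData(x, y))
        # analytic gamma skewness 2/sqrt(k) = 1; sampling SE of skewness ~ sqrt(15/n)
        assert m.skew_affected == pytest.approx(2 / math.sqrt(k), abs=3 * math.sqrt(15 / n) * 3)

    def test_undersized_group_yields_missing_moments(self):
        m = group_moments(SubjectData([1.0, 4.0, 5.0], [1, 0, 0]))
        assert math.isnan(m.var_affected)
        assert math.isnan(m.skew_affected)


class TestPredictedCFromData:
    def test_formula1_hand_example(self):
        c = predicted_c_formula1(SubjectData([0, 2, 1, 3], [0, 0, 1, 1]))
        assert c == pytest.approx(0.6914624612740131, abs=1e-12)  # Phi(0.5), frozen oracle

    def test_formula1_equal_group_means_gives_half(self):
        c = predicted_c_formula1(SubjectData([0, 2, 0, 2], [0, 0, 1, 1]))
        assert c == pytest.approx(0.5)

    def test_formula1_requires_group_variances(self):
        with pytest.raises(ValueError, match="group variance"):
            predicted_c_formula1(SubjectData([1.0, 4.0, 5.0], [1, 0, 0]))

    def test_formula2_null_slope_gives_half(self):
        c = predicted_c_formula2(SubjectData([-1, -1, 1, 1], [0, 1, 0, 1]))
        assert c == pytest.approx(0.5, abs=1e-8)

    def test_formulas_agree_on_large_equal_variance_sample(self, rng):
        """At a modest effect the two formulas coincide; combined-sample
        variance exceeds the within-group variance only at second order in
        the mean separation, so the agreement degrades as beta grows."""
        n = 50_000
        sigma, beta = 1.0, 0.5
        x = rng.normal(0, sigma, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-beta * x))).astype(int)
        d = SubjectData(x, y)
        f1 = predicted_c_formula1(d)
        f2 = predicted_c_formula2(d)
        assert f1 == pytest.approx(f2, abs=0.01)

    def test_prevalence_leaves_empirical_c_unchanged(self, rng):
        """Shifting beta0 changes prevalence but not discrimination, within MC error."""
        sigma, beta1, n, reps = 1.0, math.log(2), 1000, 60
        means = {}
        for beta0 in (-1.5, 0.0, 1.5):
            cs = []
            for _ in range(reps):
                x = rng.normal(0, sigma, n)
                y = (rng.random(n) < 1 / (1 + np.exp(-(beta0 + beta1 * x)))).astype(int)
                if 3 <= y.sum() <= n - 3:
                    c, _ = empirical_c_of_model(SubjectData(x, y))
                    cs.append(c)
            means[beta0] = (np.mean(cs), np.std(cs, ddof=1) / math.sqrt(len(cs)))
        (m_lo, se_lo), (m_mid, se_mid), (m_hi, se_hi) = means.values()
        assert abs(m_lo - m_hi) < 3 * math.hypot(se_lo, se_hi)
        assert abs(m_lo - m_mid) < 3 * math.hypot(se_lo, se_mid)


class TestCsvInterface:
    def test_round_trip_and_report(self, tmp_path, rng):
        import pandas as pd

        n = 400
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
        path = tmp_path / "subjects.csv"
        pd.DataFrame({"x": x, "y": y}).to_csv(path, index=False)
        data = read_subject_csv(path)
        report = evaluate_dataset(data)
        assert report["n"] == n
        assert report["n_affected"] == int(y.sum())
        assert 0 < report["c_empirical"] < 1
        assert report["c_formula1"] == pytest.approx(predicted_c_formula1(data))
        # d and the binormal prediction satisfy c = Phi(d/sqrt 2)
        assert report["c_formula1"] == pytest.approx(
            norm.cdf(report["d"] / math.sqrt(2)), abs=1e-12
        )

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,0\n")
        with pytest.raises(ValueError, match="required column"):
            read_subject_csv(path)
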