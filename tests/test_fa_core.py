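"""Unit and property tests for the single-factor ML core."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from unifyexpr import fa_core
from unifyexpr.fa_core import (
    FactorModel,
    conditional_expectation_scores,
    correlation_matrix,
    fit_correlation,
    fit_em,
    fix_sign,
    loglik,
    standardize,
    thomson_scores,
)
from unifyexpr.simulator import simulate_from_loadings


def make_model(lam, n=200):
    lam = np.asarray(lam, dtype=float)
    return FactorModel(
        loadings=lam,
        uniquenesses=1.0 - lam**2,
        loglik=0.0,
        n_iter=0,
        converged=True,
        heywood=np.zeros(lam.size, dtype=bool),
        p=lam.size,
        n=n,
    )


class TestStandardize:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([1.0, 2.0, 3.0], [-1.0, 0.0, 1.0]),
            ([0.0, 4.0], [-0.7071067811865476, 0.7071067811865476]),
        ],
    )
    def test_known_rows(self, row, expected):
        out = standardize(np.array([row]))
        np.testing.assert_allclose(out.values[0], expected, atol=1e-12)

    def test_zero_variance_rejected_by_name(self):
        with pytest.raises(ValueError, match="zero variance.*'flat'"):
            standardize(np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]), ["ok", "flat"])

    def test_missing_value_rejected(self):
        with pytest.raises(ValueError, match="missing or non-finite"):
            standardize(np.array([[1.0, np.nan, 3.0]]))

    @given(
        st.lists(
            st.lists(st.floats(-50, 50), min_size=5, max_size=5),
            min_size=1,
            max_size=4,
        )
    )
    def test_rows_have_zero_mean_unit_variance(self, rows):
        x = np.asarray(rows)
        if np.any(x.std(axis=1, ddof=1) == 0):
            return
        out = standardize(x)
        np.testing.assert_allclose(out.values.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.values.var(axis=1, ddof=1), 1.0, atol=1e-8)


class TestFit:
    def test_null_data_implied_correlations_shrink(self, direct_ml):
        # Under the null the ML fit can still place a large loading on one
        # coordinate (the p=3 triad formula amplifies a small denominator
        # correlation — the root of Heywood cases in weak genes), but the
        # implied cross-correlations lambda_j*lambda_k stay O(1/sqrt(n)).
        for seed in range(5):
            rng = np.random.default_rng(seed)
            data = standardize(rng.standard_normal((4, 200)))
            model = fit_em(data)
            implied = model.implied_correlation()
            off = np.abs(implied[~np.eye(4, dtype=bool)])
            assert np.all(off < 4.0 / np.sqrt(200))
            lam_oracle = direct_ml(correlation_matrix(data))
            assert np.max(np.abs(model.loadings - lam_oracle)) < 1e-3

    def test_triad_closed_form(self):
        # p=3 is just-identified: lambda_1 = sqrt(r12*r13/r23) etc.
        R = np.array([[1.0, 0.72, 0.63], [0.72, 1.0, 0.56], [0.63, 0.56, 1.0]])
        model = fit_correlation(R, 200)
        np.testing.assert_allclose(model.loadings, [0.9, 0.8, 0.7], atol=1e-4)
        np.testing.assert_allclose(model.implied_correlation(), R, atol=1e-6)

    def test_heywood_triad_flagged(self, direct_ml):
        # triad formula gives lambda_1^2 = 0.81/0.5 > 1: improper solution.
        R = np.array([[1.0, 0.90, 0.90], [0.90, 1.0, 0.50], [0.90, 0.50, 1.0]])
        model = fit_correlation(R, 200)
        assert model.heywood[0] and not model.heywood[1:].any()
        # the direct optimizer also runs into its loading bound there
        lam = direct_ml(R)
        assert lam[0] > 0.99

    def test_n_not_greater_than_p_rejected(self):
        rng = np.random.default_rng(1)
        data = standardize(rng.standard_normal((5, 5)))
        with pytest.raises(ValueError, match="n > p"):
            fit_em(data)

    def test_em_trace_monotone(self, strong_factor_data):
        data, _ = strong_factor_data
        model = fit_em(data)
        assert model.converged
        assert np.all(np.diff(model.loglik_trace) > -1e-9)

    def test_unit_diagonal_conserved(self):
        rng = np.random.default_rng(2)
        for lam_true in ([0.9, 0.8, 0.7], [0.5, 0.4, 0.6, 0.3], [0.2, 0.1, 0.15]):
            y, _ = simulate_from_loadings(lam_true, 200, rng)
            model = fit_em(standardize(y))
            np.testing.assert_allclose(
                model.loadings**2 + model.uniquenesses, 1.0, atol=1e-8
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_likelihood_optimizer(self, seed, direct_ml):
        rng = np.random.default_rng(100 + seed)
        p = 3 + seed % 3
        y, _ = simulate_from_loadings(rng.uniform(0.3, 0.95, p), 200, rng)
        data = standardize(y)
        model = fit_em(data)
        lam_oracle = direct_ml(correlation_matrix(data))
        assert np.max(np.abs(model.loadings - lam_oracle)) < 1e-3

    def test_loadings_order_matches_score_correlations(self):
        # correlation interpretation of the loadings at large n
        rng = np.random.default_rng(3)
        y, _ = simulate_from_loadings([0.9, 0.6, 0.3], 10_000, rng)
        data = standardize(y)
        model = fit_em(data)
        scores = thomson_scores(model, data).scores
        cors = [np.corrcoef(scores, data.values[j])[0, 1] for j in range(3)]
        assert list(np.argsort(model.loadings)) == list(np.argsort(cors))


class TestLoglik:
    def test_sign_invariance(self, strong_factor_data):
        data, _ = strong_factor_data
        model = fit_em(data)
        flipped = make_model(-model.loadings, n=data.n)
        assert loglik(model, data) == pytest.approx(loglik(flipped, data), abs=1e-9)

    def test_null_model_is_iid_normal_density(self):
        rng = np.random.default_rng(4)
        data = standardize(rng.standard_normal((3, 50)))
        model = make_model([0.0, 0.0, 0.0], n=50)
        expected = stats.norm.logpdf(data.values).sum()
        assert loglik(model, data) == pytest.approx(expected, rel=1e-12)

    def test_matches_multivariate_normal_density(self):
        rng = np.random.default_rng(5)
        y, _ = simulate_from_loadings([0.8, 0.7, 0.5, 0.4], 40, rng)
        data = standardize(y)
        model = make_model([0.75, 0.6, 0.5, 0.3], n=40)
        direct = stats.multivariate_normal(
            mean=np.zeros(4), cov=model.implied_correlation()
        ).logpdf(data.values.T).sum()
        assert loglik(model, data) == pytest.approx(direct, rel=1e-10)

    def test_singular_sigma_rejected(self, strong_factor_data):
        data, _ = strong_factor_data
        lam = np.array([1.0, 0.5, 0.5])
        bad = FactorModel(lam, 1 - lam**2, 0.0, 0, True, np.zeros(3, bool), 3, data.n)
        with pytest.raises(ValueError, match="singular"):
            loglik(bad, data)


class TestThomson:
    def test_zero_observation_gives_zero_score(self):
        model = make_model([0.9, 0.8, 0.7])
        data = fa_core.StandardizedVectorSet(
            np.zeros((3, 4)), ("a", "b", "c"), ("", "", "")
        )
        np.testing.assert_array_equal(thomson_scores(model, data).scores, 0.0)

    def test_closed_form_p2(self):
        # Sigma = [[1, .64], [.64, 1]], y=(1,1): score = 2*0.8/(1+0.64)
        model = make_model([0.8, 0.8])
        data = fa_core.StandardizedVectorSet(np.ones((2, 1)), ("a", "b"), ("", ""))
        assert thomson_scores(model, data).scores[0] == pytest.approx(1.6 / 1.64, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_small_matrix_form_equals_conditional_expectation(self, seed):
        rng = np.random.default_rng(200 + seed)
        p = rng.integers(2, 8)
        lam = rng.uniform(-0.95, 0.95, p)
        model = make_model(lam)
        data = fa_core.StandardizedVectorSet(
            rng.standard_normal((p, 10)), tuple(map(str, range(p))), ("",) * p
        )
        np.testing.assert_allclose(
            thomson_scores(model, data).scores,
            conditional_expectation_scores(model, data),
            atol=1e-10,
        )

    def test_weight_monotone_in_loading(self):
        # raising one loading (others fixed) raises that platform's weight
        weights = []
        for lam3 in (0.1, 0.3, 0.5, 0.7, 0.9):
            model = make_model([0.8, 0.6, lam3])
            a = model.loadings / model.uniquenesses
            weights.append((a / (1 + model.loadings @ a))[2])
        assert np.all(np.diff(weights) > 0)

    def test_scale_invariance_of_scores(self):
        rng = np.random.default_rng(6)
        raw, _ = simulate_from_loadings([0.9, 0.8, 0.7], 150, rng)
        scaled = raw * np.array([[3.7], [0.01], [250.0]])
        d1, d2 = standardize(raw), standardize(scaled)
        m1, m2 = fit_em(d1), fit_em(d2)
        np.testing.assert_allclose(
            thomson_scores(m1, d1).scores, thomson_scores(m2, d2).scores, atol=1e-10
        )


class TestFixSign:
    @pytest.mark.parametrize(
        "lam, expected",
        [
            ([-0.9, -0.8, -0.7], [0.9, 0.8, 0.7]),
            ([0.9, 0.8, 0.7], [0.9, 0.8, 0.7]),
            ([0.5, -0.5, 0.0], [0.5, -0.5, 0.0]),  # sum 0, first loading positive
            ([-0.5, 0.5, 0.0], [0.5, -0.5, 0.0]),  # sum 0, tie-break flips
        ],
    )
    def test_convention(self, lam, expected):
        model = fix_sign(make_model(lam))
        np.testing.assert_allclose(model.loadings, expected)

    def test_scores_flip_with_model(self):
        model = make_model([-0.9, -0.8, -0.7])
        scores = fa_core.FactorScores(np.array([1.0, -2.0]), np.array([0.2, 0.3, 0.1]))
        fixed, flipped = fix_sign(model, scores)
        np.testing.assert_allclose(fixed.loadings, [0.9, 0.8, 0.7])
        np.testing.assert_allclose(flipped.scores, [-1.0, 2.0])
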