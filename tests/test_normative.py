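"""Warped Bayesian linear regression normative model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from striatnorm import normative as nm
from striatnorm import synthetic as syn


def cox_de_boor(i, k, x, t):
    """Naive Cox-de Boor recursion for B-spline basis function i of degree k."""
    if k == 0:
        return 1.0 if t[i] <= x < t[i + 1] else 0.0
    d1 = t[i + k] - t[i]
    d2 = t[i + k + 1] - t[i + 1]
    left = 0.0 if d1 == 0 else (x - t[i]) / d1 * cox_de_boor(i, k - 1, x, t)
    right = 0.0 if d2 == 0 else (t[i + k + 1] - x) / d2 * cox_de_boor(i + 1, k - 1, x, t)
    return left + right


class TestBasis:
    def test_partition_of_unity(self):
        basis = nm.BasisSpec().with_range(np.array([20.0, 81.0]))
        ages = np.linspace(20, 81, 200)
        Phi = nm.design_matrix(ages, basis)
        np.testing.assert_allclose(Phi[:, :-1].sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(Phi[:, -1], 1.0)
        assert Phi.shape == (200, basis.n_spline + 1)

    def test_matches_cox_de_boor_recursion_oracle(self):
        basis = nm.BasisSpec().with_range(np.array([20.0, 81.0]))
        t = basis.knots
        # interior points and every knot except the right boundary
        xs = np.concatenate([np.linspace(20.01, 80.99, 37), t[4:-5]])
        Phi = nm.design_matrix(xs, basis)
        for j, x in enumerate(xs):
            expected = [cox_de_boor(i, 3, x, t) for i in range(basis.n_spline)]
            np.testing.assert_allclose(Phi[j, :-1], expected, atol=1e-12)

    def test_right_boundary_is_last_basis_function(self):
        basis = nm.BasisSpec().with_range(np.array([20.0, 81.0]))
        Phi = nm.design_matrix(np.array([81.0]), basis)
        np.testing.assert_allclose(Phi[0, :-1], np.eye(basis.n_spline)[-1], atol=1e-12)

    def test_repeated_age_gives_identical_rows(self):
        basis = nm.BasisSpec().with_range(np.array([20.0, 81.0]))
        Phi = nm.design_matrix(np.array([47.3, 47.3]), basis)
        np.testing.assert_array_equal(Phi[0], Phi[1])

    def test_out_of_range_ages_clamped_with_warning(self):
        basis = nm.BasisSpec().with_range(np.array([30.0, 70.0]))
        with pytest.warns(UserWarning, match="clamped"):
            Phi = nm.design_matrix(np.array([20.0, 80.0]), basis)
        Phi_edge = nm.design_matrix(np.array([30.0, 70.0]), basis)
        np.testing.assert_allclose(Phi, Phi_edge, atol=1e-12)

    def test_fewer_than_two_distinct_ages_rejected(self):
        with pytest.raises(ValueError, match="distinct ages"):
            nm.BasisSpec().with_range(np.array([50.0, 50.0]))


class TestWarp:
    def test_identity_parameters(self):
        y = np.linspace(-5, 5, 11)
        p = nm.WarpParams(0.0, 1.0)
        np.testing.assert_allclose(nm.warp(y, p), y, atol=1e-14)
        np.testing.assert_allclose(nm.warp_deriv(y, p), 1.0, atol=1e-14)

    @pytest.mark.parametrize("a,b", [(0.5, 0.8), (-1.0, 2.0)])
    def test_round_trip_bijectivity(self, a, b):
        y = np.linspace(-10, 10, 401)
        p = nm.WarpParams(a, b)
        np.testing.assert_allclose(nm.warp_inverse(nm.warp(y, p), p), y, atol=1e-12)
        np.testing.assert_allclose(nm.warp(nm.warp_inverse(y, p), p), y, atol=1e-12)

    def test_closed_form_value(self):
        # z = sinh(1*arcsinh(0) - 1) = sinh(-1)
        assert nm.warp(0.0, nm.WarpParams(1.0, 1.0)) == pytest.approx(
            -np.sinh(1.0), abs=1e-12
        )
        assert float(nm.warp(0.0, nm.WarpParams(1.0, 1.0))) == pytest.approx(-1.1752, abs=1e-4)

    @pytest.mark.parametrize("a,b", [(0.0, 1.0), (0.7, 1.4), (-0.5, 0.6)])
    def test_derivative_positive_and_matches_numeric(self, a, b):
        y = np.linspace(-4, 4, 81)
        p = nm.WarpParams(a, b)
        d = nm.warp_deriv(y, p)
        assert (d > 0).all()
        h = 1e-6
        num = (nm.warp(y + h, p) - nm.warp(y - h, p)) / (2 * h)
        np.testing.assert_allclose(d, num, rtol=1e-6)

    def test_nonpositive_tail_rejected(self):
        with pytest.raises(ValueError, match="b must be > 0"):
            nm.WarpParams(0.0, 0.0)


class TestFit:
    def test_posterior_mean_equals_ridge_oracle(self, rng):
        """Closed-form BLR posterior == ridge regression with penalty alpha/beta."""
        ages = rng.uniform(20, 80, 60)
        y = 1.3 - 0.004 * (ages - 50) + 0.05 * rng.standard_normal(60)
        alpha, beta = 0.7, 120.0
        model = nm.fit_fixed(ages, y, alpha=alpha, beta=beta)
        Phi = nm.design_matrix(ages, model.basis)
        ridge = np.linalg.solve(
            Phi.T @ Phi + (alpha / beta) * np.eye(Phi.shape[1]), Phi.T @ y
        )
        np.testing.assert_allclose(model.m_w, ridge, atol=1e-10)
        # independent implementation of the same estimator
        from sklearn.linear_model import Ridge

        sk = Ridge(alpha=alpha / beta, fit_intercept=False).fit(Phi, y)
        np.testing.assert_allclose(model.m_w, sk.coef_, atol=1e-8)

    def test_vanishing_prior_recovers_least_squares_fit(self, rng):
        ages = rng.uniform(20, 80, 80)
        y = 1.2 - 0.003 * (ages - 50) + 0.04 * rng.standard_normal(80)
        model = nm.fit_fixed(ages, y, alpha=1e-10, beta=100.0)
        Phi = nm.design_matrix(ages, model.basis)
        fitted_ls = Phi @ np.linalg.lstsq(Phi, y, rcond=None)[0]
        np.testing.assert_allclose(Phi @ model.m_w, fitted_ls, atol=1e-6)

    def test_noiseless_linear_data_interpolated(self, rng):
        ages = rng.uniform(20, 80, 50)
        y = 0.01 * ages + 0.5  # cubic splines reproduce linear functions exactly
        model = nm.fit_fixed(ages, y, alpha=1e-10, beta=1e6)
        m_star, _ = nm.predict(model, ages)
        np.testing.assert_allclose(m_star, y, atol=1e-6)

    def test_posterior_covariance_spd_and_precisions_positive(self, roi_table):
        tr = roi_table.iloc[:60]
        model = nm.fit(tr.age.to_numpy(), tr.caudate_L.to_numpy(), seed=0)
        eig = np.linalg.eigvalsh(model.S_w)
        assert (eig > 0).all()
        assert model.alpha > 0 and model.beta > 0

    def test_optimized_evidence_not_worse_than_identity_init(self, roi_table):
        ages = roi_table.age.to_numpy()
        y = roi_table.caudate_L.to_numpy()
        model = nm.fit(ages, y, seed=0)
        basis = nm.BasisSpec().with_range(ages)
        beta0 = 1.0 / np.var(y)
        init_nlml = nm.nlml(ages, y, basis, 1e-2, beta0, nm.WarpParams())
        assert model.nlml <= init_nlml + 1e-9

    def test_warp_parameter_recovery_from_model_truth(self):
        """(a, b) recovered within +/-0.1 from n=4000 well-specified draws."""
        rng = np.random.default_rng(7)
        truth = nm.WarpParams(a=0.8, b=1.3)
        ages = rng.uniform(20, 80, 4000)
        z = 1.5 * (ages - 50) / 30 + 0.5 * rng.standard_normal(4000)
        y = nm.warp_inverse(z, truth)
        model = nm.fit(ages, y, seed=1)
        assert model.warp.a == pytest.approx(truth.a, abs=0.1)
        assert model.warp.b == pytest.approx(truth.b, abs=0.1)

    def test_too_few_observations_rejected(self, rng):
        ages = rng.uniform(20, 80, 8)
        with pytest.raises(ValueError, match="observations"):
            nm.fit(ages, np.ones(8) + rng.standard_normal(8))


class TestPredictAndCentiles:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(3)
        wp = nm.WarpParams(0.3, 1.1)
        ages = rng.uniform(20, 80, 2000)
        z = 1.0 - 0.02 * (ages - 50) + 0.4 * rng.standard_normal(2000)
        y = nm.warp_inverse(z, wp)
        model = nm.fit(ages, y, seed=2)
        return model, wp, ages, y

    def test_predictive_variance_floor(self, fitted):
        model = fitted[0]
        _, s = nm.predict(model, np.linspace(20, 80, 61))
        assert (s**2 >= 1.0 / model.beta - 1e-12).all()

    def test_large_n_predictive_sd_approaches_noise_floor(self, fitted):
        model = fitted[0]
        _, s = nm.predict(model, np.array([50.0]))
        assert s[0] ** 2 == pytest.approx(1.0 / model.beta, rel=0.02)

    def test_median_centile_is_backtransformed_mean(self, fitted):
        model = fitted[0]
        ages = np.linspace(25, 75, 11)
        m_star, _ = nm.predict(model, ages)
        curves = nm.centiles(model, ages, quantiles=(0.5,))
        np.testing.assert_allclose(curves[0.5], nm.warp_inverse(m_star, model.warp),
                                   atol=1e-12)

    def test_centiles_monotone_in_quantile(self, fitted):
        model = fitted[0]
        ages = np.linspace(20, 80, 61)
        curves = nm.centiles(model, ages)
        qs = sorted(curves)
        for lo, hi in zip(qs[:-1], qs[1:]):
            assert (curves[hi] > curves[lo]).all()

    def test_identity_warp_centiles_symmetric(self, rng):
        ages = rng.uniform(20, 80, 200)
        y = 1.0 + 0.01 * ages + 0.1 * rng.standard_normal(200)
        model = nm.fit_fixed(ages, y, alpha=1e-3, beta=100.0)
        ages_eval = np.linspace(25, 75, 5)
        m_star, _ = nm.predict(model, ages_eval)
        curves = nm.centiles(model, ages_eval, quantiles=(0.05, 0.95))
        np.testing.assert_allclose(
            curves[0.95] - m_star, m_star - curves[0.05], atol=1e-10
        )

    def test_invalid_quantiles_rejected(self, fitted):
        with pytest.raises(ValueError, match="quantiles"):
            nm.centiles(fitted[0], np.array([50.0]), quantiles=(0.0, 0.5))

    def test_empirical_coverage_of_75th_centile(self, fitted):
        model, wp, *_ = fitted
        rng = np.random.default_rng(11)
        ages = rng.uniform(20, 80, 20000)
        z = 1.0 - 0.02 * (ages - 50) + 0.4 * rng.standard_normal(20000)
        y = nm.warp_inverse(z, wp)
        curve = nm.centiles(model, ages, quantiles=(0.75,))[0.75]
        frac = float(np.mean(y < curve))
        assert frac == pytest.approx(0.75, abs=0.02)


class TestZScores:
    def test_point_on_median_curve_scores_zero(self, roi_table):
        tr = roi_table.iloc[:60]
        model = nm.fit(tr.age.to_numpy(), tr.caudate_L.to_numpy(), seed=0)
        ages = np.array([40.0, 60.0])
        m_star, _ = nm.predict(model, ages)
        y = nm.warp_inverse(m_star, model.warp)
        rep = nm.zscores(model, ages, y)
        np.testing.assert_allclose(rep.z, 0.0, atol=1e-10)

    def test_exactly_two_sigma_not_flagged(self, roi_table):
        """Z == 2 exactly is not an extreme deviation: the flag is strict."""
        tr = roi_table.iloc[:60]
        model = nm.fit(tr.age.to_numpy(), tr.caudate_L.to_numpy(), seed=0)
        ages = np.array([50.0])
        m_star, s_star = nm.predict(model, ages)
        y = nm.warp_inverse(m_star + 2.0 * s_star, model.warp)
        rep = nm.zscores(model, ages, y)
        assert rep.z[0] == pytest.approx(2.0, abs=1e-9)
        assert not rep.extreme_positive[0]
        y_above = nm.warp_inverse(m_star + 2.1 * s_star, model.warp)
        assert nm.zscores(model, ages, y_above).extreme_positive[0]

    def test_training_zscores_standardized(self):
        rng = np.random.default_rng(5)
        wp = nm.WarpParams(0.4, 1.2)
        ages = rng.uniform(20, 80, 1000)
        z = 0.5 - 0.015 * (ages - 50) + 0.6 * rng.standard_normal(1000)
        y = nm.warp_inverse(z, wp)
        model = nm.fit(ages, y, seed=3)
        rep = nm.zscores(model, ages, y)
        assert np.mean(rep.z) == pytest.approx(0.0, abs=0.1)
        assert np.var(rep.z) == pytest.approx(1.0, abs=0.1)


class TestExplainedVariance:
    def test_perfect_prediction(self, rng):
        y = rng.standard_normal(50)
        assert nm.explained_variance(y, y) == pytest.approx(1.0)

    @pytest.mark.parametrize("c", [0.0, 3.7, -1.2])
    def test_any_constant_prediction_scores_zero(self, rng, c):
        y = rng.standard_normal(50)
        assert nm.explained_variance(y, np.full(50, c)) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_predictions_negative(self, rng):
        y = rng.standard_normal(200)
        assert nm.explained_variance(y, -y) < 0

    def test_matches_sklearn_explained_variance(self, rng):
        from sklearn.metrics import explained_variance_score

        y = rng.standard_normal(100)
        pred = 0.5 * y + 0.1 * rng.standard_normal(100)
        assert nm.explained_variance(y, pred) == pytest.approx(
            explained_variance_score(y, pred), abs=1e-12
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            nm.explained_variance(np.ones(5), np.zeros(5))
        with pytest.raises(ValueError, match="2 observations"):
            nm.explained_variance(np.array([1.0]), np.array([1.0]))


class TestStratifiedSplit:
    def test_default_cohort_58_58(self, cohort):
        train, test = nm.stratified_half_split(cohort, seed=0)
        assert len(train) == 58 and len(test) == 58

    def test_partition(self, cohort):
        train, test = nm.stratified_half_split(cohort, seed=1)
        assert set(train) | set(test) == set(cohort.subject_id)
        assert set(train) & set(test) == set()

    @pytest.mark.parametrize("seed", range(5))
    def test_sex_counts_balanced(self, cohort, seed):
        train, test = nm.stratified_half_split(cohort, seed=seed)
        sex = cohort.set_index("subject_id")["sex"]
        for s in ("male", "female"):
            assert abs((sex.loc[train] == s).sum() - (sex.loc[test] == s).sum()) <= 1

    @pytest.mark.parametrize("seed", range(5))
    def test_mean_ages_closely_matched(self, cohort, seed):
        train, test = nm.stratified_half_split(cohort, seed=seed)
        age = cohort.set_index("subject_id")["age"]
        assert abs(age.loc[train].mean() - age.loc[test].mean()) < 2.0

    def test_determinism(self, cohort):
        assert nm.stratified_half_split(cohort, seed=4) == nm.stratified_half_split(
            cohort, seed=4
        )


class TestRunNormative:
    def test_caudate_median_centile_declines_with_age(self, roi_table):
        res = nm.run_normative(roi_table, regions=("caudate_L",), seed=0)["caudate_L"]
        grid = res.centile_ages
        median = res.centile_curves[0.5]
        v30 = median[np.argmin(np.abs(grid - 30))]
        v75 = median[np.argmin(np.abs(grid - 75))]
        assert v75 < v30

    def test_deterministic_given_seed(self, roi_table):
        a = nm.run_normative(roi_table, regions=("caudate_L",), seed=9)["caudate_L"]
        b = nm.run_normative(roi_table, regions=("caudate_L",), seed=9)["caudate_L"]
        np.testing.assert_array_equal(a.test_report.z, b.test_report.z)
        assert a.ev_test == b.ev_test

    def test_missing_region_rejected(self, roi_table):
        with pytest.raises(ValueError, match="not in table"):
            nm.run_normative(roi_table, regions=("thalamus",), seed=0)
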