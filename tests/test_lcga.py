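"""LCGA mixture: densities, EM steps, fits, canonical order, labels."""

import numpy as np
import pytest
from scipy.stats import norm

import ptstraj as pt
from ptstraj.lcga import (DESIGN, LCGAParameters, _em, class_density, e_step,
                          fit_lcga, m_step)


def params_from_wave_means(means_per_class, sigma2, pi=None):
    """Build parameters whose fitted wave means equal the given values
    (the 3-wave quadratic is saturated, so the map is exact)."""
    means = np.atleast_2d(np.asarray(means_per_class, dtype=float))
    beta = np.linalg.solve(DESIGN, means.T).T
    K = len(beta)
    pi = np.full(K, 1 / K) if pi is None else np.asarray(pi)
    return LCGAParameters(pi=pi, beta=beta, sigma2=np.asarray(sigma2, dtype=float))


class TestClassDensity:
    def test_on_curve_unit_sd_gives_standard_normal_product(self):
        beta = np.array([30.0, 2.0, -0.5])
        y = DESIGN @ beta
        dens = class_density(y, [True] * 3, beta, np.ones(3))
        assert dens == pytest.approx((2 * np.pi) ** -1.5, rel=1e-12)

    def test_single_wave_two_sd_above_mean(self):
        beta = np.array([30.0, 0.0, 0.0])
        sigma = 4.0
        y = np.array([30.0 + 2 * sigma, 0.0, 0.0])
        dens = class_density(y, [True, False, False], beta, np.full(3, sigma**2))
        assert dens == pytest.approx(norm.pdf(2) / sigma, rel=1e-12)

    def test_declining_curve_mean_at_wave_two(self):
        beta = np.array([53.53, -33.76, 11.73])
        assert DESIGN[1] @ beta == pytest.approx(31.50, abs=1e-12)

    def test_all_waves_missing_rejected(self):
        with pytest.raises(ValueError):
            class_density([1.0, 2.0, 3.0], [False] * 3, np.zeros(3), np.ones(3))


class TestEStep:
    def test_equidistant_subject_splits_evenly(self):
        params = params_from_wave_means([[20, 20, 20], [30, 30, 30]], np.ones(3))
        pts = np.array([[25.0, 25.0, 25.0]])
        tau, _ = e_step(pts, np.ones((1, 3), bool), params)
        np.testing.assert_allclose(tau, [[0.5, 0.5]], atol=1e-12)

    def test_separation_limit_is_certain(self):
        params = params_from_wave_means([[20, 20, 20], [30, 30, 30]], np.ones(3))
        pts = np.array([[20.0, 20.0, 20.0]])
        tau, _ = e_step(pts, np.ones((1, 3), bool), params)
        assert tau[0, 0] > 0.999999

    def test_matches_direct_bayes_arithmetic(self):
        """Three subjects, two classes, missing values: brute-force Bayes
        with scipy's Normal pdf as the independent oracle."""
        params = params_from_wave_means(
            [[20, 22, 24], [40, 35, 30]], np.array([4.0, 9.0, 16.0]),
            pi=[0.7, 0.3],
        )
        pts = np.array([[21, 23, 28], [38, 30, 0], [30, 0, 0]], dtype=float)
        mask = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]], bool)
        tau, ll = e_step(pts, mask, params)

        means = params.fitted_means()
        sig = np.sqrt(np.array([4.0, 9.0, 16.0]))
        expected = np.zeros((3, 2))
        for i in range(3):
            like = np.ones(2)
            for k in range(2):
                for t in range(3):
                    if mask[i, t]:
                        like[k] *= norm.pdf(pts[i, t], means[k, t], sig[t])
            joint = np.array([0.7, 0.3]) * like
            expected[i] = joint / joint.sum()
        np.testing.assert_allclose(tau, expected, rtol=1e-10)
        total = sum(
            np.log(
                0.7 * np.prod([norm.pdf(pts[i, t], means[0, t], sig[t])
                               for t in range(3) if mask[i, t]])
                + 0.3 * np.prod([norm.pdf(pts[i, t], means[1, t], sig[t])
                                 for t in range(3) if mask[i, t]])
            )
            for i in range(3)
        )
        assert ll == pytest.approx(total, rel=1e-10)


class TestMStep:
    def test_degenerate_tau_recovers_noise_free_curves(self):
        beta_true = np.array([[20.0, 1.0, 0.5], [60.0, -10.0, 2.0]])
        y = np.vstack([np.tile(DESIGN @ beta_true[0], (5, 1)),
                       np.tile(DESIGN @ beta_true[1], (5, 1))])
        tau = np.zeros((10, 2))
        tau[:5, 0] = tau[5:, 1] = 1.0
        params = m_step(y, np.ones_like(y, bool), tau)
        np.testing.assert_allclose(params.beta, beta_true, atol=1e-9)

    def test_uniform_tau_gives_pooled_fit_in_every_class(self):
        rng = np.random.default_rng(4)
        y = rng.normal(30, 5, size=(40, 3))
        tau = np.full((40, 2), 0.5)
        params = m_step(y, np.ones_like(y, bool), tau)
        np.testing.assert_allclose(params.beta[0], params.beta[1], atol=1e-10)
        np.testing.assert_allclose(params.pi, [0.5, 0.5], atol=1e-12)

    def test_single_class_equals_ols_oracle(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, size=(60, 3)) + np.array([30.0, 28.0, 29.0])
        tau = np.ones((60, 1))
        params = m_step(y, np.ones_like(y, bool), tau)
        # saturated quadratic through the wave means: closed-form oracle
        beta_oracle = np.linalg.solve(DESIGN, y.mean(axis=0))
        np.testing.assert_allclose(params.beta[0], beta_oracle, atol=1e-9)
        np.testing.assert_allclose(
            params.sigma2, y.var(axis=0), atol=1e-9
        )


class TestFitLCGA:
    def test_k1_loglik_matches_closed_form(self):
        spec = pt.dnhs_like_spec(
            n_subjects=150, seed=21,
            dropout=pt.DropoutSpec(retention=(1.0, 1.0, 1.0)),
        )
        ds = pt.simulate_cohort(spec)
        fit = fit_lcga(ds, K=1, seed=0)
        # independent oracle: per-wave Gaussian log-likelihood at the ML
        # wave means and variances (the quadratic through 3 means is exact)
        ll = sum(
            norm.logpdf(ds.pts[:, t], ds.pts[:, t].mean(),
                        ds.pts[:, t].std()).sum()
            for t in range(3)
        )
        assert abs(fit.loglik - ll) < 1e-6

    def test_two_class_near_noise_free_recovery(self):
        spec = pt.dnhs_like_spec(
            n_subjects=120, seed=22,
            class_proportions=(0.5, 0.5),
            growth_coefficients=((20.0, 1.0, 0.0), (70.0, -5.0, 1.0)),
            wave_residual_sds=(((0.05,) * 3), ((0.05,) * 3)),
            class_labels=None,
            dropout=pt.DropoutSpec(retention=(1.0, 1.0, 1.0)),
        )
        ds = pt.simulate_cohort(spec)
        fit = fit_lcga(ds, K=2, n_starts=10, seed=1, sigma2_floor=1e-12)
        # with essentially no noise the fit recovers the realized class
        # counts exactly (canonical order: high class first)
        realized = np.bincount(ds.true_class, minlength=2) / ds.n_subjects
        np.testing.assert_allclose(fit.params.pi, realized[::-1], atol=1e-9)
        # canonical order: high class first
        np.testing.assert_allclose(fit.params.beta[0], (70.0, -5.0, 1.0), atol=0.05)
        np.testing.assert_allclose(fit.params.beta[1], (20.0, 1.0, 0.0), atol=0.05)
        assert pt.entropy_stat(fit.posteriors) > 0.999999

    def test_em_loglik_monotone(self, two_class_cohort):
        ds = two_class_cohort
        pts = np.where(ds.wave_mask, ds.pts, 0.0)
        params = params_from_wave_means(
            [[30, 30, 30], [50, 45, 45]], np.array([40.0, 40.0, 40.0])
        )
        lls = []
        for _ in range(60):
            tau, ll = e_step(pts, ds.wave_mask, params)
            lls.append(ll)
            params = m_step(pts, ds.wave_mask, tau, sigma2=params.sigma2)
        diffs = np.diff(lls)
        assert np.all(diffs >= -1e-8 * (np.abs(lls[:-1]) + 1))

    def test_canonical_order_descending_mean(self, fitted_four_class):
        avg = fitted_four_class.params.fitted_means().mean(axis=1)
        assert np.all(np.diff(avg) < 0)

    def test_loglik_consistent_with_params(self, fitted_four_class, small_cohort):
        pts = np.where(small_cohort.wave_mask, small_cohort.pts, 0.0)
        _, ll = e_step(pts, small_cohort.wave_mask, fitted_four_class.params)
        assert abs(ll - fitted_four_class.loglik) < 1e-6
        rows = fitted_four_class.posteriors.sum(axis=1)
        np.testing.assert_allclose(rows, 1.0, atol=1e-8)

    def test_param_count_formula(self, fitted_four_class):
        # (K-1) weights + 3K growth + 3 shared wave variances
        assert fitted_four_class.params.param_count == 3 + 12 + 3

    def test_permutation_invariance(self, two_class_cohort):
        ds = two_class_cohort
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n_subjects)
        fit_a = fit_lcga((ds.pts, ds.wave_mask), 2, n_starts=8, seed=5)
        fit_b = fit_lcga((ds.pts[perm], ds.wave_mask[perm]), 2, n_starts=8, seed=5)
        np.testing.assert_allclose(fit_a.params.beta, fit_b.params.beta, atol=1e-4)
        np.testing.assert_allclose(fit_a.loglik, fit_b.loglik, atol=1e-5)
        np.testing.assert_allclose(
            fit_a.posteriors[perm], fit_b.posteriors, atol=1e-6
        )


class TestAssignAndLabel:
    def _fit_with_tau(self, tau):
        K = tau.shape[1]
        params = params_from_wave_means(
            [[50 - 10 * k] * 3 for k in range(K)], np.ones(3),
        )
        return pt.LCGAFit(params=params, loglik=0.0, posteriors=tau,
                          modal_class=tau.argmax(axis=1), converged=True,
                          n_iter=1, n_starts_used=1)

    def test_modal_assignment_and_tie_break(self):
        tau = np.array([[0.1, 0.7, 0.1, 0.1], [0.25, 0.25, 0.25, 0.25]])
        fit = self._fit_with_tau(tau)
        table = pt.assign_modal_class(fit, ["a", "b"])
        assert table.loc[0, "modal_class"] == 2  # 1-based
        assert table.loc[1, "modal_class"] == 1  # tie -> lowest index
        probs = table.filter(like="prob_").to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize(
        "means, expected",
        [
            ([26.60, 25.69, 24.69], "low"),
            ([53.53, 30.74, 32.51], "decreasing"),
            ([37.85, 53.13, 54.47], "increasing"),
            ([70.06, 52.94, 60.94], "high"),
            ([45.0, 45.0, 45.0], "high"),  # boundary: >= cut-off counts
            ([50.0, 40.0, 50.0], "class_1"),  # dip pattern has no name
        ],
    )
    def test_trajectory_labels(self, means, expected):
        params = params_from_wave_means([means], np.ones(3))
        fit = pt.LCGAFit(params=params, loglik=0.0,
                         posteriors=np.ones((1, 1)), modal_class=np.zeros(1, int),
                         converged=True, n_iter=1, n_starts_used=1)
        assert pt.label_trajectories(fit, 44.0) == [expected]
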