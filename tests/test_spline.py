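"""Spline module: kernel, REML criterion, BLUP fits and curve evaluation."""

import warnings

import numpy as np
import pytest

import spcdist as sp
from spcdist import Domain, Subject
from spcdist.exceptions import DomainError, ValidationError

from oracles import kernel_quad, penalized_spline_fit, reml_direct


# ---------------------------------------------------------------------------
# kernel


class TestKernel:
    def test_left_endpoint_is_zero(self, unit_domain):
        for t in [0.0, 0.3, 1.0]:
            assert sp.kernel_value(0.0, t, unit_domain) == 0.0

    def test_midpoint_matches_quadrature(self, unit_domain):
        got = sp.kernel_value(0.5, 0.5, unit_domain)
        want = kernel_quad(0.5, 0.5, unit_domain)
        assert abs(got - want) <= 1e-10

    def test_symmetry_random_pairs(self, rng, unit_domain):
        s = rng.uniform(0, 1, 100)
        t = rng.uniform(0, 1, 100)
        a = sp.kernel_value(s, t, unit_domain)
        b = sp.kernel_value(t, s, unit_domain)
        np.testing.assert_array_equal(a, b)

    def test_rejects_out_of_domain(self, unit_domain):
        with pytest.raises(DomainError):
            sp.kernel_value(-0.5, 0.2, unit_domain)

    def test_matches_quadrature_on_general_domain(self, rng):
        dom = Domain(-3.0, 17.0)
        for _ in range(25):
            s, t = rng.uniform(-3, 17, 2)
            assert abs(sp.kernel_value(s, t, dom) - kernel_quad(s, t, dom)) <= 1e-10


class TestBuildPsi:
    def test_single_time_at_left_endpoint(self, unit_domain):
        psi = sp.build_psi([0.0], unit_domain)
        np.testing.assert_array_equal(psi, [[0.0]])

    def test_symmetric_and_psd(self, rng, unit_domain):
        times = np.sort(rng.uniform(0, 1, 30))
        psi = sp.build_psi(times, unit_domain)
        np.testing.assert_array_equal(psi, psi.T)
        evals = np.linalg.eigvalsh(psi)
        assert evals.min() >= -1e-10 * evals.max()

    def test_entrywise_quadrature_agreement(self, unit_domain):
        times = np.linspace(0, 1, 10)
        psi = sp.build_psi(times, unit_domain)
        for i, s in enumerate(times):
            for j, t in enumerate(times):
                assert abs(psi[i, j] - kernel_quad(s, t, unit_domain)) <= 1e-10

    def test_affine_time_rescaling_invariance(self, rng):
        # Psi depends only on normalised times, so [0, 180] days or [0, 1]
        # give identical matrices.
        frac = np.sort(rng.uniform(0, 1, 25))
        psi_days = sp.build_psi(180.0 * frac, Domain(0.0, 180.0))
        psi_unit = sp.build_psi(frac, Domain(0.0, 1.0))
        assert np.max(np.abs(psi_days - psi_unit)) <= 1e-12

    def test_rejects_non_increasing_times(self, unit_domain):
        with pytest.raises(ValidationError):
            sp.build_psi([0.1, 0.1, 0.5, 0.9], unit_domain)


# ---------------------------------------------------------------------------
# REML criterion


def _noisy_subject(rng, K=40, theta=None, sigma=1.0, domain=None):
    domain = domain or Domain(0.0, 1.0)
    t = np.sort(rng.uniform(domain.t_lower, domain.t_upper, K))
    if theta is None:
        y = 1.0 + 2.0 * t + sigma * rng.standard_normal(K)
    else:
        psi = sp.build_psi(t, domain)
        L = np.linalg.cholesky(psi + 1e-10 * np.eye(K))
        u = np.sqrt(theta) * sigma * (L @ rng.standard_normal(K))
        y = 1.0 + 2.0 * t + u + sigma * rng.standard_normal(K)
    return Subject("s", t, y)


class TestRemlCriterion:
    def test_finite_on_straight_line_data(self, unit_domain):
        t = np.linspace(0, 1, 20)
        subj = Subject("line", t, 2.0 + 3.0 * t)
        for log10_theta in [-6.0, 0.0, 6.0]:
            val = sp.reml_criterion(log10_theta, subj, unit_domain)
            assert np.isfinite(val)

    def test_matches_direct_evaluation(self, rng, unit_domain):
        subj = _noisy_subject(rng, K=30, theta=2.0)
        for log10_theta in [-3.0, -1.0, 0.0, 1.5, 3.0]:
            mine = sp.reml_criterion(log10_theta, subj, unit_domain)
            direct = reml_direct(log10_theta, subj, unit_domain)
            assert abs(mine - direct) <= 1e-8 * max(1.0, abs(direct))

    def test_grid_peak_tracks_theta(self, unit_domain):
        # The integrated-Wiener random effect has only a handful of
        # eigencomponents above the noise floor, so any estimator of the
        # variance ratio carries chi-square-like realisation noise with few
        # degrees of freedom; individual replicates scatter widely.  What
        # REML must deliver: (a) the criterion's peak equals the peak of an
        # independent direct evaluation, replicate by replicate, and (b) at
        # a strong signal (theta = 100) the peaks are centred on the truth
        # (median within a factor of 4).
        theta = 100.0
        grid = np.linspace(np.log10(theta) - 3, np.log10(theta) + 3, 61)
        offsets = []
        for r in range(20):
            rng = np.random.default_rng(1000 + r)
            subj = _noisy_subject(rng, K=200, theta=theta)
            solver = sp.SubjectSolver(subj, unit_domain)
            vals = [solver.reml(x) for x in grid]
            peak = grid[int(np.argmax(vals))]
            offsets.append(peak - np.log10(theta))
            if r < 5:
                direct = [reml_direct(x, subj, unit_domain) for x in grid]
                assert grid[int(np.argmax(direct))] == peak
        assert abs(np.median(offsets)) <= np.log10(4.0)


# ---------------------------------------------------------------------------
# fitting


class TestFitSpline:
    def test_noiseless_line_reproduced(self, unit_domain):
        t = np.linspace(0, 1, 15)
        y = 2.0 + 3.0 * t
        with warnings.catch_warnings():
            # an exact fit may push the REML optimum to the search boundary
            warnings.simplefilter("ignore", sp.SmoothingBoundaryWarning)
            fit = sp.fit_spline(Subject("line", t, y), unit_domain)
        assert np.max(np.abs(fit.fitted - y)) <= 1e-6
        grid = np.linspace(0, 1, 57)
        assert np.max(np.abs(fit(grid) - (2.0 + 3.0 * grid))) <= 1e-6

    def test_lambda_variance_identity(self, rng, unit_domain):
        subj = _noisy_subject(rng, K=60)
        fit = sp.fit_spline(subj, unit_domain)
        assert np.isclose(subj.n_obs * fit.lam, fit.sigma2 / fit.sigma2_u, rtol=1e-12)

    def test_rmse_below_noise_sd_on_linear_signal(self):
        # y = 5t + N(0,1) at K=200: the fitted curve should track the line
        # with error well below the noise level in nearly every replicate.
        dom = Domain(0.0, 1.0)
        t = np.linspace(0, 1, 200)
        f_true = 5.0 * t
        ok = 0
        n_rep = 100
        for r in range(n_rep):
            rng = np.random.default_rng(5000 + r)
            fit = sp.fit_spline(Subject("lin", t, f_true + rng.standard_normal(200)), dom)
            rmse = np.sqrt(np.mean((fit.fitted - f_true) ** 2))
            ok += rmse < 0.5
        assert ok >= 95

    def test_fixed_lambda_matches_penalized_spline_oracle(self, unit_domain):
        rng = np.random.default_rng(77)
        for _ in range(20):
            K = int(rng.integers(10, 31))
            t = np.sort(rng.uniform(0, 1, K))
            t[0], t[-1] = 0.0, 1.0
            y = np.sin(3 * t) + 0.4 * rng.standard_normal(K)
            lam = 10.0 ** rng.uniform(-5, 1)
            fit = sp.fit_spline_fixed_lambda(Subject("x", t, y), unit_domain, lam)
            direct = penalized_spline_fit(t, y, unit_domain, lam)
            np.testing.assert_allclose(fit.fitted, direct, rtol=1e-6, atol=1e-8)

    def test_fixed_lambda_idempotent_with_reml_choice(self, rng, unit_domain):
        subj = _noisy_subject(rng, K=50)
        fit = sp.fit_spline(subj, unit_domain)
        refit = sp.fit_spline_fixed_lambda(subj, unit_domain, fit.lam)
        np.testing.assert_array_equal(fit.fitted, refit.fitted)

    def test_large_lambda_gives_ols_line(self, rng, unit_domain):
        subj = _noisy_subject(rng, K=25)
        fit = sp.fit_spline_fixed_lambda(subj, unit_domain, 1e8)
        X = np.column_stack([np.ones(subj.n_obs), subj.times])
        ols = X @ np.linalg.lstsq(X, subj.values, rcond=None)[0]
        assert np.max(np.abs(fit.fitted - ols)) <= 1e-4

    def test_small_lambda_interpolates(self, rng, unit_domain):
        t = np.linspace(0.1, 1.0, 12)
        y = np.sin(3 * t) + 0.5 * rng.standard_normal(12)
        fit = sp.fit_spline_fixed_lambda(Subject("x", t, y), unit_domain, 1e-10)
        assert np.max(np.abs(fit.fitted - y)) <= 1e-3

    def test_roughness_decreases_with_lambda(self, rng, unit_domain):
        subj = _noisy_subject(rng, K=40)
        grid = np.linspace(0, 1, 801)
        h = grid[1] - grid[0]
        rough_prev = np.inf
        for lam in [1e-6, 1e-4, 1e-2, 1.0, 1e2]:
            fit = sp.fit_spline_fixed_lambda(subj, unit_domain, lam)
            f = fit(grid)
            d2 = np.diff(f, 2) / h**2
            rough = float(np.sum(d2**2) * h)
            assert rough <= rough_prev + 1e-8
            rough_prev = rough


class TestEvaluateCurve:
    def test_consistent_with_fitted_at_observed_times(self, rng, unit_domain):
        subj = _noisy_subject(rng, K=30)
        fit = sp.fit_spline(subj, unit_domain)
        np.testing.assert_allclose(fit(subj.times), fit.fitted, rtol=1e-10)

    def test_linear_beyond_last_observation(self, rng):
        # natural-spline boundary: psi(t, t_k) is linear in t past every t_k
        dom = Domain(0.0, 1.0)
        t = np.sort(np.random.default_rng(9).uniform(0.0, 0.6, 20))
        y = np.sin(4 * t) + 0.2 * np.random.default_rng(10).standard_normal(20)
        fit = sp.fit_spline(Subject("x", t, y), dom)
        tail = np.linspace(0.65, 1.0, 200)
        second_diff = np.diff(fit(tail), 2)
        assert np.max(np.abs(second_diff)) < 1e-8

    def test_rejects_extrapolation(self, rng, unit_domain):
        subj = _noisy_subject(rng, K=20)
        fit = sp.fit_spline(subj, unit_domain)
        with pytest.raises(DomainError):
            fit(1.5)


class TestValidation:
    def test_subject_requires_four_observations(self):
        with pytest.raises(ValidationError):
            Subject("tiny", [0.1, 0.2, 0.3], [1.0, 2.0, 3.0])

    def test_subject_rejects_duplicate_times(self):
        with pytest.raises(ValidationError):
            Subject("dup", [0.1, 0.2, 0.2, 0.3], [1.0, 2.0, 3.0, 4.0])

    def test_domain_requires_ordering(self):
        with pytest.raises(ValidationError):
            Domain(1.0, 1.0)
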