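"""Cubic smoothing splines via their linear mixed-model representation.

A subject's irregular series ``(t_k, y_k), k = 1..K`` on a domain
``[T_L, T_U]`` is smoothed by the natural cubic smoothing spline
minimising

    (1/K) * sum_k (y_k - f(t_k))^2  +  lam * int f''(t)^2 dt

For a *fixed* smoothing parameter ``lam`` this minimiser coincides with
the best linear unbiased predictor (BLUP) in the linear mixed model

    y = X beta + u + eps,
    u ~ N(0, sigma_u^2 * Psi),   eps ~ N(0, sigma^2 * I),

where ``X`` holds an unpenalised intercept and slope, ``Psi`` is the
integrated-truncated-linear (integrated Wiener) correlation kernel
evaluated at the observation times, and the variance components are tied
to the smoothing parameter by ``sigma_u^2 = sigma^2 / (K * lam)``.  The
ratio ``K * lam = sigma^2 / sigma_u^2`` is the inverse signal-to-noise
ratio of the subject.  Treating ``theta = sigma_u^2 / sigma^2`` as a
free variance ratio and maximising the restricted likelihood (REML)
therefore selects the smoothing parameter from the data itself.

The kernel is computed on the *normalised* time axis
``t~ = (t - T_L) / (T_U - T_L)``:

    psi(s, t) = (T_U - T_L)^{-3} * int_{T_L}^{T_U} (s-tau)_+ (t-tau)_+ dtau
              = s~^2 (3 t~ - s~) / 6           for s~ <= t~,

which makes ``Psi`` dimensionless and invariant to affine changes of the
time axis; ``lam`` is correspondingly dimensionless.  Off-grid
prediction uses the Gaussian-process cross-covariance with the same
kernel, which reproduces the natural spline (linear beyond the last
observation).

All fits go through :class:`SubjectSolver`, which caches the spectral
decomposition of ``Psi`` so that repeated fits of one subject at many
smoothing parameters -- the workhorse of the commuted dissimilarity --
cost O(K^2) each instead of O(K^3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .exceptions import (
    DegenerateDesignError,
    DomainError,
    SmoothingBoundaryWarning,
    ValidationError,
)

__all__ = [
    "Domain",
    "Subject",
    "SplineFit",
    "SubjectSolver",
    "kernel_value",
    "kernel_cross",
    "build_psi",
    "reml_criterion",
    "fit_spline",
    "fit_spline_fixed_lambda",
    "evaluate_curve",
]

#: REML search box for log10(theta), theta = sigma_u^2 / sigma^2.
LOG10_THETA_BOUNDS = (-8.0, 8.0)

_MIN_OBS = 4  # smallest K admitting a nondegenerate REML fit (2 fixed effects)


@dataclass(frozen=True)
class Domain:
    """Closed time interval ``[T_L, T_U]`` on which all curves live."""

    t_lower: float
    t_upper: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.t_lower) or not np.isfinite(self.t_upper):
            raise ValidationError("domain endpoints must be finite")
        if not self.t_lower < self.t_upper:
            raise ValidationError(
                f"domain requires t_lower < t_upper, got [{self.t_lower}, {self.t_upper}]"
            )

    @property
    def span(self) -> float:
        return self.t_upper - self.t_lower

    def normalize(self, t: np.ndarray) -> np.ndarray:
        """Map times to ``[0, 1]``."""
        return (np.asarray(t, dtype=float) - self.t_lower) / self.span

    def check(self, t: np.ndarray, what: str = "time") -> np.ndarray:
        """Validate that every entry of ``t`` lies in the domain."""
        t = np.asarray(t, dtype=float)
        tol = 1e-12 * max(1.0, abs(self.t_lower), abs(self.t_upper))
        if np.any(t < self.t_lower - tol) or np.any(t > self.t_upper + tol):
            bad = t[(t < self.t_lower - tol) | (t > self.t_upper + tol)]
            raise DomainError(
                f"{what} outside domain [{self.t_lower}, {self.t_upper}]: {bad[:5]}"
            )
        return np.clip(t, self.t_lower, self.t_upper)


@dataclass(frozen=True)
class Subject:
    """One individual's irregular longitudinal series.

    ``times`` must be strictly increasing (duplicate observation times
    are rejected) with at least four observations, the minimum for a
    nondegenerate REML fit with an intercept-and-slope fixed effect.
    """

    id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", y)
        if t.ndim != 1 or y.ndim != 1 or len(t) != len(y):
            raise ValidationError(f"subject {self.id!r}: times/values must be 1-d and equal length")
        if len(t) < _MIN_OBS:
            raise ValidationError(
                f"subject {self.id!r}: needs at least {_MIN_OBS} observations, got {len(t)}"
            )
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
            raise ValidationError(f"subject {self.id!r}: non-finite times or values")
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"subject {self.id!r}: times must be strictly increasing (duplicates rejected)"
            )

    @property
    def n_obs(self) -> int:
        return len(self.times)


@dataclass
class SplineFit:
    """A REML- or fixed-``lam``-fitted smoothing spline for one subject.

    The fitted curve at any ``t`` in the domain is

        f(t) = beta[0] + beta[1] * t + sum_k psi(t, times[k]) * blup_weights[k]

    By construction ``n_obs * lam == sigma2 / sigma2_u`` exactly.
    """

    subject_id: str
    lam: float
    sigma2: float
    sigma2_u: float
    beta: np.ndarray
    blup_weights: np.ndarray
    fitted: np.ndarray
    times: np.ndarray
    domain: Domain
    theta: float = field(repr=False, default=0.0)

    def __call__(self, t_grid) -> np.ndarray:
        return evaluate_curve(self, t_grid)


# ---------------------------------------------------------------------------
# kernel


def kernel_value(s, t, domain: Domain):
    """Integrated-truncated-linear kernel ``psi(s, t)``.

    Closed form on normalised coordinates ``s~ <= t~``:
    ``psi = s~^2 (3 t~ - s~) / 6``; symmetric in its arguments and zero
    whenever either argument equals the left endpoint.
    """
    s_arr = domain.check(np.asarray(s, dtype=float), "s")
    t_arr = domain.check(np.asarray(t, dtype=float), "t")
    sn = domain.normalize(s_arr)
    tn = domain.normalize(t_arr)
    a = np.minimum(sn, tn)
    b = np.maximum(sn, tn)
    out = a * a * (3.0 * b - a) / 6.0
    if np.isscalar(s) and np.isscalar(t):
        return float(out)
    return out


def kernel_cross(t_a, t_b, domain: Domain) -> np.ndarray:
    """Matrix of ``psi(t_a[i], t_b[j])`` values."""
    t_a = domain.check(np.atleast_1d(np.asarray(t_a, dtype=float)), "t_a")
    t_b = domain.check(np.atleast_1d(np.asarray(t_b, dtype=float)), "t_b")
    an = domain.normalize(t_a)[:, None]
    bn = domain.normalize(t_b)[None, :]
    lo = np.minimum(an, bn)
    hi = np.maximum(an, bn)
    return lo * lo * (3.0 * hi - lo) / 6.0


def build_psi(times, domain: Domain) -> np.ndarray:
    """Kernel (correlation) matrix of the random effect at the given times.

    Symmetric positive semi-definite; invariant to affine rescaling of
    the time axis because the kernel is computed on normalised
    coordinates.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(np.diff(times) <= 0):
        raise ValidationError("times must be strictly increasing")
    return kernel_cross(times, times, domain)


# ---------------------------------------------------------------------------
# REML machinery


class SubjectSolver:
    """Per-subject fitting engine with a cached eigendecomposition of Psi.

    Building the solver costs one O(K^3) symmetric eigendecomposition;
    every subsequent REML-criterion evaluation or fixed-parameter fit is
    O(K^2).  This is what makes assembling a full commuted dissimilarity
    matrix (n REML solves plus 2 * C(n, 2) fixed-parameter fits)
    affordable.
    """

    def __init__(self, subject: Subject, domain: Domain):
        domain.check(subject.times, f"subject {subject.id!r} times")
        self.subject = subject
        self.domain = domain
        K = subject.n_obs
        self.psi = build_psi(subject.times, domain)
        evals, evecs = np.linalg.eigh(self.psi)
        # Psi is PSD; clip the O(eps) negative eigenvalues from roundoff.
        self.eigvals = np.clip(evals, 0.0, None)
        self.evecs = evecs
        self.X = np.column_stack([np.ones(K), subject.times])
        self.Xt = evecs.T @ self.X
        self.yt = evecs.T @ subject.values

    # -- internal -----------------------------------------------------------

    def _profile(self, theta: float):
        """GLS quantities at W = theta * Psi + I (in the eigenbasis)."""
        d = 1.0 / (theta * self.eigvals + 1.0)  # eigenvalues of W^{-1}
        A = (self.Xt * d[:, None]).T @ self.Xt  # X' W^{-1} X
        b = self.Xt.T @ (d * self.yt)
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            raise DegenerateDesignError(
                f"subject {self.subject.id!r}: singular fixed-effect design"
            )
        beta = np.linalg.solve(A, b)
        rss = float(self.yt @ (d * self.yt) - beta @ b)
        rss = max(rss, 1e-300)  # exact fits: keep the criterion finite
        return d, beta, rss, logdet_A

    # -- public -------------------------------------------------------------

    def reml(self, log10_theta: float) -> float:
        """Profiled restricted log-likelihood at ``theta = 10**log10_theta``.

        sigma^2 is profiled out in closed form,
        ``sigma2_hat = RSS_W / (K - 2)`` with RSS_W the GLS residual sum
        of squares under ``W = theta * Psi + I``.
        """
        theta = 10.0 ** float(log10_theta)
        d, _, rss, logdet_A = self._profile(theta)
        nu = self.subject.n_obs - 2
        sigma2 = rss / nu
        logdet_W = -float(np.sum(np.log(d)))
        return -0.5 * (nu * np.log(2.0 * np.pi * sigma2) + logdet_W + logdet_A + nu)

    def fit_at_theta(self, theta: float, lam: float | None = None) -> SplineFit:
        """BLUP fit at a fixed variance ratio theta = sigma_u^2 / sigma^2."""
        if not theta > 0:
            raise ValidationError("theta must be positive")
        d, beta, rss, _ = self._profile(theta)
        K = self.subject.n_obs
        sigma2 = rss / (K - 2)
        resid_t = self.yt - self.Xt @ beta
        # c = theta * (theta*Psi + I)^{-1} (y - X beta); random part at any
        # t is then sum_k psi(t, t_k) c_k, i.e. the BLUP cross-covariance.
        c = theta * (self.evecs @ (d * resid_t))
        fitted = self.X @ beta + self.psi @ c
        return SplineFit(
            subject_id=self.subject.id,
            lam=1.0 / (K * theta) if lam is None else lam,
            sigma2=sigma2,
            sigma2_u=theta * sigma2,
            beta=beta,
            blup_weights=c,
            fitted=fitted,
            times=self.subject.times,
            domain=self.domain,
            theta=theta,
        )

    def fit_reml(self) -> SplineFit:
        """Maximise the profiled REML criterion over log10(theta)."""
        lo, hi = LOG10_THETA_BOUNDS
        res = minimize_scalar(
            lambda x: -self.reml(x),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8, "maxiter": 500},
        )
        x = float(res.x)
        if x <= lo + 1e-6 or x >= hi - 1e-6:
            warnings.warn(
                f"subject {self.subject.id!r}: REML optimum at the search "
                f"boundary (log10 theta = {x:.2f}); clipping",
                SmoothingBoundaryWarning,
                stacklevel=2,
            )
            x = float(np.clip(x, lo, hi))
        # route through the smoothing parameter so a later fixed-lambda
        # refit at .lam reproduces this fit bit for bit
        return self.fit_lambda(1.0 / (self.subject.n_obs * 10.0 ** x))

    def fit_lambda(self, lam: float) -> SplineFit:
        """BLUP fit with the smoothing parameter imposed (theta = 1/(K lam))."""
        if not lam > 0:
            raise ValidationError("lam must be positive")
        return self.fit_at_theta(1.0 / (self.subject.n_obs * lam), lam=lam)

    def curve(self, fit: SplineFit, points: np.ndarray, cross: np.ndarray | None = None) -> np.ndarray:
        """Evaluate a fit of this subject on ``points``.

        ``cross`` may carry a precomputed ``kernel_cross(points, times)``
        matrix so the caller can amortise it over many fits.
        """
        if cross is None:
            cross = kernel_cross(points, self.subject.times, self.domain)
        return fit.beta[0] + fit.beta[1] * np.asarray(points, float) + cross @ fit.blup_weights


def reml_criterion(log10_theta: float, subject: Subject, domain: Domain) -> float:
    """Profiled restricted log-likelihood; see :meth:`SubjectSolver.reml`."""
    return SubjectSolver(subject, domain).reml(log10_theta)


def fit_spline(subject: Subject, domain: Domain) -> SplineFit:
    """REML fit: selects the smoothing parameter from the data."""
    return SubjectSolver(subject, domain).fit_reml()


def fit_spline_fixed_lambda(subject: Subject, domain: Domain, lam: float) -> SplineFit:
    """Fit with the smoothing parameter imposed; sigma^2 still profiled by REML."""
    return SubjectSolver(subject, domain).fit_lambda(lam)


def evaluate_curve(fit: SplineFit, t_grid) -> np.ndarray:
    """Evaluate the fitted curve anywhere in the domain (no extrapolation).

    Uses the BLUP cross-covariance form
    ``f(t) = beta0 + beta1 t + sum_k psi(t, t_k) c_k``; at the observed
    times this reproduces ``fit.fitted``, and beyond the last observation
    (inside the domain) the curve continues linearly, as a natural spline
    must.
    """
    scalar = np.isscalar(t_grid)
    t = np.atleast_1d(np.asarray(t_grid, dtype=float))
    t = fit.domain.check(t, "evaluation time")
    cross = kernel_cross(t, fit.times, fit.domain)
    out = fit.beta[0] + fit.beta[1] * t + cross @ fit.blup_weights
    return float(out[0]) if scalar else out
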