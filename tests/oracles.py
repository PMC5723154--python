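"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a route deliberately different from
the implementation under test: adaptive quadrature for the closed-form
kernel, a banded penalized natural-cubic-spline solve for the BLUP fit,
explicit-determinant REML, grid-plus-polish minimisation for the Q
criterion, pair enumeration for the Rand indices, and exhaustive medoid
search for PAM.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize

from spcdist import Domain, Subject, build_psi


def kernel_quad(s: float, t: float, domain: Domain) -> float:
    """psi(s, t) by adaptive quadrature of the defining integral."""
    h = domain.span
    val, _ = quad(
        lambda tau: max(s - tau, 0.0) * max(t - tau, 0.0),
        domain.t_lower,
        domain.t_upper,
        points=[min(s, t), max(s, t)],
        epsabs=1e-13,
        epsrel=1e-13,
    )
    return val / h**3


def penalized_spline_fit(times: np.ndarray, values: np.ndarray, domain: Domain, lam: float) -> np.ndarray:
    """Direct minimiser of (1/K)||y - f||^2 + lam * int f''^2 over natural
    cubic splines, via the banded Green-Silverman system (no mixed model)."""
    t01 = domain.normalize(times)
    y = np.asarray(values, float)
    K = len(t01)
    h = np.diff(t01)
    Q = np.zeros((K, K - 2))
    R = np.zeros((K - 2, K - 2))
    for j in range(1, K - 1):
        c = j - 1
        Q[j - 1, c] = 1 / h[j - 1]
        Q[j, c] = -1 / h[j - 1] - 1 / h[j]
        Q[j + 1, c] = 1 / h[j]
        R[c, c] = (h[j - 1] + h[j]) / 3
        if c + 1 < K - 2:
            R[c, c + 1] = R[c + 1, c] = h[j] / 6
    alpha = K * lam
    gamma = np.linalg.solve(R + alpha * (Q.T @ Q), Q.T @ y)
    return y - alpha * (Q @ gamma)


def reml_direct(log10_theta: float, subject: Subject, domain: Domain) -> float:
    """Restricted log-likelihood by explicit determinants and solves."""
    theta = 10.0 ** log10_theta
    t, y = subject.times, subject.values
    K = len(t)
    W = theta * build_psi(t, domain) + np.eye(K)
    X = np.column_stack([np.ones(K), t])
    Wi_X = np.linalg.solve(W, X)
    Wi_y = np.linalg.solve(W, y)
    A = X.T @ Wi_X
    beta = np.linalg.solve(A, X.T @ Wi_y)
    resid = y - X @ beta
    rss = float(resid @ np.linalg.solve(W, resid))
    nu = K - 2
    sigma2 = rss / nu
    _, logdet_W = np.linalg.slogdet(W)
    _, logdet_A = np.linalg.slogdet(A)
    return -0.5 * (nu * np.log(2 * np.pi * sigma2) + logdet_W + logdet_A + nu)


def q_bruteforce(d_hat, d_true) -> float:
    """Q criterion by coarse grid search over (a, b) plus Nelder-Mead polish."""
    mask = ~np.eye(d_hat.n, dtype=bool)
    x = d_hat.values[mask]
    y = d_true.values[mask]
    w = 1.0 / y
    n2 = d_hat.n ** 2

    def loss(ab):
        r = ab[0] + ab[1] * x - y
        return float((w * r * r).sum() / n2)

    scale_b = (np.abs(y).max() + 1) / (np.abs(x).max() + 1e-12)
    best = None
    for a0 in np.linspace(-np.abs(y).max(), np.abs(y).max(), 21):
        for b0 in np.linspace(-2 * scale_b, 2 * scale_b, 21):
            v = loss((a0, b0))
            if best is None or v < best[0]:
                best = (v, (a0, b0))
    res = minimize(loss, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
    res2 = minimize(loss, res.x, method="Powell",
                    options={"xtol": 1e-14, "ftol": 1e-15, "maxiter": 5000})
    return float(min(res.fun, res2.fun))


def rand_enumeration(labels, truth) -> tuple[float, float]:
    """Rand index by direct pair counting; ARI by the hypergeometric
    chance-correction computed from the contingency table."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    n = len(labels)
    agree = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a = labels[i] == labels[j]
        same_b = truth[i] == truth[j]
        agree += same_a == same_b
    total = comb(n, 2)
    rand = agree / total

    cats_a = sorted(set(labels.tolist()))
    cats_b = sorted(set(truth.tolist()))
    nij = np.array([[np.sum((labels == a) & (truth == b)) for b in cats_b] for a in cats_a])
    sum_ij = sum(comb(int(v), 2) for v in nij.ravel())
    sum_a = sum(comb(int(v), 2) for v in nij.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in nij.sum(axis=0))
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    ari = 1.0 if max_index == expected else (sum_ij - expected) / (max_index - expected)
    return rand, ari


def pam_exhaustive(D, k: int) -> float:
    """Globally optimal k-medoids objective by exhaustive enumeration."""
    d = D.values
    best = np.inf
    for meds in itertools.combinations(range(D.n), k):
        best = min(best, float(d[:, meds].min(axis=1).sum()))
    return best
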