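"""Dissimilarity measures between irregularly observed curves.

The headline measure is the *smoothing parameter commutation*
dissimilarity ``d_SPC``: fit each subject's smoothing parameter by REML,
then for a pair (i, j) smooth *both* series with subject i's parameter,
take the L2 distance between the two curves, do the same with subject
j's parameter, and average the two rooted integrals:

    d_ij = 1/2 * [ || f_i(.; lam_i) - f_j(.; lam_i) ||_L2
                 + || f_i(.; lam_j) - f_j(.; lam_j) ||_L2 ]

Commuting the smoothing parameters makes the comparison robust to each
subject's own noise level: a pair with similar underlying curves stays
close no matter whose signal-to-noise ratio drives the smoothing.  Two
baselines are provided: ``d_SS`` (each curve smoothed with its own
parameter, no commutation) and the pointwise Euclidean distance
``d_EUCL`` (defined only when all subjects share one time grid -- its
failure on irregular data is exactly what the spline-based measures
fix).

All three satisfy nonnegativity, zero on identity and symmetry; the
triangle inequality is not guaranteed (hence "dissimilarity", not
"distance"), which is no obstacle for dissimilarity-based clustering.
Integrals are approximated by composite Simpson quadrature on a uniform
grid (401 points by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson
from scipy.spatial.distance import squareform, pdist

from .exceptions import ValidationError
from .spline import Domain, Subject, SubjectSolver, SplineFit, kernel_cross

__all__ = [
    "QuadratureGrid",
    "DissimilarityMatrix",
    "MEASURES",
    "l2_curve_distance",
    "d_spc",
    "d_ss",
    "d_eucl",
    "dissimilarity_matrix",
    "dissimilarity_matrices",
    "infer_domain",
]

MEASURES = ("spc", "ss", "eucl")


@dataclass(frozen=True)
class QuadratureGrid:
    """Discretisation of the domain used to approximate L2 integrals."""

    points: np.ndarray
    scheme: str = "simpson"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or len(pts) < 101:
            raise ValidationError("quadrature grid needs at least 101 points")
        if np.any(np.diff(pts) <= 0):
            raise ValidationError("quadrature grid must be strictly increasing")

    @classmethod
    def uniform(cls, domain: Domain, n_points: int = 401) -> "QuadratureGrid":
        return cls(points=np.linspace(domain.t_lower, domain.t_upper, n_points))

    def matches(self, domain: Domain) -> None:
        tol = 1e-9 * max(1.0, domain.span)
        if abs(self.points[0] - domain.t_lower) > tol or abs(self.points[-1] - domain.t_upper) > tol:
            raise ValidationError("quadrature grid endpoints must equal the domain bounds")

    def weights(self) -> np.ndarray:
        """Quadrature weights w with w @ y == simpson(y, x=points).

        Simpson's rule is linear in the integrand, so the weights are
        recovered by integrating the identity's columns once.
        """
        n = len(self.points)
        return simpson(np.eye(n), x=self.points, axis=0)


@dataclass
class DissimilarityMatrix:
    """Symmetric nonnegative pairwise dissimilarities with zero diagonal."""

    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        self.ids = list(self.ids)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError(f"matrix shape {v.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValidationError("duplicate subject ids")
        asym = float(np.max(np.abs(v - v.T))) if n else 0.0
        scale = max(1.0, float(np.max(np.abs(v)))) if n else 1.0
        if asym > 1e-12 * scale:
            raise ValidationError(f"matrix not symmetric: max |D - D'| = {asym:g}")
        if np.any(np.diag(v) != 0.0):
            raise ValidationError("diagonal must be exactly zero")
        if np.any(v < 0):
            raise ValidationError("negative dissimilarity entries")

    @property
    def n(self) -> int:
        return len(self.ids)

    def select(self, ids) -> "DissimilarityMatrix":
        """Submatrix for a subset of ids, in the given order."""
        idx = [self.ids.index(i) for i in ids]
        return DissimilarityMatrix(ids=list(ids), values=self.values[np.ix_(idx, idx)])

    def offdiag(self) -> np.ndarray:
        """All ordered off-diagonal entries, row-major."""
        mask = ~np.eye(self.n, dtype=bool)
        return self.values[mask]


def infer_domain(subjects: list[Subject]) -> Domain:
    """Common domain: the smallest interval covering every observation."""
    lo = min(float(s.times[0]) for s in subjects)
    hi = max(float(s.times[-1]) for s in subjects)
    return Domain(lo, hi)


# ---------------------------------------------------------------------------
# pairwise operations


def l2_curve_distance(fit_a: SplineFit, fit_b: SplineFit, grid: QuadratureGrid) -> float:
    """Rooted integrated squared difference between two fitted curves."""
    if fit_a.domain != fit_b.domain:
        raise ValidationError("fits live on different domains")
    grid.matches(fit_a.domain)
    fa = fit_a(grid.points)
    fb = fit_b(grid.points)
    val = simpson((fa - fb) ** 2, x=grid.points)
    return float(np.sqrt(max(val, 0.0)))


def _weighted_l2(curve_a: np.ndarray, curve_b: np.ndarray, w: np.ndarray) -> float:
    diff = curve_a - curve_b
    return float(np.sqrt(max(float(w @ (diff * diff)), 0.0)))


def d_spc(
    subject_i: Subject,
    subject_j: Subject,
    domain: Domain | None = None,
    grid: QuadratureGrid | None = None,
) -> float:
    """Smoothing-parameter-commutation dissimilarity for one pair."""
    D = dissimilarity_matrices([_copy_id(subject_i, "_a"), _copy_id(subject_j, "_b")],
                               measures=("spc",), domain=domain, grid=grid)["spc"]
    return float(D.values[0, 1])


def d_ss(
    subject_i: Subject,
    subject_j: Subject,
    domain: Domain | None = None,
    grid: QuadratureGrid | None = None,
) -> float:
    """L2 distance between the two own-parameter smoothed curves."""
    D = dissimilarity_matrices([_copy_id(subject_i, "_a"), _copy_id(subject_j, "_b")],
                               measures=("ss",), domain=domain, grid=grid)["ss"]
    return float(D.values[0, 1])


def d_eucl(subject_i: Subject, subject_j: Subject) -> float:
    """Pointwise Euclidean distance; requires identical time grids."""
    _check_shared_grid([subject_i, subject_j])
    diff = subject_i.values - subject_j.values
    return float(np.sqrt(diff @ diff))


def _copy_id(s: Subject, suffix: str) -> Subject:
    # pairwise helpers must tolerate two subjects carrying the same id
    return Subject(id=f"{s.id}{suffix}", times=s.times, values=s.values)


def _check_shared_grid(subjects: list[Subject]) -> None:
    t0 = subjects[0].times
    for s in subjects[1:]:
        if len(s.times) != len(t0) or np.any(s.times != t0):
            raise ValidationError(
                "d_eucl requires identical time grids for all subjects "
                f"(subject {s.id!r} differs); use a spline-based measure for irregular data"
            )


# ---------------------------------------------------------------------------
# matrix assembly


def dissimilarity_matrices(
    subjects: list[Subject],
    measures=MEASURES,
    domain: Domain | None = None,
    grid: QuadratureGrid | None = None,
) -> dict[str, DissimilarityMatrix]:
    """Pairwise matrices for several measures sharing one set of REML fits.

    Each subject's REML problem is solved once (the expensive part); the
    commuted measure then adds two fixed-parameter refits per pair, each
    O(K^2) thanks to the cached eigendecomposition in
    :class:`~spcdist.spline.SubjectSolver`.
    """
    n = len(subjects)
    if n < 2:
        raise ValidationError("need at least 2 subjects")
    ids = [s.id for s in subjects]
    if len(set(ids)) != n:
        raise ValidationError("duplicate subject ids")
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise ValidationError(f"unknown measures: {sorted(unknown)}")
    if domain is None:
        domain = infer_domain(subjects)
    if grid is None:
        grid = QuadratureGrid.uniform(domain)
    grid.matches(domain)

    out: dict[str, DissimilarityMatrix] = {}

    if "eucl" in measures:
        _check_shared_grid(subjects)
        Y = np.vstack([s.values for s in subjects])
        out["eucl"] = DissimilarityMatrix(ids=ids, values=squareform(pdist(Y)))

    spline_measures = [m for m in measures if m in ("spc", "ss")]
    if spline_measures:
        w = grid.weights()
        if np.any(w < 0):  # non-uniform Simpson weights can go negative
            raise ValidationError("quadrature weights not nonnegative; refine the grid")
        solvers = []
        own_fits = []
        cross_mats = []
        own_curves = np.empty((n, len(grid.points)))
        for k, s in enumerate(subjects):
            try:
                solver = SubjectSolver(s, domain)
                fit = solver.fit_reml()
            except Exception as exc:
                raise type(exc)(f"subject {s.id!r}: {exc}") from exc
            cross = kernel_cross(grid.points, s.times, domain)
            solvers.append(solver)
            own_fits.append(fit)
            cross_mats.append(cross)
            own_curves[k] = solver.curve(fit, grid.points, cross)

        if "ss" in spline_measures:
            # d_SS is a plain weighted-L2 metric on the own-parameter curves
            D = squareform(pdist(own_curves * np.sqrt(w)))
            np.fill_diagonal(D, 0.0)
            out["ss"] = DissimilarityMatrix(ids=ids, values=D)

        if "spc" in spline_measures:
            D = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    cross_j = solvers[j].curve(
                        solvers[j].fit_lambda(own_fits[i].lam), grid.points, cross_mats[j]
                    )
                    cross_i = solvers[i].curve(
                        solvers[i].fit_lambda(own_fits[j].lam), grid.points, cross_mats[i]
                    )
                    d = 0.5 * (
                        _weighted_l2(own_curves[i], cross_j, w)
                        + _weighted_l2(cross_i, own_curves[j], w)
                    )
                    D[i, j] = D[j, i] = d
            out["spc"] = DissimilarityMatrix(ids=ids, values=D)

    return out


def dissimilarity_matrix(
    subjects: list[Subject],
    measure: str = "spc",
    domain: Domain | None = None,
    grid: QuadratureGrid | None = None,
) -> DissimilarityMatrix:
    """Pairwise dissimilarity matrix for a single measure."""
    return dissimilarity_matrices(subjects, measures=(measure,), domain=domain, grid=grid)[measure]
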