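"""Synthetic longitudinal data: factorial curve/noise study and irregular fixtures.

The factorial design crosses four true-curve families on t in [0, 1]

    CONST:     f(t; eta) = 3 eta
    PERIODIC:  f(t; eta) = sin(2 pi t) - t + 2 eta cos(4 pi t)
    LINEAR:    f(t; eta) = 3 t + 2 eta t
    NONLINEAR: f(t; eta) = 5 eta { (t - 0.5)^2 - 2 t (1 - t) }

with eta ~ N(1, 0.3^2) drawn independently per subject, against four
noise mechanisms driven by iid standard normal innovations xi_k:

    WN:    e_k = xi_k                                   (independent)
    AR:    e_k = 0.8 e_{k-1} + xi_k                     (stationary)
    SARMA: e_k = 0.8 e_{k-10} + 0.8 xi_{k-10} + xi_k    (cyclostationary)
    BILR:  e_k = 0.8 e_{k-1} + 0.2 xi_{k-1}
               - 0.2 e_{k-1} xi_{k-1} + xi_k            (non-stationary bilinear)

Observations are y_k = f(t_k; eta) + e_k on the shared grid
t_k = (k-1)/(K-1), K = 200 by default; 10 subjects per cell over the
full 4 x 4 design gives 160 series.  Recursions start from zero and run
a 200-step burn-in before emitting, so initial transients (decay factor
0.8^200) are negligible.  The bilinear mechanism occasionally produces
large excursions; these are intentional and not clipped.

``gen_irregular_fixture`` emulates dose-record-like panels: smooth
saturating per-subject trajectories observed on a random subset of a
daily grid, optionally with injected magnitude or shape outliers, for
exercising the outlier-detection workflow on irregular data.

Every generator is a pure function of its arguments and seed; each
subject consumes its own child RNG stream, so results do not depend on
generation order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .dissim import DissimilarityMatrix
from .exceptions import ValidationError
from .spline import Subject

__all__ = [
    "CurveModel",
    "NoiseKind",
    "NoiseMechanism",
    "TrueCurve",
    "SimulationConfig",
    "curve_value",
    "gen_noise",
    "gen_dataset",
    "true_dissimilarity",
    "true_dissimilarity_matrix",
    "gen_irregular_fixture",
]


class CurveModel(str, enum.Enum):
    CONST = "CONST"
    PERIODIC = "PERIODIC"
    LINEAR = "LINEAR"
    NONLINEAR = "NONLINEAR"


class NoiseKind(str, enum.Enum):
    WN = "WN"
    AR = "AR"
    SARMA = "SARMA"
    BILR = "BILR"


@dataclass(frozen=True)
class NoiseMechanism:
    kind: NoiseKind
    burn_in: int = 200

    def __post_init__(self) -> None:
        kind = NoiseKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if self.burn_in < 0:
            raise ValidationError("burn_in must be nonnegative")
        if kind is not NoiseKind.WN and self.burn_in < 100:
            raise ValidationError(f"{kind.value} needs burn_in >= 100 to wash out the zero start")


@dataclass(frozen=True)
class TrueCurve:
    """A latent curve f(.; eta): deterministic given (model, eta)."""

    model: CurveModel
    eta: float

    def __call__(self, t) -> np.ndarray:
        return curve_value(self.model, t, self.eta)


@dataclass(frozen=True)
class SimulationConfig:
    """Factorial study configuration (defaults are the reference design)."""

    seed: int
    models: tuple = tuple(CurveModel)
    mechanisms: tuple = tuple(NoiseKind)
    n_per_cell: int = 10
    grid_size: int = 200
    eta_mean: float = 1.0
    eta_sd: float = 0.3
    n_replicates: int = 200

    def __post_init__(self) -> None:
        object.__setattr__(self, "models", tuple(CurveModel(m) for m in self.models))
        object.__setattr__(self, "mechanisms", tuple(NoiseKind(m) for m in self.mechanisms))
        if min(self.n_per_cell, self.grid_size, self.n_replicates) <= 0:
            raise ValidationError("all counts must be positive")
        if self.eta_sd < 0:
            raise ValidationError("eta_sd must be nonnegative")

    @property
    def grid(self) -> np.ndarray:
        """Shared observation grid t_k = (k-1)/(K-1) on [0, 1]."""
        return np.linspace(0.0, 1.0, self.grid_size)


def curve_value(model, t, eta: float):
    """Evaluate a true-curve family at time(s) t in [0, 1]."""
    model = CurveModel(model)
    t = np.asarray(t, dtype=float)
    if np.any(t < -1e-12) or np.any(t > 1 + 1e-12):
        raise ValidationError("curve models are defined on t in [0, 1]")
    if model is CurveModel.CONST:
        out = np.full_like(t, 3.0 * eta)
    elif model is CurveModel.PERIODIC:
        out = np.sin(2 * np.pi * t) - t + 2 * eta * np.cos(4 * np.pi * t)
    elif model is CurveModel.LINEAR:
        out = 3.0 * t + 2.0 * eta * t
    else:  # NONLINEAR
        out = 5.0 * eta * ((t - 0.5) ** 2 - 2.0 * t * (1.0 - t))
    return out if out.ndim else float(out)


def gen_noise(mechanism: NoiseMechanism, K: int, rng: np.random.Generator) -> np.ndarray:
    """Draw K consecutive values of the noise process after burn-in."""
    if K < 1:
        raise ValidationError("K must be >= 1")
    kind = mechanism.kind
    if kind is NoiseKind.WN:
        return rng.standard_normal(K)
    total = mechanism.burn_in + K
    xi = rng.standard_normal(total)
    eps = np.zeros(total)
    if kind is NoiseKind.AR:
        for k in range(total):
            prev = eps[k - 1] if k >= 1 else 0.0
            eps[k] = 0.8 * prev + xi[k]
    elif kind is NoiseKind.SARMA:
        for k in range(total):
            e10 = eps[k - 10] if k >= 10 else 0.0
            x10 = xi[k - 10] if k >= 10 else 0.0
            eps[k] = 0.8 * e10 + 0.8 * x10 + xi[k]
    else:  # BILR
        for k in range(total):
            e1 = eps[k - 1] if k >= 1 else 0.0
            x1 = xi[k - 1] if k >= 1 else 0.0
            eps[k] = 0.8 * e1 + 0.2 * x1 - 0.2 * e1 * x1 + xi[k]
    return eps[mechanism.burn_in:]


def gen_dataset(
    config: SimulationConfig, replicate: int = 0
) -> tuple[list[Subject], list[TrueCurve]]:
    """One replicate of the factorial design.

    Returns subjects and their latent curves in matched order; cell
    order is (model, mechanism) as listed in the config, with
    ``n_per_cell`` subjects per cell.  Fully reproducible from
    ``(config.seed, replicate)``.
    """
    grid = config.grid
    n_cells = len(config.models) * len(config.mechanisms)
    children = np.random.SeedSequence([int(config.seed), int(replicate)]).spawn(
        n_cells * config.n_per_cell
    )
    subjects: list[Subject] = []
    curves: list[TrueCurve] = []
    idx = 0
    for model in config.models:
        for mech_kind in config.mechanisms:
            mech = NoiseMechanism(kind=mech_kind)
            for r in range(config.n_per_cell):
                rng = np.random.default_rng(children[idx])
                idx += 1
                eta = float(config.eta_mean + config.eta_sd * rng.standard_normal())
                curve = TrueCurve(model=model, eta=eta)
                y = curve(grid) + gen_noise(mech, config.grid_size, rng)
                subjects.append(
                    Subject(
                        id=f"{model.value}-{mech_kind.value}-{r:02d}",
                        times=grid,
                        values=y,
                    )
                )
                curves.append(curve)
    return subjects, curves


def true_dissimilarity(curve_i: TrueCurve, curve_j: TrueCurve, grid) -> float:
    """Noise-free reference dissimilarity: sum over the grid of squared
    differences of the latent curves (a sum of squares, not rooted)."""
    grid = np.asarray(grid, dtype=float)
    diff = curve_i(grid) - curve_j(grid)
    return float(np.sum(diff * diff))


def true_dissimilarity_matrix(curves: list[TrueCurve], grid, ids) -> DissimilarityMatrix:
    """All pairwise true dissimilarities on a shared grid."""
    grid = np.asarray(grid, dtype=float)
    F = np.vstack([c(grid) for c in curves])
    return DissimilarityMatrix(ids=list(ids), values=squareform(pdist(F, "sqeuclidean")))


def gen_irregular_fixture(
    n: int,
    grid_days: int = 60,
    keep_prob: float = 0.5,
    n_outliers: int = 0,
    seed: int = 0,
    outlier_kind: str = "magnitude",
) -> tuple[list[Subject], list[str]]:
    """Irregular dose-record-like panel with optional injected outliers.

    Each subject follows a smooth saturating trajectory
    ``a + b (1 - exp(-day/tau))`` plus N(0, 4^2) measurement noise,
    observed on a Bernoulli(keep_prob) subset of days 1..grid_days (at
    least 4 observations; the day subset is redrawn otherwise).
    Outlying subjects are shifted up by 10 standard deviations of the
    clean panel values ("magnitude") or reflected about the panel mean
    ("shape"); their ids are returned alongside the subjects.
    """
    if not 0 < keep_prob <= 1:
        raise ValidationError("keep_prob must be in (0, 1]")
    if n_outliers > n:
        raise ValidationError("n_outliers cannot exceed n")
    if outlier_kind not in ("magnitude", "shape"):
        raise ValidationError("outlier_kind must be 'magnitude' or 'shape'")
    master = np.random.SeedSequence(int(seed))
    pick_rng = np.random.default_rng(master)
    days = np.arange(1, grid_days + 1, dtype=float)
    children = master.spawn(n)

    raw: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(n):
        rng = np.random.default_rng(children[i])
        a = rng.uniform(20.0, 60.0)
        b = rng.uniform(-20.0, 40.0)
        tau = rng.uniform(10.0, 60.0)
        while True:
            keep = rng.random(grid_days) < keep_prob
            if keep.sum() >= 4:
                break
        t = days[keep]
        y = a + b * (1.0 - np.exp(-t / tau)) + 4.0 * rng.standard_normal(len(t))
        raw.append((t, y))

    all_values = np.concatenate([y for _, y in raw])
    sd = float(np.std(all_values))
    mean = float(np.mean(all_values))
    outlier_pos = sorted(pick_rng.choice(n, size=n_outliers, replace=False).tolist())

    subjects: list[Subject] = []
    outlier_ids: list[str] = []
    for i, (t, y) in enumerate(raw):
        sid = f"s{i:03d}"
        if i in outlier_pos:
            y = y + 10.0 * sd if outlier_kind == "magnitude" else 2.0 * mean - y
            outlier_ids.append(sid)
        subjects.append(Subject(id=sid, times=t, values=y))
    return subjects, outlier_ids
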