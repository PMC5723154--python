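"""Scoring dissimilarity measures, PAM clustering and kNN outlier detection.

Two criteria score an estimated dissimilarity matrix ``d_hat`` against
the noise-free reference ``d_true``:

* ``Q = n^-2 min_{a,b} sum_{i} sum_{j != i} (a + b d_hat_ij - d_ij)^2 / d_ij``
  -- the loss of the best affine map from estimated to true
  dissimilarities, normalised by the true scales.  The inner minimum is
  a weighted least-squares fit (weights ``1/d_ij``) solved in closed
  form; Q is zero for any affine transform of the truth.

* ``R = n^-2 sum_{i} sum_{j != i} (rhat_ij - r_ij)^2`` -- the mean
  squared discrepancy between the ranks of estimated and true
  dissimilarities over all ordered pairs (midranks on ties), zero for
  any strictly increasing transform of the truth.

Small Q and R mean a good measure.  Cluster recovery is assessed by
partitioning around medoids (PAM, classic BUILD + SWAP on the
dissimilarity matrix) and the Rand / adjusted Rand indices against the
true grouping.  Outliers are scored by each subject's average
dissimilarity to its k nearest neighbours; subjects above the standard
boxplot fence (Q3 + 1.5 IQR) of that score distribution are flagged.

``run_benchmark`` and ``run_outlier_benchmark`` drive the full
simulation pipelines end to end and return tidy data frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score, rand_score

from . import simulate
from .dissim import (
    DissimilarityMatrix,
    QuadratureGrid,
    dissimilarity_matrices,
    dissimilarity_matrix,
    infer_domain,
)
from .exceptions import ValidationError
from .simulate import CurveModel, NoiseKind, SimulationConfig

__all__ = [
    "MeasureScore",
    "ClusteringResult",
    "OutlierReport",
    "q_criterion",
    "r_criterion",
    "score_measure",
    "pam_cluster",
    "rand_indices",
    "knn_outlier_scores",
    "run_benchmark",
    "run_outlier_benchmark",
]


@dataclass(frozen=True)
class MeasureScore:
    measure_name: str
    Q: float
    R: float


@dataclass
class ClusteringResult:
    labels: np.ndarray          # cluster index 0..k-1 per subject
    medoid_ids: list            # subject ids of the k medoids
    objective: float            # sum of dissimilarities to assigned medoids


@dataclass
class OutlierReport:
    ids: list
    k_range: list
    knn_avg: np.ndarray         # n x len(k_range) average kNN dissimilarities
    flags: dict                 # k -> list of flagged subject ids

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, k in enumerate(self.k_range):
            flagged = set(self.flags[k])
            for i, sid in enumerate(self.ids):
                rows.append(
                    {"subject": sid, "k": k, "knn_avg": self.knn_avg[i, j],
                     "flagged": sid in flagged}
                )
        return pd.DataFrame(rows)


def _paired_offdiag(d_hat: DissimilarityMatrix, d_true: DissimilarityMatrix):
    if d_hat.ids != d_true.ids:
        raise ValidationError("matrices must share the same ids in the same order")
    return d_hat.offdiag(), d_true.offdiag()


def q_criterion(d_hat: DissimilarityMatrix, d_true: DissimilarityMatrix) -> float:
    """Best-affine-approximation loss, normalised by the true scales."""
    x, y = _paired_offdiag(d_hat, d_true)
    if np.any(y <= 0):
        raise ValidationError("q_criterion needs strictly positive true dissimilarities")
    w = 1.0 / y
    # weighted LS of y on (1, x): normal equations for (a, b)
    sw, swx, swxx = w.sum(), (w * x).sum(), (w * x * x).sum()
    swy, swxy = (w * y).sum(), (w * x * y).sum()
    A = np.array([[sw, swx], [swx, swxx]])
    b = np.array([swy, swxy])
    a_hat, b_hat = np.linalg.solve(A, b)
    resid = a_hat + b_hat * x - y
    n = d_hat.n
    return float((w * resid * resid).sum() / n**2)


def r_criterion(d_hat: DissimilarityMatrix, d_true: DissimilarityMatrix) -> float:
    """Mean squared rank discrepancy over all ordered pairs (midranks on ties)."""
    x, y = _paired_offdiag(d_hat, d_true)
    r_hat = rankdata(x, method="average")
    r_true = rankdata(y, method="average")
    n = d_hat.n
    return float(np.sum((r_hat - r_true) ** 2) / n**2)


def score_measure(name: str, d_hat: DissimilarityMatrix, d_true: DissimilarityMatrix) -> MeasureScore:
    return MeasureScore(measure_name=name, Q=q_criterion(d_hat, d_true),
                        R=r_criterion(d_hat, d_true))


# ---------------------------------------------------------------------------
# PAM clustering


def pam_cluster(D: DissimilarityMatrix, k: int, seed: int | None = None) -> ClusteringResult:
    """Partitioning around medoids: BUILD initialisation, then greedy SWAP
    steps until no swap lowers the objective.

    Deterministic: exact ties are broken by lowest index, so ``seed`` has
    no effect on the result and is accepted only for interface symmetry
    with stochastic clusterers.
    """
    n = D.n
    if not 2 <= k < n:
        raise ValidationError(f"need 2 <= k < n, got k={k}, n={n}")
    d = D.values

    # BUILD: first medoid minimises the total dissimilarity, later ones
    # maximise the reduction of the objective.
    medoids = [int(np.argmin(d.sum(axis=0)))]
    while len(medoids) < k:
        nearest = d[:, medoids].min(axis=1)
        gain = np.clip(nearest[:, None] - d, 0.0, None).sum(axis=0)
        gain[medoids] = -np.inf
        medoids.append(int(np.argmax(gain)))

    def objective(meds: list[int]) -> float:
        return float(d[:, meds].min(axis=1).sum())

    current = objective(medoids)
    while True:
        best_obj, best_swap = current, None
        others = [h for h in range(n) if h not in medoids]
        for pos, m in enumerate(medoids):
            for h in others:
                cand = medoids.copy()
                cand[pos] = h
                obj = objective(cand)
                if obj < best_obj - 1e-12:
                    best_obj, best_swap = obj, (pos, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
        current = best_obj

    medoids = sorted(medoids)
    labels = np.argmin(d[:, medoids], axis=1)
    final = float(d[np.arange(n), [medoids[l] for l in labels]].sum())
    return ClusteringResult(
        labels=labels, medoid_ids=[D.ids[m] for m in medoids], objective=final
    )


def rand_indices(labels, truth) -> tuple[float, float]:
    """Pair-counting Rand index and its chance-corrected adjustment."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape != truth.shape:
        raise ValidationError("label vectors must have equal length")
    return float(rand_score(truth, labels)), float(adjusted_rand_score(truth, labels))


# ---------------------------------------------------------------------------
# outlier detection


def knn_outlier_scores(D: DissimilarityMatrix, k_range) -> OutlierReport:
    """Average dissimilarity to the k nearest neighbours, for each k.

    Subjects whose score exceeds the boxplot fence Q3 + 1.5 IQR of that
    k's score distribution are flagged; raw scores are always reported
    so the distribution can also be judged visually.
    """
    k_range = sorted(int(k) for k in k_range)
    n = D.n
    if not k_range or k_range[0] < 1 or k_range[-1] > n - 1:
        raise ValidationError(f"k_range must lie within [1, {n - 1}]")
    d = D.values.copy()
    np.fill_diagonal(d, np.inf)
    csum = np.cumsum(np.sort(d, axis=1)[:, : n - 1], axis=1)
    scores = np.column_stack([csum[:, k - 1] / k for k in k_range])
    flags = {}
    for j, k in enumerate(k_range):
        col = scores[:, j]
        q1, q3 = np.percentile(col, [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
        flags[k] = [D.ids[i] for i in np.nonzero(col > fence)[0]]
    return OutlierReport(ids=list(D.ids), k_range=k_range, knn_avg=scores, flags=flags)


# ---------------------------------------------------------------------------
# end-to-end simulation benchmarks


def run_benchmark(
    seed: int,
    n_replicates: int = 20,
    models=tuple(CurveModel),
    mechanisms=(NoiseKind.WN, NoiseKind.SARMA),
    n_per_cell: int = 10,
    grid_size: int = 200,
    measures=("spc", "ss", "eucl"),
    grid_points: int = 401,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicated factorial study scoring several dissimilarity measures.

    For every replicate and noise mechanism, generates one dataset over
    the curve models, computes each measure's matrix, and records Q, R
    (against the true dissimilarities) and PAM cluster recovery (Rand and
    adjusted Rand against the curve-model grouping, k = #models).

    Returns ``(scores, cell_scores)``: per-(replicate, mechanism,
    measure) criteria, and per-cell Q values for the spline measures
    (one cell = the subjects sharing a curve model).
    """
    models = tuple(CurveModel(m) for m in models)
    mechanisms = tuple(NoiseKind(m) for m in mechanisms)
    rows, cell_rows = [], []
    for rep in range(n_replicates):
        for mech in mechanisms:
            cfg = SimulationConfig(
                seed=int(seed),
                models=models,
                mechanisms=(mech,),
                n_per_cell=n_per_cell,
                grid_size=grid_size,
                n_replicates=n_replicates,
            )
            subjects, curves = simulate.gen_dataset(cfg, replicate=rep)
            ids = [s.id for s in subjects]
            d_true = simulate.true_dissimilarity_matrix(curves, cfg.grid, ids)
            domain = infer_domain(subjects)
            grid = QuadratureGrid.uniform(domain, grid_points)
            mats = dissimilarity_matrices(subjects, measures=measures, domain=domain, grid=grid)
            truth_labels = np.repeat(np.arange(len(models)), n_per_cell)
            for name in measures:
                score = score_measure(name, mats[name], d_true)
                clust = pam_cluster(mats[name], k=len(models))
                rand, ari = rand_indices(clust.labels, truth_labels)
                rows.append(
                    {"replicate": rep, "mechanism": mech.value, "measure": name,
                     "Q": score.Q, "R": score.R, "rand": rand, "ari": ari}
                )
            for m_idx, model in enumerate(models):
                cell_ids = ids[m_idx * n_per_cell: (m_idx + 1) * n_per_cell]
                d_true_cell = d_true.select(cell_ids)
                for name in measures:
                    if name == "eucl":
                        continue
                    cell_rows.append(
                        {"replicate": rep, "mechanism": mech.value, "model": model.value,
                         "measure": name,
                         "Q": q_criterion(mats[name].select(cell_ids), d_true_cell)}
                    )
    return pd.DataFrame(rows), pd.DataFrame(cell_rows)


def run_outlier_benchmark(
    seed: int,
    n_runs: int = 40,
    n: int = 50,
    grid_days: int = 60,
    keep_prob: float = 0.5,
    k: int = 3,
) -> pd.DataFrame:
    """Repeated irregular fixtures with one injected magnitude outlier.

    For each run, builds the commuted-dissimilarity matrix, scores every
    subject by its average dissimilarity to the ``k`` nearest
    neighbours, and records whether the injected subject has the top
    score and whether the boxplot fence flags it.
    """
    rows = []
    child_seeds = np.random.SeedSequence(int(seed)).generate_state(n_runs) % (2**31)
    for run in range(n_runs):
        subjects, outlier_ids = simulate.gen_irregular_fixture(
            n=n, grid_days=grid_days, keep_prob=keep_prob, n_outliers=1,
            seed=int(child_seeds[run]),
        )
        D = dissimilarity_matrix(subjects, measure="spc")
        report = knn_outlier_scores(D, [k])
        scores = report.knn_avg[:, 0]
        top_id = D.ids[int(np.argmax(scores))]
        rows.append(
            {"run": run, "outlier": outlier_ids[0], "top_scorer": top_id,
             "top_hit": top_id == outlier_ids[0],
             "flagged": outlier_ids[0] in report.flags[k]}
        )
    return pd.DataFrame(rows)
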