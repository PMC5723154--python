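# Methods

## Model

Each subject i contributes observations `y_ik = f_i(t_ik) + ε_ik`,
`k = 1..K_i`, at strictly increasing times inside a common interval
`[T_L, T_U]`, with iid Gaussian noise `ε_ik ~ N(0, σ²)` and a latent
smooth curve `f_i`. The curve estimate is the natural cubic smoothing
spline, obtained through its mixed-model form

    y = Xβ + u + ε,   u ~ N(0, σ_u² Ψ),   ε ~ N(0, σ² I),

where X has columns (1, t) and Ψ is the integrated-truncated-linear
(integrated Wiener) kernel computed on *normalised* time
`t~ = (t − T_L)/(T_U − T_L)`:

    ψ(s, t) = s~²(3 t~ − s~)/6   for s~ ≤ t~  (symmetric).

Because the kernel is normalised, Ψ — and hence the smoothing parameter
λ = σ²/(K σ_u²) — is invariant to affine changes of the time axis; λ is
dimensionless and lives on the normalised scale (the raw-axis penalty
differs only by the constant factor `(T_U − T_L)³` absorbed into λ).
For fixed λ the BLUP of this model equals the penalized-spline
minimiser; the test suite verifies this against an independent banded
Green–Silverman solver to ~1e−10 relative.

### REML fitting

The variance ratio θ = σ_u²/σ² is estimated by maximising the profiled
restricted likelihood: with `W = θΨ + I`, β̂ is the GLS estimate,
`σ̂² = RSS_W/(K − 2)` (two fixed-effect columns), and

    ℓ_R(θ) = −½ [ (K−2) ln(2π σ̂²) + ln|W| + ln|X′W⁻¹X| + (K−2) ].

Optimisation is bounded scalar (Brent) over `log10 θ ∈ [−8, 8]` with
tolerance 1e−8; a boundary hit (e.g. exactly linear or noise-free data)
is clipped with a `SmoothingBoundaryWarning`, never a silent failure.
Each subject's Ψ is eigendecomposed once (O(K³)) so that every criterion
evaluation and every subsequent fixed-λ refit is O(K²); negative
eigenvalues of order machine-epsilon are clipped to zero. Off-grid
prediction uses the BLUP cross-covariance `f̂(t) = β̂₀ + β̂₁t +
Σ_k ψ(t, t_k) c_k` with `c = θ(θΨ + I)⁻¹(y − Xβ̂)`, which continues
linearly beyond the last observation, as a natural spline must; no
extrapolation outside `[T_L, T_U]` is allowed.

A caveat established while validating: the integrated-Wiener random
effect has only a handful of eigencomponents above the noise floor
(about five at K = 200), so θ̂ from a single subject carries
chi-square-like realisation noise with few degrees of freedom. REML is
median-accurate at strong signal but individual θ̂ scatter over an
order of magnitude; the commuted dissimilarity is designed to be robust
to exactly this uncertainty. The fitted *curves* agree with mgcv's REML
`gam` to ~1e−3 (basis difference) on shared data.

## Dissimilarities

* `d_SPC(i,j) = ½[‖f̂_i(·;λ̂_i) − f̂_j(·;λ̂_i)‖₂ + ‖f̂_i(·;λ̂_j) − f̂_j(·;λ̂_j)‖₂]`
* `d_SS(i,j) = ‖f̂_i(·;λ̂_i) − f̂_j(·;λ̂_j)‖₂` (own parameters, no commutation)
* `d_EUCL(i,j) = √Σ_k (y_ik − y_jk)²` — only defined when all subjects
  share one grid; requesting it on irregular data is an error by design.

L2 integrals are approximated by composite Simpson quadrature on a
uniform 401-point grid spanning the domain (configurable; ≥101 points
enforced). Doubling the grid moves d_SPC by well under 0.1% on smooth
fits. Matrix assembly solves each subject's REML problem once (n REML
solves) and adds two O(K²) fixed-λ refits per pair for d_SPC; cross fits
are recomputed per pair rather than cached, trading memory for
simplicity. The dataset domain defaults to the smallest interval
covering all observations. Subjects with fewer than four observations
are rejected up front. Nonnegativity, zero-on-identity and symmetry hold
for all three measures; the triangle inequality is not guaranteed and
not needed by PAM or kNN scoring.

## Synthetic data

The factorial generator reproduces a standard benchmark design: curve
families CONST `3η`, PERIODIC `sin 2πt − t + 2η cos 4πt`, LINEAR
`3t + 2ηt`, NONLINEAR `5η{(t−0.5)² − 2t(1−t)}` with `η ~ N(1, 0.3²)`
per subject, crossed with noise mechanisms WN (iid N(0,1)), AR(1)
(φ = 0.8), seasonal ARMA at period 10 (`ε_k = 0.8ε_{k−10} + 0.8ξ_{k−10}
+ ξ_k`) and a non-stationary bilinear recursion, on the shared grid
`t_k = (k−1)/(K−1)`, K = 200, 10 subjects per cell (160 series over the
full 4×4 design). Recursions start at zero with a 200-step burn-in
(transients decay as 0.8^200 ≈ 1e−20); the bilinear process's occasional
large excursions are left unclipped, as they are part of the mechanism.
Each subject draws from its own seed-derived RNG stream, so a cell's
data do not depend on generation order.

The irregular fixture emulates dose-record panels: saturating
trajectories `a + b(1 − e^{−day/τ})` with `a ~ U(20,60)`,
`b ~ U(−20,40)`, `τ ~ U(10,60)` days and N(0,4²) measurement noise,
observed on a Bernoulli(keep_prob) subset of a daily grid (≥4 visits
enforced by redraw). Injected outliers are shifted by +10 panel SDs
(magnitude) or reflected about the panel mean (shape). What this
generator does **not** emulate: informative dropout, censoring-by-death,
discretised dose levels, or phase/warping variation — conclusions from
passing tests transfer to real panels only insofar as those features are
absent or mild.

## Evaluation

`Q = n⁻² min_{a,b} Σ_{i≠j} (a + b d̂_ij − d_ij)²/d_ij` scores the best
affine approximation of the estimated to the true dissimilarities
(`d_ij` is the noise-free sum of squared curve differences over the
grid, unrooted); the minimum is an exact weighted least-squares solve,
with b unconstrained. `R = n⁻² Σ_{i≠j} (r̂_ij − r_ij)²` compares ranks
over all *ordered* pairs, with midranks on ties (ties have probability
zero on continuous data but occur in tests; ordered-versus-unordered
only changes a constant factor). Q requires all true off-diagonal
dissimilarities to be strictly positive.

PAM is the classic BUILD + steepest-descent SWAP on the dissimilarity
matrix; it is fully deterministic (exact ties broken by lowest index —
the `seed` argument exists only for interface symmetry). Its objectives
were verified identical to R's `cluster::pam` on 50 planar instances
(5e−15 agreement); like any local optimiser it misses the global
k-medoids optimum on a minority of unstructured instances (9/50 at
n=20, k=2, worst gap ~11%). Rand and adjusted Rand indices come from
scikit-learn and are cross-checked against pair enumeration in the
tests.

Outlier scores are each subject's mean dissimilarity to its k nearest
neighbours, for a range of k; a subject is flagged when its score
exceeds Q3 + 1.5·IQR of that k's score distribution. The fence
automates what is naturally a visual boxplot judgement, so raw scores
are always exported alongside the flags.

## Problem sizes

The packaged benchmark (`run_benchmark`) uses 20 replicates of the
4-model × {WN, SARMA} design with 10 subjects per cell and K = 200 —
large enough that the mean adjusted Rand, Q and R orderings between
d_SPC, d_SS and d_EUCL are stable, and small enough to run in about a
minute. The outlier benchmark uses 40 fixtures with n = 50, a 60-day
grid at 50% retention and one +10 SD magnitude outlier. These are the
defaults behind `scripts/acceptance.py`.

## Known limitations

- Gaussian iid noise is assumed within the fit; dependent noise enters
  only through the simulation mechanisms (the REML spline is known to be
  robust to moderate mis-specification, and the benchmark quantifies the
  effect on clustering).
- Dense O(K³) linear algebra per subject: fine for K up to a few
  hundred; very long series would need the banded spline algorithms.
- λ estimation is noisy per subject by the nature of the problem (see
  REML caveat above); d_SS inherits this fully, d_SPC partially by
  construction.
- No curve alignment/warping: subjects are compared on the absolute time
  axis.
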