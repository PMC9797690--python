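# Methods

`ecdcm` estimates resting-state effective connectivity — the directed
coupling matrix of a small brain network — from BOLD time series, and
carries the estimates through a group-level hierarchical analysis and
downstream frequentist statistics. This note documents the generative
model, the estimators, the synthetic study design, and the numerical
choices, together with what the validation experiments do and do not
demonstrate.

## Generative model

**Neuronal level.** Node activity follows the linear stochastic
differential equation

    dx/dt = A x + C u + v,

with `A[i, j]` (Hz) the influence of node *j* on node *i* (directions run
from columns to rows). In resting state the exogenous input `u` and any
modulatory matrices `B` are identically zero; the types carry them so the
same machinery extends to task designs, but they are out of scope here.
The endogenous fluctuation `v` has a power-law spectral density
g(f) = α·f^(−β) per node (two-sided, units signal²/Hz); β = 0 is white
noise of intensity α, and then the stationary covariance solves the
Lyapunov equation A·Σ + Σ·Aᵀ + α·I = 0, which the test-suite uses as an
oracle. Stability (all eigenvalues of `A` with negative real part) is
enforced everywhere.

**Hemodynamic level.** Each node drives an independent Balloon model:
vasodilatory signal s, inflow f, venous volume v and deoxyhemoglobin q,

    ds/dt = ε·x − κ·s − γ·(f − 1)
    df/dt = s
    τ·dv/dt = f − v^(1/α)
    τ·dq/dt = f·E(f, E₀)/E₀ − v^(1/α)·q/v,   E(f, E₀) = 1 − (1 − E₀)^(1/f)

with the static BOLD readout

    y = V₀ [ k₁(1 − q) + k₂(1 − q/v) + k₃(1 − v) ].

Defaults are the published constants of the generalised BOLD signal
model: κ = 0.64 s⁻¹, γ = 0.32 s⁻¹, τ = 2 s, α = 0.32, E₀ = 0.4,
V₀ = 0.04, with k₁–k₃ computed for a 3 T scanner at 30 ms echo time
(θ₀ = 80.6 s⁻¹, r₀ = 110 s⁻¹, intra/extravascular ratio 0.47). All are
configurable fields of `HemodynamicParams`.

**Spectral prediction.** The data feature is the Hermitian cross-spectral
density (CSD) over positive frequencies below Nyquist = 1/(2·TR). The
model-implied CSD uses the transfer function of the linearised system:

    S_y(f) = |h(f)|² · H(f) G_v(f) H(f)ᴴ + G_e(f)·I,

where H(f) = (2πi f·I − A)⁻¹ and h(f) is the scalar hemodynamic transfer
obtained by numerically linearising the Balloon equations about their
resting fixed point. The linearisation is accurate in the small-
fluctuation regime; the default fluctuation amplitude (α = 10⁻³,
neuronal standard deviation a few per cent) keeps simulations inside it,
and the spectral-oracle experiment verifies analytic-vs-simulated
agreement within 10 % there. Larger amplitudes excite Balloon
nonlinearities that the linear predictor does not capture.

## Subject-level inversion (`SpectralDCM`)

The latent parameter vector contains the off-diagonal `A` entries
(direct scale), self-connections as a_ii = −0.5·exp(θ_ii) (guaranteeing
a negative diagonal), log-scalings of the fluctuation and observation
noise amplitudes plus additive offsets on their exponents, and — by
default — tight log-scalings of κ and τ. Priors are conventional
shrinkage priors: N(0, 1/64) on coupling and noise latents, N(0, 1/256)
on the hemodynamic latents.

Estimation is variational Laplace: a Gaussian posterior q = N(μ, Σ)
maximising the free energy

    F = ⟨log p(data | θ)⟩_q − KL(q ‖ prior),

with an independent Gaussian likelihood on the stacked real and
imaginary CSD entries and a single log-precision hyperparameter λ
updated by EM. μ is updated by Gauss–Newton steps with
Levenberg–Marquardt damping; a candidate step is accepted only if the
fully recomputed F does not decrease, so the recorded free-energy trace
is non-decreasing by construction. Convergence is declared after three
consecutive |ΔF| < 10⁻⁴, with a cap of 128 iterations. Derivatives are
central finite differences (step 10⁻⁴ on the latent scale), evaluated in
a single vectorised batch per iteration. Proposals with unstable `A` are
rejected through the damping loop.

The CSD itself is estimated by Welch cross-periodograms (two-sided
density convention: white noise of variance σ² sampled at TR has density
σ²·TR), optionally Daniell-smoothed across adjacent bins and decimated.
The default inversion grid (segment length 64, span-3 smoothing, 6 bins
in 0.008–0.1 Hz) decimates by the smoothing span so retained bins are
approximately independent — treating smoothed, overlapping bins as
independent observations overstates the likelihood precision and makes
the posterior overconfident, which the recovery experiment's 2-SD
coverage check would expose. A multivariate-autoregressive spectral
estimator is available as an alternative (`SpectralConfig.method="var"`).

## Group level (`PEB` + BMR)

Subjects are pooled in a two-level linear-Gaussian model: subject
parameters are a design-matrix combination of group effects plus an
i.i.d. random effect with a single between-subject log-precision γ, and
the group effects carry a N(0, 1/64) shrinkage prior. Before pooling,
each subject's posterior is converted back to its likelihood kernel by
subtracting the prior precision (precision Λ = Σ⁻¹ − S₀⁻¹, mean
Λ⁻¹(Σ⁻¹μ − S₀⁻¹m₀), with a floor on Λ's eigenvalues for directions the
data did not inform). This removes first-level shrinkage bias — pooling
raw posterior means systematically underestimates group effects — while
the inflated variances of weakly informed directions are down-weighted
naturally by the marginal covariance. γ is optimised by maximising the
marginal likelihood (β integrated out) under a weak N(4, 16) hyperprior;
β then has a closed-form Gaussian posterior.

**Bayesian model reduction.** For any reduced prior, the change in log
evidence and the reduced posterior follow from Gaussian algebra alone
(verified against 1-D quadrature to ~10⁻⁶ nats). The model search
switches each group-mean connection off (prior variance 10⁻⁸, mean 0):
with at most 8 parameters the 2^p model space is scored exhaustively;
above that, connections whose removal improves the evidence are greedily
pruned and the 8 parameters with the smallest evidence margins are then
enumerated exhaustively. Posterior connection probabilities and strengths
come from Bayesian model averaging with softmax(evidence) weights;
self-connections are reported back-transformed to their real values
(delta-method variances). Thresholded networks retain connections with
probability above a level in {0, 0.5, 0.75, 0.95, 0.99}; the 0 level is
the no-threshold condition.

Per-group PEB fits (one per clinical group) are the default, mirroring
group-wise reporting; a design matrix with group regressors is equally
supported.

## Downstream statistics

`anova_connections` runs a one-way ANOVA per connection on subject-level
strengths (the unthresholded subject posterior means), then all pairwise
group contrasts with pooled-error standard errors and Bonferroni-adjusted
significance (family = the 6 pairwise comparisons within a connection,
capped at 1). `stepwise_regression` is SPSS-style forward selection
(entry p < 0.05, removal p > 0.10 by default) of a cognitive score on
connection strengths, reporting standardized β, per-predictor p, and the
final model's R², F and p. Safeguards: an iteration cap and a
visited-model set stop the classic stepwise cycling pathology, and a
numerically perfect fit short-circuits with R² = 1.

## Synthetic cohort

The generator emulates a four-group AD-progression study: groups CN /
EMCI / LMCI / AD of sizes 31/34/31/34; TR = 3 s; 140 volumes acquired
per subject of which the first 10 are discarded (130 retained). The
ground-truth 7-node coupling matrix is the reference CN group matrix
(`BASE_A`; nodes L-PCC, R-PCC, L-ACC, R-ACC, L-dlPFC, R-dlPFC, mPFC).
Disease is modelled as a multiplicative attenuation of the off-diagonal
couplings — defaults (1.0, 0.6, 0.3, 0.05) along CN→EMCI→LMCI→AD — plus
an optional additive shift on self-connections. Each subject adds a
N(0, 0.03²) random effect to every coupling entry, with stability-
rejected resampling (0.03 Hz attributes roughly half of the subject-level
connection variance implied by the reference pairwise standard errors to
true heterogeneity, the rest to estimation noise). BOLD series come from
the full nonlinear forward model (Euler–Maruyama at dt = 0.05 s, RK4
Balloon, 60 s burn-in) with power-law measurement noise.

Cognitive scores are linear readouts of the subject's coupling matrix
plus Gaussian noise. The default MMSE-like and CDR-like models load
uniformly on the off-diagonal couplings with the weight solved so that
the CN and AD group means hit the reference demographics (29.32 and
19.80 for MMSE; 0.00 and 1.02 for CDR); intermediate group means then
follow the attenuation schedule linearly (≈25.4 and 22.4 for MMSE),
which is steeper than the reference profile — a single linear
score-on-connectivity model cannot reproduce the strongly nonlinear
MMSE trajectory, and we prefer anchored endpoints over per-group
intercepts that would decouple scores from connectivity. Scores are not
floored at zero (a CDR-like draw can be slightly negative).

What the generator does **not** emulate: scanner artefacts, head motion,
physiological confounds, spatial heterogeneity inside ROIs, non-Gaussian
random effects, and site effects. Passing tests therefore demonstrate
correctness of the estimation machinery under the model's own
assumptions, not robustness to real-data violations of them.

## Validation experiments (`ecdcm.experiments`)

Problem sizes were chosen so each experiment carries statistical meaning
at desk scale:

* **Lyapunov oracle** — a fixed well-conditioned 3-node system
  (eigenvalues ≈ −0.7…−1.2 Hz), 10⁵ Euler–Maruyama steps at dt = 0.05 s
  with the seed varying the noise realisation; empirical stationary
  covariance vs. the Lyapunov solution (≤ 5 % relative Frobenius error;
  the residual is finite-sample variance plus O(dt) integrator bias).
* **Spectral oracle** — 10⁴ BOLD volumes; Welch estimate (segment 128,
  75 % overlap, span-7 smoothing, 0.01–0.1 Hz) vs. the analytic CSD
  (≤ 10 %; the floor is Welch estimator variance, which does not average
  down across bins in a relative-Frobenius metric).
* **Recovery** — one 20-subject group, 4 nodes (L-PCC, R-PCC, L-dlPFC,
  mPFC submatrix), 1500 retained volumes, negligible measurement noise:
  ≥ 90 % of off-diagonal couplings within 2 posterior SD of each
  subject's own truth, and pooled Spearman rank correlation ≥ 0.7.
  The long runs are what "high SNR" means here: at the study's own 130
  volumes the per-subject posterior is strongly prior-dominated.
* **Progression** — the four-group design at reduced scale: 4 nodes with
  a strong-signal ground truth (uniform 0.08 Hz off-diagonals — the
  regime in which full network recovery is statistically attainable),
  16 subjects/group, 1000 retained volumes, attenuation (1.0, 0.6, 0.3,
  0.05), 10 replicates. Checks that the CN-like group is fully connected
  at the 0.5 threshold and that the 0.99-threshold edge count is
  non-increasing across stages. With the paper-scale couplings (many
  below 0.04 Hz) and 130 volumes, per-connection group evidence is too
  weak for fullness at any feasible group size — the qualitative
  dwindling pattern survives, the ceiling effect does not.
* **Statistics oracles** — ANOVA F against explicit sums of squares
  (10⁻¹⁰), F = t² for two groups, stepwise vs. exhaustive best-subset,
  planted-predictor entry in ≥ 80 % of 50 replicates.
* **ROI oracle** — sphere means against a brute-force voxel loop, exact.
* **Determinism** — the full synthetic pipeline (4 nodes, 12 subjects)
  run twice with one seed produces byte-identical text outputs; no
  timestamps enter any artefact, and manifest paths are stored relative
  to the manifest.

## Numerical choices and edge cases

* Euler–Maruyama for the neuronal SDE (dt ≤ 0.1 s required, 0.05 s
  default — at 0.1 s the O(dt) variance inflation is a few per cent,
  visible against the spectral oracle); exact matrix-exponential stepping
  for noise-free runs; classical RK4 for the Balloon equations with a
  floor of 10⁻⁶ on f and v against fractional-power blow-up.
  Integrator loops are numba-compiled, with a pure-Python fallback.
* Endogenous and measurement noise are synthesised spectrally (Gaussian
  Fourier coefficients scaled to the target density; DC bin zeroed),
  which is exact for the power-law family including white noise.
* All randomness flows from `numpy.random.default_rng` seeds; a cohort,
  a pipeline run, and every experiment are reproducible from one seed.
* Degenerate inputs raise typed exceptions (`StabilityError`,
  `DataError`, `ConfigError`, …) mapped to distinct CLI exit codes
  (2 config / 3 data / 4 numerical).
* An inversion that exhausts its iteration budget returns a flagged
  (`converged=False`) result rather than raising; BMR refuses prior
  reductions that would make the reduced posterior precision indefinite.

## Known limitations

* Directionality of reciprocal connections is weakly identified from
  CSDs at TR = 3 s; transpose-pair estimates are correlated, and the sum
  of a reciprocal pair is recovered better than the difference.
* The likelihood treats CSD features as independent Gaussians; the
  decimated default grid approximates this, but heavy smoothing without
  decimation yields overconfident posteriors.
* Hemodynamic parameters beyond κ and τ are fixed; subject-wise
  hemodynamic variability is not modelled.
* The greedy model search is exact only up to the pruning heuristic;
  parameters pruned before the exhaustive stage receive probability 0
  rather than a graded value.
* Scores are linear in connectivity; see the cohort section for what
  that implies about intermediate group means.
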