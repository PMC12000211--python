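# Methods

## The model

Two-alternative choice is modelled as stochastic evidence accumulation in a
2-D plane. Each option is a unit direction vector; the angle γ between the
two vectors is itself a parameter of the model. Evidence increments are
bivariate normal with mean `|μ| (cos φ, sin φ) dt` and isotropic covariance
`σ² dt I`. After every increment the state is projected onto each option
vector; the first projection to reach the threshold θ triggers the
corresponding choice, and the response time adds a non-decision time τ.

Two familiar model classes are special cases of the geometry:

* **γ = π** — the options are polar opposites. The projection onto A is the
  negative of the projection onto B, so the process reduces to a 1-D
  diffusion between absorbing boundaries ±θ: the diffusion decision model
  (relative evidence). The signed balance drift is δ = |μ| cos φ.
* **γ = π/2** — the options are orthogonal. The two projections are
  independent diffusions racing to θ: an accumulator model (absolute
  evidence).

Intermediate angles interpolate continuously; γ thereby measures how
similar the two choice options are in the decision-maker's representation,
and estimating γ is a graded form of model identification.

### Projection-space simulation

The stopping rule consults only the projection pair (p_A, p_B), which is
itself a bivariate diffusion whose noise components have correlation
cos γ. The engine (`first_passage`) therefore steps the projections
directly:

    p_A += d_A dt + σ√dt z₁
    p_B += d_B dt + σ√dt (cos γ · z₁ + sin γ · z₂)

with d_A = |μ| cos φ and d_B = |μ| cos(γ − φ). This is exact up to time
discretisation, needs no per-γ special cases, and vectorises over trials
with arbitrary per-trial parameters (the engine compacts finished trials
out of its working arrays, which is what makes 10⁶–10⁷-trial corpora
tractable on one core).

When comparing the diffusion class against accumulators, the drift
magnitude is multiplied by √2: at γ = π the projection of a drift step onto
an option vector is shorter than at γ = π/2 by that factor, and the scaling
keeps the classes matched in effective signal.

### Start points and drift variability

Model classes disagree about start-point distributions, and the package
keeps each class's own convention: the diffusion class draws the starting
*balance* uniformly from [−s_v, +s_v]; the accumulator and gsr classes draw
each accumulator's starting support independently from U(0, s_v), making
the starting balance triangular and peaked at zero. s_v = 0 (the default
outside the application model) starts every trial at the origin.

Across-trial drift variability ν is a zero-mean Gaussian perturbation
resampled each trial: on δ for the diffusion class (the classical DDM
convention), independently on each accumulator's drift for the accumulator
class, and on the magnitude |μ| for free-γ models, which keeps the
perturbed drift a genuine 2-D vector at any angle.

## Priors and parameters

Simulated participants are drawn from

| parameter | prior | mean | units |
|---|---|---|---|
| φ (drift direction) | U(0, 1) | .5 | radians |
| \|μ\| (drift magnitude) | Gamma(2, 2) | 4 | evidence/s |
| θ (threshold) | Gamma(2, 2) | 4 | evidence |
| τ (non-decision time) | Gamma(1, .4) | .4 | s |
| ν (drift variability) | Gamma(1, 1) | 1 | evidence/s |
| γ (option angle, when free) | U(0, π) | π/2 | radians |

Gamma distributions are in shape–scale form. σ is fixed at 1 as the scaling
convention that makes the remaining parameters identifiable. φ is treated
as radians; this spans slightly more than half of the first quadrant and is
configurable. The start-point half-width s_v has no published prior in the
application model; the package uses U(0, θ_min/2) and documents it as a
placeholder.

## Experimental designs and the condition mapping

The application design crosses 2 coherence × 3 match × 2 discriminability
levels (12 conditions, 10 trials each, 120 trials per participant; the
default fixture set of 34 participants gives 4080 trials). Factors map onto
model components rather than onto a monolithic drift rate: coherence →
|μ|, match → φ, discriminability → γ (with θ also free per discriminability
level, since option separability is visible before stimulus onset). The
resulting application mapping has 14 free parameters: 3 φ + 4 |μ|
(coherence × the two informative match levels; mean drift is pinned to 0 in
the ambiguous lowest-match condition) + 2 θ + 2 γ + shared τ, ν, s_v.

For the racing-accumulator version of the application model, both drifts
come from a single parameter: the probability that a stimulus sample
favours the correct option is computed under a wrapped-normal orientation
model (SD set by coherence, option separation by discriminability, mean
offset by match), multiplied by |μ|, and per-accumulator variability is
added.

## Summary vectors

Networks consume fixed-layout summaries, not trials. Single condition: 15
slots (mean accuracy; minimum and mean RT for corrects and errors; RT
quantiles .1/.3/.5/.7/.9 per response type). Multi-condition: 8 slots per
condition (mean accuracy, mean correct/error RT, the five quantiles of the
correct-RT distribution), i.e. 96 slots for the application design — the
per-condition layout omits minimum RT, and the five quantiles are taken
once per condition, which is the only reading consistent with 8 × 12 = 96.
Quantiles use linear interpolation of order statistics (type-7). Cells with
no error (or no correct) trials copy the missing side from the present side
and flag the vector; censored trials are excluded from all summaries.

## Accumulated-evidence profiles

The profile is the distribution, over trials, of the signed balance of
evidence present when the trial ends, optionally divided by the number of
samples. Relative-evidence stopping under-samples moderate evidence, so the
γ = π profile is bimodal with a central gap and inflated variance, while
the γ = π/2 profile tracks the generating stimulus distribution closely.

Profile-shape statements are granularity-dependent: they are sharpest in
the *discrete-sample* regime, where each step is one stimulus sample and θ
and σ are expressed in per-sample units (the engine runs this regime with
`dt = 1`). In the fine-dt continuous regime the normalized balance is
±θ/T whose branches are heavy-tailed in 1/T, which depresses
kurtosis-based bimodality measures (B ≈ 0.17 for the sweep below) without
changing the visual bimodality. The bimodality sweep reported by the
acceptance script therefore uses per-sample units (drifts {0, .5, 1},
θ = 1, σ = 1 per sample), where it reaches B ≈ 0.37.

For the continuous 1-D diffusion a closed form exists: the process stops at
exactly ±θ, so the normalized end-of-trial evidence is ±θ/t weighted by the
first-passage density at the corresponding boundary
(`ddm_continuous_profile`). The density itself (`wiener_fpt_density`) uses
the standard small-time/large-time series with per-time-point selection of
the cheaper representation at absolute tolerance 1e-7.

Sarle's bimodality coefficient is B = (g² + 1) / (k + 3(n−1)²/((n−2)(n−3)))
with bias-adjusted sample skewness g and excess kurtosis k; B is location-
and scale-invariant, ≈ 1/3 for normal samples, 5/9 for uniform, → 1 for a
balanced two-point distribution.

K-L identification of γ: divergences from the observed profile to simulated
profiles on a γ grid (π/8 … π by default), cubic spline through (γ, KL),
minimiser found by dense evaluation (10⁴ points) inside the grid range;
edge minimisers carry a boundary flag. Histograms default to 61 equal-width
bins on a shared range; the reference is additively smoothed by
1/(n·bins) only when it has empty bins where the observed profile has mass,
so identical histograms give exactly zero.

## Amortized networks

Classification (diffusion = 0 vs accumulator = 1) and estimation networks
are fully connected multilayer perceptrons: three hidden layers of 128
rectified units, standardized inputs, Adam, early stopping on a 10%
validation split with patience 10 (all configurable via `NetSpec`). These
settings are the package's own declared choices, not a reconstruction of
any particular published architecture. Estimation targets are
log-transformed, so exponentiating the outputs guarantees positive
estimates; option-angle estimates are clipped into (0, π].

Corpus sizes are configurable. The test suite and acceptance script use
reduced scales chosen as the package's own desk-scale defaults: 2×10⁴
participants per class (N = 100 trials) for the single-condition
classifier, 10⁴ participants (N = 200) for the estimator, and 4×10³ per
class per trial count for the monotonicity property. Full-scale corpora
(10⁵–5×10⁵ per class, where the 12-condition classifier reaches >98%
accuracy) run through exactly the same code path via `--n-sims`.

## Synthetic data

The fixture generator emulates the *shape* and generative structure of a
12-condition orientation-discrimination study: factorial condition labels,
per-participant parameters from the stated priors, model classes with known
ground truth, censoring flags. It does not emulate real-data features such
as lapses, post-decision stimulus frames contaminating traces,
session/practice effects, or parameter correlations across participants —
so passing tests demonstrate internal consistency and recoverability under
the model, not fidelity to any particular empirical dataset.

## Numerical choices

* Euler step dt = 0.001 s, horizon t_max = 10 s; first crossing on the
  discrete grid without sub-step interpolation. Grid crossing has an
  O(√dt) boundary-overshoot bias (~0.006 in choice probability at
  dt = 0.001 for θ = 1), verified to shrink toward the closed form as dt is
  refined; tolerance-based tests use 3 Monte-Carlo SEs.
* Trials that reach t_max are flagged censored, never raised; summaries and
  profiles exclude them, and corpus generation resamples participants with
  no uncensored trials (counts logged).
* Same-step double crossings resolve to the larger projection; exact ties
  flip a fair coin from the trial's stream.
* Every stochastic function takes an explicit `numpy.random.Generator`; no
  global state. Derived integer seeds stay below 2³¹.

## Limitations

* Reduced-scale corpora recover the qualitative results (classifier above
  the 74% band floor, γ recovery r > 0.5, posterior/γ̂ anti-correlation)
  but not the full-scale 98%+ confusion matrix, which requires 5×10⁵
  participants per class.
* The summary layouts are the two fixed ones; no defective-CDF or
  histogram-bin summaries.
* No leaky/competing accumulation, collapsing boundaries, urgency signals,
  multi-alternative choice, or posterior-uncertainty (dropout/Bayesian)
  estimation.
* K-L identification needs large trial counts; for sparse data the
  bimodality coefficient and the networks are the practical routes.
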