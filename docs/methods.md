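# Methods

## Model and assumptions

Inter-movement intervals in a self-paced repetitive task are treated as
reaction times relative to an endogenous timing signal. Each movement is
modelled as a LATER race: a decision variable rises linearly from baseline
at rate *r* ~ N(μᵣ, σᵣ²), drawn independently per trial, and triggers the
movement after covering the threshold distance θ. The interval T = θ/r is
recinormal: promptness P = 1/T is N(μₚ, σₚ²) with μₚ = μᵣ/θ, σₚ = σᵣ/θ.
Only the promptness-scale parameters are identifiable from interval data;
the package convention fixes θ = 1 when mechanistic race parameters are
requested — ratios of θ across conditions remain meaningful and are the
quantity of scientific interest.

The promptness normal is **untruncated**. Its negative mass corresponds to
races that never finish (no response) and is ignored in the likelihood, the
classic treatment that keeps the MLE closed-form (sample mean and divisor-n
SD of 1/T). A `reliable` flag on the parameters is lowered when
μₚ/σₚ < 2 — i.e. when more than ~2.3% of promptness mass lies at or below
zero and the approximation starts to matter. At the movement rates this
package targets (≈3 Hz with CV ≈ 0.15, so μₚ/σₚ ≈ 6.7) the ignored mass is
~10⁻¹¹.

## Reciprobit coordinates

The empirical transform plots sorted −1/T against the probit of the Hazen
plotting position (i − ½)/n. Hazen positions avoid infinite probits at the
extremes; exact duplicate abscissae (which arise under frame quantization)
are collapsed to one point at the mean of their plotting positions, keeping
both coordinates strictly increasing. Theoretical recinormal quantiles at
the same positions are exactly linear (residuals at machine precision),
which the tests use as the oracle for the transform.

## Joint two-condition fits

All four models are maximum-likelihood on the promptness scale, with the
−2·Σ log tᵢ Jacobian added so reported log-likelihoods are genuine
recinormal likelihoods (the Jacobian is model-independent and cancels in
every BIC difference).

- **null** (k = 2): pooled mean and ML variance of the combined sample.
- **unconstrained** (k = 4): per-condition mean and ML variance.
- **shift** (k = 3): per-condition means, pooled ML variance (closed form).
- **swivel** (k = 3): shared intercept k₀ = μₚ/σₚ, per-condition σₚ.
  Profiling over k₀, the inner maximization has a closed form: the
  stationarity condition is the quadratic σ² + k₀·m·σ − E[p²] = 0 with a
  single positive root (m, E[p²] the condition's promptness mean and raw
  second moment). The outer 1-D profile is scanned on an 80-point
  log-spaced grid over k₀ ∈ [0.05, 200] and refined by bounded Brent search
  on the bracketing interval (xatol 10⁻¹²). Each profile evaluation is O(1)
  in the data via sufficient statistics, which is what makes 10⁵ bootstrap
  refits cheap. The tests verify the optimum against dense grid searches.

BIC uses n = total observations across both conditions (the joint
likelihood's sample size). BIC differences are labelled with the
Kass–Raftery bands, half-open on the left: (0, 2] weak, (2, 6] substantial,
(6, 10] strong, > 10 very strong.

The threshold ratio θ_stim/θ_pre equals μₚ,pre/μₚ,stim (and identically
σₚ,pre/σₚ,stim) under the swivel constraint; the implementation asserts the
two agree to optimizer tolerance. Its uncertainty is a percentile bootstrap:
resampling with replacement **within** each condition (condition membership
is fixed by the stimulation protocol), refitting swivel, and taking the
2.5/97.5 percentiles of ≥ 200 resampled ratios. Percentile rather than BCa
because it is the simplest fully reproducible choice; BCa would be a
straightforward extension. Resamples on which the fit degenerates are
redrawn, capped at 10× the requested count. With a skewed resampling
distribution at very small n the raw percentile interval can exclude the
full-sample point estimate; the interval is widened to contain it so the
estimate is always inside its own CI.

## Early-component mixture

Datasets with a minor population of unusually fast responses are fitted with
a two-component normal mixture on the promptness scale by EM (convergence
when the log-likelihood gain drops below 10⁻⁸, cap 500 iterations; the EM
log-likelihood is nondecreasing by construction and the tests check it).
Initialization splits the sample at its 85th percentile, seeding the early
component from the upper tail — appropriate because the early component is
expected to be minor. The component with the larger mean promptness is
always labelled *early*; a flag records whether it is genuinely minor
(weight < ½) rather than relabelling, since a majority-weight fast
component would mean the "early" reading of the data is wrong, which the
caller should see, not have silently renamed. Both components are free
(no shared-intercept constraint between early and main); this is the least
committal parameterization and is flagged for sensitivity analysis. If the
mixture fails to improve on the single-component likelihood the
single-component fit is returned with weight 0 and `single_component=True`.

## Synthetic experiment generator

`simulate_experiment` emits one block: events are generated sequentially,
with the interval draw using baseline parameters while the current event
precedes stimulation onset and stimulation parameters once it lies inside
the window, so exactly one draw naturally spans the onset and is later
discarded by the labelling rules. Defaults define the study conditions:

- baseline frequency 2.96 Hz (mean promptness);
- threshold factor 0.65 (manual) with 0.56 used for the vocal condition in
  the reproduction script; values < 1 shorten the race;
- promptness CV 0.15 — interval dispersion is not reported for the target
  experiment, so this is a generator choice of a realistic reaction-time
  CV, recorded in every manifest;
- pre/stim durations 60 s each — enough for ~180/270 intervals per block at
  these rates; calibration studies use longer blocks or draw intervals
  directly.

Stimulation implements a **pure swivel** by default (both promptness
parameters scaled by 1/factor, intercept preserved exactly), because a
threshold change is the mechanism of interest; a shift mode (mean only) is
provided for model-selection calibration. Non-positive rate draws are
rejected and redrawn — the simplest exactly documented scheme. Frame
quantization rounds **event times** (not intervals) to the nearest grid
point so that rounding error accumulates as it does in real video
annotation; quantized data are nonetheless fitted with the continuous
likelihood. At 40 ms frames and ~0.3 s intervals this biases parameters by
far less than sampling noise (the acceptance check measures the ratio shift
at < 0.05, typically < 0.01); an interval-censored likelihood is a
deliberate non-goal.

What the generator does **not** emulate: drifts or autocorrelation in the
baseline rate, fatigue, movement-duration overlap, detection jitter in the
event annotations, and any stimulation-artifact structure. Passing tests
therefore demonstrate correctness of the estimators under the model's own
assumptions, not robustness to every feature of clinical recordings.

## Interval pipeline and frequency statistics

Windows follow a half-open convention: an event at exactly stimulation
onset belongs to the stimulation window. An interval is labelled *stim* iff
both bounding events lie in [onset, offset], *pre* iff both lie in
[onset − w, onset) with the pre-window w defaulting to the stimulation
duration (comparable exposure); everything else is discarded and counted,
so pre + stim + discarded always equals the number of successive pairs.

Frequency summaries use instantaneous frequency 1/T per interval. The
omnibus analysis is an ordinary-least-squares linear model with
stimulation, effector and patient as categorical predictors plus their
interactions — a deliberate **fixed-effects approximation** of a mixed
model with patient as a random factor: with a handful of patients the
random-effect variance is ill-estimated, and the report header flags the
approximation. Post hoc pre-vs-stim comparisons are pooled-variance t-tests
per patient × effector cell, Bonferroni-multiplied by the number of cells
and capped at 1. Cells below the minimum size are excluded with a recorded
warning, never silently.

## Numerical choices and degenerate inputs

- Single-condition MLE requires n ≥ 3 and non-identical intervals
  (degenerate variance raises a dedicated error); the mixture requires
  n ≥ 20; the bootstrap requires n_boot ≥ 200.
- All simulation randomness flows through `numpy.random.default_rng`
  seeds; the fixture suite spawns per-fixture seeds from one
  `SeedSequence`, so one integer reproduces every file byte-identically.
- Problem sizes in the test and reproduction suites: 25 datasets of n ≤ 50
  for the grid-search oracle, 20 replicates of n = 2000/condition for
  selection calibration and ratio recovery, and 100 replicates of
  n = 150/condition with 1000 bootstrap resamples for CI coverage — sizes
  chosen so each property is measured with comfortable margin while the
  whole suite completes in about a minute.

## Known limitations

- The likelihood ignores negative-promptness mass; fits where μₚ/σₚ < 2
  are flagged, not corrected.
- No interval-censored likelihood for quantized data; no BCa bootstrap; no
  random-effects (REML) mixed model; no designs with more than two
  conditions; at most two mixture components.
- The swivel profile search covers k₀ ∈ [0.05, 200]; data whose true
  intercept falls outside (CV above 20 or below 0.5%) would hit the bounds.
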