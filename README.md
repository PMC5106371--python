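# laterkit

LATER/recinormal modelling of self-paced inter-movement intervals: reciprobit
analysis, constrained two-condition model comparison (swivel vs. shift) by
BIC, and bootstrap estimation of the decision-threshold reduction factor —
together with a race-model simulator that generates synthetic
stimulation-experiment event streams with the statistical structure the
analysis assumes.

## Who this is for

Researchers analysing streams of self-paced, repetitive movements (finger
taps, syllable repetitions) recorded around an intervention — e.g. direct
cortical stimulation — who want to ask not just *whether* the movement rate
changed, but *which latent decision parameter* changed: the distance from
baseline to the decision threshold, or the mean rate of rise of the decision
signal.

## The model

In the LATER (Linear Approach to Threshold with Ergodic Rate) race model, a
decision signal rises linearly from baseline at a rate *r* drawn afresh on
each trial from N(μᵣ, σᵣ²); a movement is triggered when the signal covers
the baseline-to-threshold distance θ. The inter-movement interval is
T = θ/r, so the *promptness* P = 1/T is normal with

    μₚ = μᵣ/θ,   σₚ = σᵣ/θ,

and T follows the **recinormal** distribution. On a *reciprobit plot*
(−1/T on the abscissa, probit of the cumulative probability on the
ordinate), recinormal samples fall on a line of slope 1/σₚ crossing abscissa
zero (infinite time) at μₚ/σₚ.

Two canonical changes between a pre-intervention and an intervention
condition are distinguished by joint maximum likelihood on the promptness
scale:

- **swivel** — shared infinite-time intercept μₚ/σₚ, signature of a changed
  threshold distance θ;
- **shift** — shared slope σₚ, signature of a changed mean rate of rise μᵣ;

plus the **null** (no change) and **unconstrained** alternatives. Models are
compared by BIC = −2·logL + k·ln(n), with Kass–Raftery evidence labels on
BIC differences. Under the winning swivel model the threshold ratio

    θ_stim/θ_pre = μₚ,pre/μₚ,stim = σₚ,pre/σₚ,stim

is reported with a within-condition percentile-bootstrap 95% CI. A
two-component promptness mixture handles datasets with a minor population of
unusually fast "early" responses, and the interval pipeline computes
per-cell instantaneous-frequency summaries with omnibus (fixed-effects OLS)
and Bonferroni-adjusted post hoc tests.

## Worked example

Simulate the canonical fixture suite and analyse the swivel-truth stream
(baseline 2.96 Hz, threshold reduced to 0.65 of its pre-stimulation value
inside the stimulation window):

```bash
laterkit simulate --seed 7 --out demo/fixtures
laterkit pipeline demo/fixtures/swivel.csv --seed 7 --n-boot 1000 --out demo/run
```

prints

```json
{
  "winner": "swivel",
  "threshold_ratio": {
    "ratio": 0.6712038238842083,
    "ci_low": 0.6516133911009604,
    "ci_high": 0.6915750944013921,
    "n_boot": 1000,
    "seed": 7
  }
}
```

The full report (`demo/run/report.json`) shows the extraction bookkeeping
(177 pre intervals, 265 stim intervals, 1 straddling interval discarded) and
the BIC table: swivel wins with ΔBIC = 26.55 over shift ("very strong"),
5.87 over unconstrained ("substantial") and 422.04 over null ("very
strong"). The recovered threshold ratio 0.67 [0.65–0.69] brackets the
generating value 0.65: the stimulation window behaves as if the race to
threshold were shortened to about two-thirds of its baseline length —
*reversed procrastination* — rather than the rise rate being accelerated.

The same analysis runs from Python:

```python
from laterkit import compare_models, bootstrap_ratio, RecinormalParams, simulate_later

pre = simulate_later(RecinormalParams(2.96, 0.444), 2000, seed=1)
stim = simulate_later(RecinormalParams(2.96 / 0.65, 0.444 / 0.65), 2000, seed=2)
comparison = compare_models(pre, stim)     # ranking[0] == "swivel"
estimate = bootstrap_ratio(pre, stim, n_boot=1000, seed=3)
```

## Layout

- `src/laterkit/recinormal.py` — recinormal pdf/cdf, closed-form MLE,
  reciprobit transform, early-component mixture (EM)
- `src/laterkit/joint.py` — null/shift/swivel/unconstrained joint fits, BIC
  comparison, threshold ratio, bootstrap
- `src/laterkit/simulate.py` — LATER race simulator, experiment streams,
  fixture suite
- `src/laterkit/pipeline.py` — event-to-interval extraction, frequency
  statistics
- `src/laterkit/cli.py` — `laterkit` command (simulate, intervals, fit,
  compare, bootstrap, stats, pipeline)
- `docs/methods.md` — modelling assumptions, parameter defaults, numerical
  choices and limitations
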