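# Methods

`absampler` implements a rational process model of judgment and
decision-making: behavior is generated from *autocorrelated samples* of
fine-grained hypotheses, drawn from a task posterior by Metropolis-coupled
MCMC (MC³), and turned into six behavioral measures — probability judgments,
point estimates, confidence intervals, choices, confidence judgments, and
response times — by a handful of simple read-out rules. This note records the
model, the defaults, the numerical choices, and what the simulations do and
do not establish.

## The model

**Task posterior.** Each trial's stimulus induces a posterior P(h|s) over
fine-grained hypotheses h (e.g., candidate dot counts after a brief
numerosity display). The running task family is a Gaussian posterior with
mean at the true stimulus value and a free sd σ collecting perceptual and
computational uncertainty; arbitrary tabulated (discrete-grid) posteriors are
supported for oracle tests. The model never evaluates the posterior globally:
all read-outs consume samples, and the sampler needs only local density
ratios.

**Sampler.** `n_chains` random-walk Metropolis chains run on tempered
versions of the target (π^{1/T}, temperatures 1 = T₁ < T₂ < ...), with a
probability `swap_prob` per tick of proposing to swap a uniformly chosen
adjacent pair of chains. The cold chain's positions are the reported samples.
Rejected proposals repeat the current position (each reported sample is the
chain's state), and there is never a burn-in: the starting-point transient
*is* the psychological mechanism behind anchoring and sequential effects.
Variants: `rwm` (single chain) and `direct` (i.i.d. draws).

**Response prior.** Evidence counts (samples classified into response
alternatives through a partition of the hypothesis space; a value exactly on
a boundary belongs to the upper interval) are combined with a conjugate
Beta/Dirichlet prior on responses. The reported probability judgment and the
decision confidence are both the posterior mean
(α_m + S_m)/(N + Σα). After feedback, the prior resets to uniform plus one
pseudocount on the reinforced alternative (binary: Beta(2,1) or Beta(1,2));
only the immediately preceding trial is used.

**Stopping.** Judgments, estimates and intervals use a fixed sample budget
N. Choices use the max-minus-next rule on the pseudocount-seeded totals:
stop when the leader exceeds the runner-up by Δ (compared as ≥ Δ, so the
achieved difference at stopping is exactly Δ unless the prior already
exceeded it — a biased prior at threshold answers with zero samples). A cap
`n_max` (default 1000) with a majority fallback guards against
nontermination; ties break uniformly at random. The dynamic-programming
optimal policy is deliberately out of scope (a documented stub).

**Read-outs.** Estimates report the most recent sample (the sample mean is an
option; the two do not differ qualitatively). Intervals at coverage γ use
linearly interpolated symmetric order statistics, clamped to the sample
range: for N = 5 and γ = 0.6 the bounds are exactly the 2nd and 4th order
statistics. Interval evaluation reports the raw fraction of samples inside
the probed interval (optionally tempered through the response prior; off by
default). RT is t0 plus an Erlang(n, λ) sampling time (Poisson sample
arrivals). In decision-then-estimate tasks the decision's samples are reused
for the estimate; no fresh sampling occurs.

## Default parameters

| parameter | default | units | why |
|---|---|---|---|
| posterior sd σ | 3 | hypothesis units | numerosity-scale uncertainty; free task parameter |
| temperatures | (1, 3, 9) | — | hot chains supply the long mixing timescales behind 1/f structure |
| proposal sd | 0.3 σ | hypothesis units | genuinely local sampling; see "Choosing the sampling timescale" |
| swap_prob | 0.5 | per tick | frequent enough to splice hot-chain timescales into the cold chain |
| Δ (speed / accuracy) | 2 / 5 | evidence units | speeded vs. careful decision regimes |
| difficulty d (easy / difficult) | 2.0 / 0.5 | σ units of mean–boundary offset | easy vs. hard discrimination |
| N (judgments/estimates/CIs) | 5 | samples | small-sample regime in which the characteristic biases live |
| conjunction budget | ⌈N/2⌉ | samples | complex conjunctive events are costlier to tally |
| λ | 10 | samples/s | sampling rate; sets the RT scale |
| t0 | 0.2 | s | nondecision time |
| anchor-task Δ | 28 | evidence units | unspeeded deliberative judgments; see below |

"random" initialization draws each chain from its own tempered target (the
cold chain from the posterior itself). This keeps the whole ensemble at joint
stationarity from the first sample, which matters because there is no
burn-in: initializing every chain from the posterior instead leaves hot
chains too narrow, and the swap move — which preferentially pulls
higher-density values into the cold chain — then visibly over-concentrates
early samples (measured as a +0.04 upward bias in interval-evaluation
judgments).

**Initialization policy across trials.** Choice batteries re-initialize at
random from each trial's posterior: every trial presents a new stimulus, so
the previous chain position carries no information about the new hypothesis
space. Carryover (positions kept verbatim) applies when consecutive trials
concern the same quantity — the repeated-estimation series — and an explicit
anchor h* (decision-then-estimate tasks) overrides both.

**Choosing the sampling timescale.** The proposal scale trades off competing
phenomena. Fast proposals (≈ 1 σ) wash out the cross-trial autocorrelation:
a 5-sample-per-trial estimate series becomes spectrally flat, and slow
errors and the resolution of confidence shrink toward zero. Very slow
proposals freeze within-trial evidence into all-or-nothing runs, flattening
the confidence–discriminability relation. 0.3 σ with the (1, 3, 9) ladder
keeps the estimate-series spectrum in the 1/f band (slope ≈ −1.1 at one
sample per trial, ≈ −0.55 at five) while leaving enough within-trial mixing
for the confidence effects. The anchor-task threshold (Δ = 28) follows from
the same timescale: classic anchoring paradigms are unspeeded deliberative
judgments, and with a local sampler a speeded threshold would leave the
estimate glued to h*, masking the repulsion that optional stopping produces
once the chain has had time to decouple from the anchor. (Both anchoring and
repulsion shrink as the budget grows, which the model predicts; at Δ = 28
the far-anchor pull is still ≈ 40 hypothesis units.)

**Repeated-estimation series.** The 1/f battery simulates 1024 consecutive
trials × 10 simulated participants. Estimation trials draw one fresh sample
each (the estimate is the current hypothesis; rapid production tasks leave
no room for more), except for the fixed-budget variant, which by definition
spends N = 5. The companion RT series comes from a repeated *decision*
battery (Δ = 4 on a fixed stimulus with carryover): RT inherits serial
dependence only through optional stopping, which is also why it is
distinctly shallower — counting samples to a threshold whitens the spectrum
— and why the fixed-budget variant's RT series is exactly white (an i.i.d.
Erlang sequence).

## Model variants

The effect battery runs four variants: **full** (MC³ + adaptive prior +
max-minus-next), **no_prior** (all pseudocounts zero, no adaptation),
**direct_sampling** (i.i.d. samples), and **fixed_sample_size** (N = 5 for
everything, decisions included). Each qualitative effect is a directional
pass/fail criterion: a one-sided test at 2 Monte-Carlo standard errors plus
a fixed smallest-effect-of-interest floor (confidence differences 0.01,
correlations 0.05, interval overconfidence 0.05, judgment shrinkage 0.03,
anchor pull 1.0 / repulsion 0.3 hypothesis units, Q–Q slope 1.05 with
R² > 0.95, RT spectral slope below −0.04 and at least 0.1 shallower than the
estimate slope). Exact-match criteria (the subadditivity closed form) use
3 standard errors with a 0.02 floor so that one ~3σ Monte-Carlo excursion
among dozens of cells cannot flip a qualitative verdict. Trial counts per
condition (20 000 for error-RT and metacognition batteries, 120 000 for fast
errors, a few thousand elsewhere) keep standard errors well under the
expected effect sizes.

Metacognitive efficiency is computed with the rate-based construction:
choices with confidence ≥ c count as the signal response, hit and
false-alarm rates are recomputed, and meta-d′ = Φ⁻¹(HR) − Φ⁻¹(FAR) with a
1/(2n) clamp on degenerate rates; criteria run over the achievable (discrete)
confidence grid. The estimator is validated against a Gaussian observer
whose confidence is the exact posterior, for which meta-d′/d′ = 1 at every
criterion; efficiency is judged top-criterion-vs-bottom-criterion because the
confidence grid can be coarse. No maximum-likelihood (response-specific)
meta-d′ fitting is attempted.

## Known limitations and honest misses

Two cells of the expected effect × variant grid do not reproduce under this
parameter regime, and are reported as failures rather than patched:

- **Fixed-budget variant, resolution of confidence.** With confidence
  (α + S_chosen)/(N + Σα) at fixed N, higher confidence on correct trials is
  a mathematical consequence of evidence counts varying with correctness —
  the same variation that gives this variant its confidence–discriminability
  and metacognitive effects. We measure a robust ≈ +0.05 resolution for this
  variant at every mixing regime examined, so the expectation that it shows
  *no* resolution is unattainable with an honest mean-confidence contrast.
- **Full model, fast errors.** In the easy/speeded condition the
  adaptive-prior starting-point mechanism produces N = 1 errors (clearly
  visible in the direct-sampling variant: errors ≈ 0.10 s faster), but with
  locally autocorrelated sampling a wrong first sample persists as a
  wrong-side run, and these slow errors cancel the fast ones almost exactly
  (full-model contrast ≈ +0.01 s). No parameter regime examined preserves
  the 1/f band, slow errors, resolution, and calibrated interval evaluation
  while also yielding full-model fast errors.

Other caveats: the synthetic task battery uses stationary Gaussian
posteriors with difficulty operationalized purely as mean–boundary offset —
real stimuli add sensory-noise structure, non-Gaussian posteriors, and
learning across sessions, none of which these simulations speak to. Passing
the battery shows the *mechanisms* produce the qualitative signatures under
controlled conditions, not that the model fits any particular dataset;
quantitative fitting (e.g., by approximate Bayesian computation) is out of
scope. RT realism is limited to a scalar nondecision time plus Erlang
sampling time. Hypothesis spaces are one-dimensional; hierarchical or
structured representations are not modeled.
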