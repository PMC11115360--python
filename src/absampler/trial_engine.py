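"""Run one trial end to end.

A trial draws samples from its posterior until the stopping rule fires, maps
each sample to a response alternative through the partition, and converts the
sample set into whatever measure the query asks for:

- ``choice`` — the stopping rule's winner, with confidence from the response
  prior;
- ``probability_judgment`` — posterior-mean probability of the target event;
- ``estimate`` — the most recent sample (or the sample mean);
- ``ci_produce`` — an interval at coverage ``ci_level`` from interpolated
  sample quantiles;
- ``ci_evaluate`` — the fraction of samples inside a given interval;
- ``choice_plus_estimate`` / ``choice_plus_confidence`` — a decision whose
  samples are *reused* for the secondary response (no fresh sampling), which
  is what couples estimates to the preceding decision (anchoring/repulsion).

Response time is the time to generate the samples: a Poisson sampling process
at rate lambda makes the RT for ``n`` samples Erlang(n, lambda), shifted by a
nondecision time ``t0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hypothesis_model import Partition, PosteriorSpec, classify
from .response_prior import EvidenceCounts, ResponsePrior, probability_estimate
from .sampler import SamplerConfig, SamplerState, next_sample, reset_positions
from .stopping import StoppingRule, should_stop

QUERIES = (
    "choice",
    "probability_judgment",
    "estimate",
    "ci_produce",
    "ci_evaluate",
    "choice_plus_estimate",
    "choice_plus_confidence",
)


@dataclass
class TrialConfig:
    """Everything needed to run one trial.

    ``anchor`` controls initialization: a number pins every chain to that
    comparison value h*, ``"random"`` re-draws positions from the trial's
    posterior, and ``None`` carries the previous trial's state over
    unchanged. ``event_map`` maps partition cells onto response alternatives
    (identity by default), letting a 3-cell partition express a binary
    inside/outside-interval event. ``target`` names the alternative whose
    probability a judgment reports; ``correct_alt`` is the alternative the
    task defines as correct (for accuracy scoring and feedback).
    """

    spec: PosteriorSpec
    partition: Partition | None = None
    query: str = "choice"
    rule: StoppingRule = field(default_factory=StoppingRule)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    anchor: float | str | None = None
    ci_level: float = 0.6
    eval_interval: tuple | None = None
    rate_lambda: float = 10.0
    t0: float = 0.0
    target: int = 1
    correct_alt: int | None = None
    event_map: tuple | None = None
    estimate_mode: str = "last"
    temper_evaluation: bool = False

    def __post_init__(self) -> None:
        if self.query not in QUERIES:
            raise ValueError(f"unknown query {self.query!r}")
        if not (self.rate_lambda > 0):
            raise ValueError("rate_lambda must be > 0")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")
        if not (0 < self.ci_level <= 1):
            raise ValueError("ci_level must be in (0, 1]")
        if self.eval_interval is not None and not self.eval_interval[0] < self.eval_interval[1]:
            raise ValueError("eval_interval must satisfy lo < hi")


@dataclass
class TrialRecord:
    """One trial's samples and derived measures."""

    samples: list
    counts: EvidenceCounts
    choice: int | None = None
    correct: bool | None = None
    rt: float = 0.0
    confidence: float | None = None
    prob_judgment: float | None = None
    estimate: float | None = None
    ci: tuple | None = None
    trial_index: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def estimate_from_samples(samples, mode: str = "last") -> float:
    """Point estimate from the trial's samples.

    ``last`` (default) reports the most recent sample — with autocorrelated
    sampling, later samples are least contaminated by the starting point.
    ``mean`` averages; the two do not differ qualitatively in aggregate.
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    if mode == "last":
        return float(samples[-1])
    if mode == "mean":
        return float(np.mean(samples))
    raise ValueError(f"unknown estimate mode {mode!r}")


def ci_produce(samples, gamma: float) -> tuple[float, float]:
    """Produce a confidence interval covering a fraction ``gamma`` of the sample.

    With order statistics x_(1..N), the interval covers m = gamma*N sample
    points symmetrically: fractional ranks r = (N - m)/2 + 1 and
    s = r + m - 1, linearly interpolated between adjacent order statistics
    and clamped to [x_(1), x_(N)]. For five samples at gamma = 0.6 the bounds
    are exactly the 2nd and 4th order statistics. Because small samples
    underrepresent the tails, the produced intervals systematically
    undercover the target distribution (production overconfidence).
    """
    xs = np.sort(np.asarray(samples, dtype=float))
    n = xs.size
    if n < 2:
        raise ValueError("need at least two samples to produce an interval")
    if not (0 < gamma <= 1):
        raise ValueError("gamma must be in (0, 1]")
    m = gamma * n
    r = (n - m) / 2.0 + 1.0
    s = r + m - 1.0

    def at_rank(rank: float) -> float:
        rank = min(max(rank, 1.0), float(n))
        k = int(np.floor(rank))
        if k >= n:
            return float(xs[-1])
        frac = rank - k
        return float(xs[k - 1] + frac * (xs[k] - xs[k - 1]))

    return at_rank(r), at_rank(s)


def ci_evaluate(samples, interval, prior: ResponsePrior | None = None) -> float:
    """Judge the probability that the quantity lies in ``interval``.

    The raw proportion of samples inside the closed interval (an unbiased
    estimator, hence the good calibration of interval evaluation). If a
    ``prior`` is supplied the proportion is tempered through the response
    prior like any other binary probability judgment.
    """
    xs = np.asarray(samples, dtype=float)
    if xs.size == 0:
        raise ValueError("need at least one sample")
    lo, hi = float(interval[0]), float(interval[1])
    if not lo < hi:
        raise ValueError("interval must satisfy lo < hi")
    inside = int(np.count_nonzero((xs >= lo) & (xs <= hi)))
    if prior is None:
        return inside / xs.size
    ev = EvidenceCounts(counts=(inside, xs.size - inside))
    return probability_estimate(prior, ev, 0)


def rt_draw(n_samples: int, rate_lambda: float, t0: float,
            rng: np.random.Generator) -> float:
    """Response time for ``n_samples`` samples: t0 + Erlang(n, lambda).

    Samples arrive as a Poisson process, so inter-sample waits are i.i.d.
    exponential(lambda); mean t0 + n/lambda, variance n/lambda^2. Zero
    samples (a decision made on pseudocounts alone) costs only t0.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    if not (rate_lambda > 0):
        raise ValueError("rate_lambda must be > 0")
    if n_samples == 0:
        return float(t0)
    return float(t0 + rng.gamma(shape=n_samples, scale=1.0 / rate_lambda))


def _effective_rule(config: TrialConfig) -> StoppingRule:
    return config.rule


def run_trial(config: TrialConfig, state: SamplerState,
              prior: ResponsePrior) -> tuple[TrialRecord, SamplerState]:
    """Execute one trial; returns the record and the state for carryover.

    Initialization precedence: an explicit anchor (number or "random")
    overrides carryover; otherwise the chains stay where the previous trial
    left them. The stopping rule is evaluated before the first sample, so a
    feedback-biased prior already at threshold answers with zero samples.
    """
    spec = config.spec
    scfg = config.sampler
    rng = state.rng
    if config.anchor is not None and scfg.algorithm != "direct":
        reset_positions(state, config.anchor, spec, scfg)

    partition = config.partition
    n_alt = prior.m
    emap = config.event_map
    counts = [0] * n_alt
    samples: list[float] = []
    rule = _effective_rule(config)
    if partition is None and (rule.kind != "fixed_n"
                              or config.query.startswith("choice")
                              or config.query == "probability_judgment"):
        raise ValueError("this query/stopping rule needs a partition")

    def check_stop():
        if partition is None:
            # pure sampling queries (estimate/CI): budgeted by sample count
            return len(samples) >= rule.n_fixed, None
        return should_stop(rule, prior, EvidenceCounts(counts=tuple(counts)), rng)

    stop, chosen = check_stop()
    while not stop:
        h, state = next_sample(state, spec, scfg)
        samples.append(h)
        if partition is not None:
            cell = classify(partition, h)
            counts[emap[cell] if emap is not None else cell] += 1
        stop, chosen = check_stop()

    ev = EvidenceCounts(counts=tuple(counts))
    rec = TrialRecord(samples=samples, counts=ev, trial_index=state.trial_index)
    rec.rt = rt_draw(len(samples), config.rate_lambda, config.t0, rng)

    q = config.query
    if q in ("choice", "choice_plus_estimate", "choice_plus_confidence"):
        rec.choice = chosen
        rec.confidence = probability_estimate(prior, ev, chosen)
        if config.correct_alt is not None:
            rec.correct = bool(chosen == config.correct_alt)
        if q == "choice_plus_estimate":
            rec.estimate = estimate_from_samples(samples, config.estimate_mode)
    elif q == "probability_judgment":
        rec.prob_judgment = probability_estimate(prior, ev, config.target)
    elif q == "estimate":
        rec.estimate = estimate_from_samples(samples, config.estimate_mode)
    elif q == "ci_produce":
        rec.ci = ci_produce(samples, config.ci_level)
    elif q == "ci_evaluate":
        if config.eval_interval is None:
            raise ValueError("ci_evaluate query needs eval_interval")
        rec.prob_judgment = ci_evaluate(
            samples, config.eval_interval,
            prior if config.temper_evaluation else None,
        )

    state.trial_index += 1
    return rec, state


# -- serialization ---------------------------------------------------------

def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "trial_index": r.trial_index,
            "n_samples": r.n_samples,
            "choice": r.choice,
            "correct": r.correct,
            "rt": r.rt,
            "confidence": r.confidence,
            "prob_judgment": r.prob_judgment,
            "estimate": r.estimate,
            "ci_lo": None if r.ci is None else r.ci[0],
            "ci_hi": None if r.ci is None else r.ci[1],
        })
    return pd.DataFrame(rows)


def samples_to_frame(records) -> pd.DataFrame:
    """Sidecar table of raw samples (trial_index, position_in_trial, value)."""
    rows = []
    for r in records:
        for k, v in enumerate(r.samples):
            rows.append({"trial_index": r.trial_index, "position_in_trial": k, "value": v})
    return pd.DataFrame(rows)
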