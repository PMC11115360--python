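"""Stopping rules: when to quit sampling and answer.

Judgments, estimates and confidence intervals use a fixed sample size.
Choices use the max-minus-next heuristic: accumulate evidence (pseudocounts
from the response prior plus sample tallies) and stop as soon as the leader
exceeds the runner-up by the threshold Delta. Because the pseudocounts seed
the accumulator, a prior biased by the previous trial's feedback acts as a
shifted starting point — the mechanism behind fast errors — and can even
satisfy the threshold before any sample is drawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .response_prior import EvidenceCounts, ResponsePrior


@dataclass(frozen=True)
class StoppingRule:
    """Either ``fixed_n`` (stop at exactly ``n_fixed`` samples) or
    ``max_minus_next`` (stop when the evidence gap reaches ``delta``;
    ``n_max`` caps runaway trials with a majority fallback)."""

    kind: str = "max_minus_next"
    n_fixed: int = 5
    delta: int = 2
    n_max: int = 1000

    def __post_init__(self) -> None:
        if self.kind not in ("fixed_n", "max_minus_next"):
            raise ValueError(f"unknown stopping rule {self.kind!r}")
        if self.kind == "fixed_n" and not (1 <= self.n_fixed <= self.n_max):
            raise ValueError("need 1 <= n_fixed <= n_max")
        if self.kind == "max_minus_next" and self.delta < 1:
            raise ValueError("delta must be >= 1")


def _argmax_tiebreak(totals: np.ndarray, rng: np.random.Generator) -> int:
    best = np.flatnonzero(totals == totals.max())
    if best.size == 1:
        return int(best[0])
    return int(best[int(rng.integers(0, best.size))])


def should_stop(rule: StoppingRule, prior: ResponsePrior, ev: EvidenceCounts,
                rng: np.random.Generator) -> tuple[bool, int | None]:
    """Evaluate the stopping rule on the current evidence.

    Returns ``(stop, chosen)``; ``chosen`` is None while sampling continues.
    The achieved difference is compared as ``>= delta`` (integer evidence
    arrives one unit at a time, so the gap at stopping is exactly delta
    unless the pseudocounts already exceeded it). Ties are broken uniformly
    at random from the experiment's RNG stream.
    """
    totals = np.asarray(prior.alphas, dtype=float) + np.asarray(ev.counts, dtype=float)
    if rule.kind == "fixed_n":
        if ev.n >= rule.n_fixed:
            return True, _argmax_tiebreak(totals, rng)
        return False, None
    top2 = np.partition(totals, -2)[-2:]
    if top2[1] - top2[0] >= rule.delta:
        return True, _argmax_tiebreak(totals, rng)
    if ev.n >= rule.n_max:
        return True, _argmax_tiebreak(totals, rng)
    return False, None


def optimal_stop_reference(delta_grid=None, cost_params=None):
    """Dynamic-programming optimal stopping policy (not implemented).

    The exact optimal policy requires solving a dynamic program over the
    evidence lattice; the max-minus-next heuristic above is used as its
    well-known approximation. This stub documents the boundary of scope.
    """
    raise NotImplementedError(
        "optimal stopping via dynamic programming is out of scope; "
        "use the max-minus-next StoppingRule"
    )
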