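"""The Bayesian Monte Carlo prior on responses.

Raw relative frequencies of sampled evidence make terrible probability
estimates at small sample sizes (one sample forces an estimate of 0 or 1).
The model therefore maintains a conjugate Beta/Dirichlet prior over the
probability that each response alternative is correct; evidence counts act as
pseudocounts, and the reported probability judgment (equivalently the
confidence judgment) is the posterior mean

    P_hat(m) = (alpha_m + S_m) / (N + sum_k alpha_k).

The prior adapts to experience minimally: after feedback, a fresh uniform
prior gains one pseudocount on whichever alternative was correct on the
immediately preceding trial (binary: Beta(1,1) -> Beta(2,1) or Beta(1,2)).
Setting every alpha to zero removes the prior entirely (the no-prior model
variant, where the estimate collapses to the relative frequency).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ResponsePrior:
    """Dirichlet pseudocounts over M response alternatives (Beta when M=2)."""

    alphas: tuple

    def __post_init__(self) -> None:
        a = tuple(float(x) for x in self.alphas)
        if len(a) < 2:
            raise ValueError("need at least two response alternatives")
        if any(x < 0 for x in a):
            raise ValueError("pseudocounts must be nonnegative")
        object.__setattr__(self, "alphas", a)

    @property
    def m(self) -> int:
        return len(self.alphas)

    @property
    def total(self) -> float:
        return float(sum(self.alphas))


def uniform_prior(m: int = 2, alpha0: float = 1.0) -> ResponsePrior:
    """Symmetric Dir(alpha0, ..., alpha0); Beta(1,1) by default for binary."""
    return ResponsePrior(alphas=(alpha0,) * m)


@dataclass(frozen=True)
class EvidenceCounts:
    """Sample tallies per response alternative."""

    counts: tuple

    def __post_init__(self) -> None:
        c = tuple(int(x) for x in self.counts)
        if any(x < 0 for x in c):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(sum(self.counts))


def probability_estimate(prior: ResponsePrior, ev: EvidenceCounts, target: int) -> float:
    """Posterior-mean probability that alternative ``target`` is correct.

    Serves as both the probability judgment and the decision confidence (the
    Bayesian Confidence Hypothesis). With no pseudocounts and no samples
    there is nothing to report.
    """
    if len(ev.counts) != prior.m:
        raise ValueError("counts and prior disagree on the number of alternatives")
    if not 0 <= target < prior.m:
        raise ValueError("target out of range")
    denom = ev.n + prior.total
    if denom <= 0:
        raise ValueError("no information: all-zero prior and no samples")
    return (prior.alphas[target] + ev.counts[target]) / denom


def adapt_from_feedback(base: ResponsePrior, correct: int | None) -> ResponsePrior:
    """Prior for the next trial given the previous trial's feedback.

    Resets to a uniform Dir(1,...,1) and adds one pseudocount on the
    alternative that was just reinforced; only the immediately preceding
    trial is used (no accumulation over the session). ``correct=None`` (no
    feedback yet) returns the noninformative uniform prior unchanged.
    """
    m = base.m
    if correct is None:
        return uniform_prior(m)
    if not 0 <= correct < m:
        raise ValueError("correct out of range")
    alphas = [1.0] * m
    alphas[correct] += 1.0
    return ResponsePrior(alphas=tuple(alphas))


def confidence_at_stop(prior: ResponsePrior, ev: EvidenceCounts, chosen: int) -> float:
    """Decision confidence when optional stopping fires.

    Identical to :func:`probability_estimate` for the chosen alternative. For
    a binary choice stopped at achieved difference
    ``Delta = |i + S(A) - (j + S(B))|`` this equals
    ``(i + j + N + Delta) / (2 (i + j + N))`` for the winning side, so
    confidences of the two alternatives sum to 1 and decisions reached with
    more samples (at the same threshold) are *less* confident.
    """
    return probability_estimate(prior, ev, chosen)


def confidence_multialt(pseudo_evidence, delta: float | None = None) -> float:
    """Confidence in the leading option of a multialternative choice.

    ``pseudo_evidence`` holds the accumulated totals (pseudocounts plus
    sample counts) per option, best first. With totals ``(i, j, k, ...)``,
    ``i > j >= ...``, confidence in the winner is ``i / sum``; equivalently
    ``Diff * i / Delta`` where ``Diff = (i - j)/sum`` is the confidence gap
    to the runner-up and ``Delta = i - j`` the achieved stopping difference.
    """
    ev = [float(x) for x in pseudo_evidence]
    if len(ev) < 2:
        raise ValueError("need at least two options")
    i, j = ev[0], ev[1]
    achieved = i - j
    if delta is None:
        delta = achieved
    if delta <= 0 or achieved <= 0:
        raise ValueError("stopping difference Delta must be positive (break ties first)")
    if abs(achieved - delta) > 1e-9:
        raise ValueError("Delta inconsistent with the top-two totals")
    return i / sum(ev)


def subadditivity_bias(m_prime: int, n: int, alpha0: float,
                       exhaustive: bool = False) -> float:
    """Predicted explicit-subadditivity bias under a symmetric Beta prior.

    For ``M'`` mutually exclusive components judged separately (each as a
    binary event with prior Beta(alpha0, alpha0)) and a fixed sample size
    ``N`` per judgment, the expected excess of the summed component judgments
    over the judged disjunction is ``(M' - 1) alpha0 / (N + 2 alpha0)``.
    When the components are mutually exhaustive and only the ``M'`` components
    are judged (the disjunction is logically certain), the bias is
    ``(M' - 2) alpha0 / (N + 2 alpha0)`` — zero for binary complements.
    """
    if m_prime < 1:
        raise ValueError("m_prime must be >= 1")
    if n + 2 * alpha0 <= 0:
        raise ValueError("need N + 2*alpha0 > 0")
    k = m_prime - 2 if exhaustive else m_prime - 1
    return k * alpha0 / (n + 2 * alpha0)
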