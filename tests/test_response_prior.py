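import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from absampler.response_prior import (
    EvidenceCounts,
    ResponsePrior,
    adapt_from_feedback,
    confidence_at_stop,
    confidence_multialt,
    probability_estimate,
    subadditivity_bias,
    uniform_prior,
)


class TestProbabilityEstimate:
    def test_two_unanimous_samples(self):
        # Beta(1,1) prior, both samples favor the chosen option: 3/4
        assert probability_estimate(uniform_prior(2), EvidenceCounts((2, 0)), 0) == 0.75

    def test_hundred_samples_51_49(self):
        est = probability_estimate(uniform_prior(2), EvidenceCounts((51, 49)), 0)
        assert est == pytest.approx(52 / 102)

    def test_no_prior_reduces_to_relative_frequency(self):
        assert probability_estimate(uniform_prior(2, 0.0), EvidenceCounts((3, 2)), 0) == 0.6

    def test_dirichlet_prior_mean_without_samples(self):
        assert probability_estimate(uniform_prior(7), EvidenceCounts((0,) * 7), 3) == pytest.approx(1 / 7)

    def test_no_information_error(self):
        with pytest.raises(ValueError, match="no information"):
            probability_estimate(uniform_prior(2, 0.0), EvidenceCounts((0, 0)), 0)

    @given(st.integers(0, 30), st.integers(0, 30), st.floats(0.1, 5.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_prior_bounds_reachable_range(self, sa, sb, alpha):
        prior = uniform_prior(2, alpha)
        ev = EvidenceCounts((sa, sb))
        est = probability_estimate(prior, ev, 0)
        denom = ev.n + prior.total
        assert alpha / denom - 1e-12 <= est <= (alpha + ev.n) / denom + 1e-12

    def test_monotone_in_counts(self):
        prior = uniform_prior(2)
        base = probability_estimate(prior, EvidenceCounts((3, 3)), 0)
        assert probability_estimate(prior, EvidenceCounts((4, 3)), 0) > base
        assert probability_estimate(prior, EvidenceCounts((3, 4)), 0) < base


class TestAdaptiveFeedback:
    def test_binary_feedback(self):
        base = uniform_prior(2)
        assert adapt_from_feedback(base, 0).alphas == (2.0, 1.0)
        assert adapt_from_feedback(base, 1).alphas == (1.0, 2.0)

    def test_no_feedback_keeps_uniform(self):
        assert adapt_from_feedback(uniform_prior(2), None).alphas == (1.0, 1.0)

    def test_reset_not_accumulate(self):
        # adapting twice from an already-biased prior still yields Dir(1,..)+1
        biased = ResponsePrior(alphas=(5.0, 1.0))
        assert adapt_from_feedback(biased, 1).alphas == (1.0, 2.0)


class TestConfidence:
    @pytest.mark.parametrize("counts,expected", [((2, 0), 0.75), ((51, 49), 52 / 102)])
    def test_worked_examples(self, counts, expected):
        assert confidence_at_stop(uniform_prior(2), EvidenceCounts(counts), 0) == pytest.approx(expected)

    @given(st.integers(0, 3), st.integers(0, 3), st.integers(0, 40), st.integers(0, 40))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_closed_form_identity(self, i, j, sa, sb):
        # Conf_A = (i + j + N + Delta) / (2 (i + j + N)) when A leads
        if i + sa <= j + sb or i + j + sa + sb == 0:
            return
        prior = ResponsePrior(alphas=(float(i), float(j)))
        ev = EvidenceCounts((sa, sb))
        n = sa + sb
        delta = abs(i + sa - (j + sb))
        closed = (i + j + n + delta) / (2 * (i + j + n))
        assert confidence_at_stop(prior, ev, 0) == pytest.approx(closed)
        assert confidence_at_stop(prior, ev, 0) + confidence_at_stop(prior, ev, 1) == pytest.approx(1.0)


class TestMultialternative:
    def test_direct_substitution(self):
        assert confidence_multialt((5, 3, 2), 2) == pytest.approx(0.5)

    def test_uninformative_limit(self):
        k = 10_000_000
        assert confidence_multialt((2 + k, k, k)) == pytest.approx(1 / 3, abs=1e-6)

    @given(st.integers(1, 50), st.integers(0, 49), st.integers(0, 48))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_two_forms_agree(self, i, j, k):
        if not i > j >= k:
            return
        total = i + j + k
        diff = (i - j) / total
        delta = i - j
        assert confidence_multialt((i, j, k)) == pytest.approx(diff * i / delta)

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            confidence_multialt((3, 3, 1))


class TestSubadditivityBias:
    def test_no_unpacking_no_bias(self):
        assert subadditivity_bias(1, 5, 1.0) == 0.0

    def test_exhaustive_binary_complementarity(self):
        assert subadditivity_bias(2, 5, 1.0, exhaustive=True) == 0.0

    def test_fig_configuration_value(self):
        assert subadditivity_bias(3, 5, 1.0) == pytest.approx(2 / 7)

    def test_strictly_increasing_in_components(self):
        vals = [subadditivity_bias(m, 5, 1.0) for m in range(1, 8)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


def test_prior_validation():
    with pytest.raises(ValueError):
        ResponsePrior(alphas=(1.0,))
    with pytest.raises(ValueError):
        ResponsePrior(alphas=(1.0, -0.5))
    with pytest.raises(ValueError):
        EvidenceCounts((-1, 2))
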