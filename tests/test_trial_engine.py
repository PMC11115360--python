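import numpy as np
import pytest
from scipy import stats as sps

from absampler.hypothesis_model import Partition, gaussian
from absampler.response_prior import ResponsePrior, uniform_prior
from absampler.sampler import SamplerConfig, init_state
from absampler.stopping import StoppingRule
from absampler.trial_engine import (
    TrialConfig,
    ci_evaluate,
    ci_produce,
    estimate_from_samples,
    records_to_frame,
    rt_draw,
    run_trial,
)

FIVE = [10.0, 12.0, 14.0, 16.0, 18.0]


class TestEstimate:
    def test_last_and_mean(self):
        assert estimate_from_samples([22, 26, 24], "last") == 24
        assert estimate_from_samples([22, 26, 24], "mean") == 24
        assert estimate_from_samples([7.5], "last") == estimate_from_samples([7.5], "mean")

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            estimate_from_samples([])


class TestCiProduce:
    def test_sixty_percent_is_second_and_fourth_order_statistic(self):
        assert ci_produce(FIVE, 0.6) == (12.0, 16.0)

    def test_full_coverage_is_range(self):
        assert ci_produce(FIVE, 1.0) == (10.0, 18.0)

    def test_interpolated_ranks(self):
        lo, hi = ci_produce(FIVE, 0.93)
        assert lo == pytest.approx(10.35)
        assert hi == pytest.approx(17.65)

    def test_bounds_inside_sample_range_and_widen_with_gamma(self):
        rng = np.random.default_rng(2)
        xs = rng.normal(size=9)
        widths = []
        for g in (0.2, 0.5, 0.8, 0.95):
            lo, hi = ci_produce(xs, g)
            assert xs.min() <= lo <= hi <= xs.max()
            widths.append(hi - lo)
        assert all(b >= a for a, b in zip(widths, widths[1:]))

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            ci_produce([1.0], 0.5)


class TestCiEvaluate:
    def test_proportion_inside_closed_interval(self):
        assert ci_evaluate(FIVE, (11, 17)) == pytest.approx(0.6)
        assert ci_evaluate(FIVE, (0, 100)) == 1.0

    def test_prior_tempering(self):
        judged = ci_evaluate(FIVE, (11, 17), prior=uniform_prior(2))
        assert judged == pytest.approx((3 + 1) / (5 + 2))

    def test_unbiased_for_true_central_region(self, rng):
        # i.i.d. Gaussian samples against the true central 80% region
        lo, hi = sps.norm.ppf(0.1), sps.norm.ppf(0.9)
        vals = [ci_evaluate(rng.normal(size=5), (lo, hi)) for _ in range(10_000)]
        assert np.mean(vals) == pytest.approx(0.8, abs=0.02)


class TestRtDraw:
    def test_zero_samples_costs_only_t0(self, rng):
        assert rt_draw(0, 10.0, 0.25, rng) == 0.25

    def test_erlang_moments(self, rng):
        draws = np.array([rt_draw(5, 10.0, 0.1, rng) for _ in range(30_000)])
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - (0.1 + 0.5)) < 3 * se
        assert draws.var(ddof=1) == pytest.approx(5 / 100, rel=0.1)

    def test_fixed_n_rt_is_erlang_distributed(self, rng):
        draws = np.array([rt_draw(5, 10.0, 0.0, rng) for _ in range(10_000)])
        p = sps.kstest(draws, sps.gamma(a=5, scale=0.1).cdf).pvalue
        assert p > 0.001


def _choice_config(spec, delta=2, query="choice", **kw):
    return TrialConfig(spec=spec, partition=Partition(boundaries=(25.0,)),
                       query=query, rule=StoppingRule("max_minus_next", delta=delta),
                       sampler=SamplerConfig(), anchor="random",
                       rate_lambda=10.0, t0=0.2, correct_alt=1, **kw)


class TestRunTrial:
    def test_estimate_is_most_recent_sample(self, numerosity_posterior, rng):
        cfg = TrialConfig(spec=numerosity_posterior, query="estimate",
                          rule=StoppingRule("fixed_n", n_fixed=5),
                          sampler=SamplerConfig(), anchor="random")
        state = init_state(cfg.sampler, "random", numerosity_posterior, rng)
        rec, _ = run_trial(cfg, state, uniform_prior(2))
        assert rec.n_samples == 5
        assert rec.estimate == rec.samples[-1]

    def test_zero_sample_decision(self, numerosity_posterior, rng):
        # prior at threshold answers instantly from pseudocounts alone
        cfg = _choice_config(gaussian(27.0, 3.0), delta=1)
        state = init_state(cfg.sampler, "random", cfg.spec, rng)
        rec, _ = run_trial(cfg, state, ResponsePrior(alphas=(2.0, 1.0)))
        assert rec.n_samples == 0
        assert rec.rt == 0.2
        assert rec.choice == 0
        assert rec.confidence == pytest.approx(2 / 3)

    def test_choice_is_majority_consistent_and_above_chance(self, rng):
        cfg = _choice_config(gaussian(27.0, 3.0), delta=2)
        state = init_state(cfg.sampler, "random", cfg.spec, rng)
        correct = 0
        for _ in range(500):
            rec, state = run_trial(cfg, state, uniform_prior(2))
            correct += rec.correct
        assert correct / 500 > 0.5

    def test_large_rate_removes_sampling_time(self, numerosity_posterior, rng):
        cfg = TrialConfig(spec=numerosity_posterior, query="estimate",
                          rule=StoppingRule("fixed_n", n_fixed=5),
                          sampler=SamplerConfig(), anchor="random",
                          rate_lambda=1e9, t0=0.3)
        state = init_state(cfg.sampler, "random", numerosity_posterior, rng)
        rec, _ = run_trial(cfg, state, uniform_prior(2))
        assert rec.rt == pytest.approx(0.3, abs=1e-6)

    def test_rt_mean_increases_with_delta(self, rng):
        spec = gaussian(26.5, 3.0)
        means = []
        for delta in (2, 5):
            cfg = _choice_config(spec, delta=delta)
            state = init_state(cfg.sampler, "random", spec, rng)
            rts = []
            for _ in range(800):
                rec, state = run_trial(cfg, state, uniform_prior(2))
                rts.append(rec.rt)
            means.append(np.mean(rts))
        assert means[1] > means[0]

    def test_records_frame_columns(self, numerosity_posterior, rng):
        cfg = _choice_config(numerosity_posterior)
        state = init_state(cfg.sampler, "random", numerosity_posterior, rng)
        recs = [run_trial(cfg, state, uniform_prior(2))[0] for _ in range(3)]
        df = records_to_frame(recs)
        assert {"n_samples", "choice", "rt", "confidence"} <= set(df.columns)
        assert len(df) == 3

    def test_max_minus_next_without_partition_rejected(self, numerosity_posterior, rng):
        cfg = TrialConfig(spec=numerosity_posterior, query="estimate",
                          rule=StoppingRule("max_minus_next", delta=2),
                          sampler=SamplerConfig(), anchor="random")
        state = init_state(cfg.sampler, "random", numerosity_posterior, rng)
        with pytest.raises(ValueError):
            run_trial(cfg, state, uniform_prior(2))


def test_production_coverage_below_nominal_at_small_n(rng):
    # order-statistic intervals from 5 i.i.d. draws underrepresent the tails
    spec = gaussian(0.0, 1.0)
    cover = []
    for _ in range(4000):
        lo, hi = ci_produce(rng.normal(size=5), 0.9)
        cover.append(sps.norm.cdf(hi) - sps.norm.cdf(lo))
    assert np.mean(cover) < 0.8
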