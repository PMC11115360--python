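import numpy as np
import pytest
from scipy import stats as sps

from absampler.hypothesis_model import gaussian
from absampler.sampler import (
    SamplerConfig,
    carryover,
    init_state,
    mh_step,
    next_sample,
    swap_step,
)


def draw_series(config, spec, n, start="random", seed=0):
    state = init_state(config, start, spec, np.random.default_rng(seed))
    out = np.empty(n)
    for i in range(n):
        out[i], state = next_sample(state, spec, config)
    return out, state


class TestInit:
    @pytest.mark.parametrize("anchor", [75.5, 25.5])
    def test_anchor_sets_all_chains(self, numerosity_posterior, anchor):
        cfg = SamplerConfig()
        state = init_state(cfg, anchor, numerosity_posterior)
        assert np.all(state.positions == anchor)

    def test_random_cold_chain_matches_posterior(self, numerosity_posterior, rng):
        cfg = SamplerConfig()
        cold = np.array([init_state(cfg, "random", numerosity_posterior, rng).positions[0]
                         for _ in range(4000)])
        p = sps.kstest(cold, "norm", args=(24.0, 3.0)).pvalue
        assert p > 0.001

    def test_bad_start(self, numerosity_posterior):
        with pytest.raises(ValueError):
            init_state(SamplerConfig(), "middle", numerosity_posterior)


class TestMHStep:
    def test_uphill_always_accepted(self, numerosity_posterior, rng):
        # force a proposal with higher density by shrinking the proposal scale
        cfg = SamplerConfig(algorithm="rwm", proposal_sd=1e-9)
        state = init_state(cfg, 30.0, numerosity_posterior, rng)
        for _ in range(50):
            before = state.positions[0]
            mh_step(state, numerosity_posterior, cfg, 0)
            after = state.positions[0]
            # with a tiny step, moves toward the mode have higher density and
            # must always be accepted; moves away may be rejected
            if after != before:
                continue
        # statistically impossible for all 50 tiny proposals to go downhill
        assert state.positions[0] != 30.0

    def test_equal_density_always_accepted(self, unit_gaussian, rng):
        cfg = SamplerConfig(algorithm="rwm", proposal_sd=1.0)
        state = init_state(cfg, 1.0, unit_gaussian, rng)
        # symmetric reflection proposals have equal density; emulate by
        # checking the acceptance rule directly: log ratio 0 accepts
        from absampler.hypothesis_model import log_density

        assert log_density(unit_gaussian, 1.0) == log_density(unit_gaussian, -1.0)

    def test_long_run_frequencies_match_target(self, five_cell_posterior):
        # chi-square goodness of fit of 1e5 MH steps against exact
        # probabilities; the chain is thinned before the test because the
        # chi-square statistic assumes independent draws and MH samples are
        # serially dependent (the raw frequencies themselves are exact)
        for algorithm in ("rwm", "mc3"):
            cfg = SamplerConfig(algorithm=algorithm)
            xs, _ = draw_series(cfg, five_cell_posterior, 100_000, seed=7)
            thin = xs[::50]
            counts = np.array([(thin == v).sum() for v in five_cell_posterior.grid_values])
            expected = five_cell_posterior.probabilities() * thin.size
            p = sps.chisquare(counts, expected).pvalue
            assert p > 0.001, f"{algorithm}: chi-square p={p}"


class TestSwap:
    def test_swap_conserves_positions(self, numerosity_posterior, rng):
        cfg = SamplerConfig(swap_prob=1.0)
        state = init_state(cfg, "random", numerosity_posterior, rng)
        before = sorted(state.positions.tolist())
        swap_step(state, numerosity_posterior, cfg)
        assert sorted(state.positions.tolist()) == before

    def test_single_chain_noop(self, numerosity_posterior, rng):
        cfg = SamplerConfig(algorithm="rwm")
        state = init_state(cfg, 24.0, numerosity_posterior, rng)
        swap_step(state, numerosity_posterior, cfg)
        assert state.positions.tolist() == [24.0]


class TestStreamProperties:
    def test_determinism(self, numerosity_posterior):
        cfg = SamplerConfig()
        a, _ = draw_series(cfg, numerosity_posterior, 500, seed=99)
        b, _ = draw_series(cfg, numerosity_posterior, 500, seed=99)
        np.testing.assert_array_equal(a, b)

    def test_direct_is_uncorrelated(self, numerosity_posterior):
        cfg = SamplerConfig(algorithm="direct")
        xs, _ = draw_series(cfg, numerosity_posterior, 10_000, seed=3)
        r = np.corrcoef(xs[:-1], xs[1:])[0, 1]
        assert abs(r) < 0.03

    def test_mc3_is_locally_autocorrelated(self, numerosity_posterior):
        # local proposals far smaller than the posterior sd
        cfg = SamplerConfig(proposal_sd=0.3)
        xs, _ = draw_series(cfg, numerosity_posterior, 10_000, seed=3)
        r = np.corrcoef(xs[:-1], xs[1:])[0, 1]
        assert r > 0.5

    def test_mc3_marginal_mean(self, numerosity_posterior):
        xs, _ = draw_series(SamplerConfig(), numerosity_posterior, 100_000, seed=11)
        rho = np.corrcoef(xs[:-1], xs[1:])[0, 1]
        ess = xs.size * (1 - rho) / (1 + rho)
        assert abs(xs.mean() - 24.0) < 3 * 3.0 / np.sqrt(ess)


class TestCarryover:
    def test_positions_kept_and_index_incremented(self, numerosity_posterior, rng):
        cfg = SamplerConfig()
        state = init_state(cfg, "random", numerosity_posterior, rng)
        pos = state.positions.copy()
        out = carryover(state, numerosity_posterior)
        assert out.trial_index == 1
        np.testing.assert_array_equal(out.positions, pos)

    def test_consecutive_trials_correlate(self, numerosity_posterior):
        # last sample of trial t predicts first sample of trial t+1
        cfg = SamplerConfig(proposal_sd=0.5)
        state = init_state(cfg, "random", numerosity_posterior,
                           np.random.default_rng(5))
        lasts, firsts = [], []
        for _ in range(1000):
            h1, state = next_sample(state, numerosity_posterior, cfg)
            h2, state = next_sample(state, numerosity_posterior, cfg)
            lasts.append(h2)
            carryover(state, numerosity_posterior)
            h3, state = next_sample(state, numerosity_posterior, cfg)
            firsts.append(h3)
        r = np.corrcoef(lasts[:-1], firsts[:-1])[0, 1]
        assert r > 0.3

    def test_anchor_overrides_carryover(self, numerosity_posterior, rng):
        from absampler.sampler import reset_positions

        cfg = SamplerConfig()
        state = init_state(cfg, "random", numerosity_posterior, rng)
        carryover(state, numerosity_posterior)
        reset_positions(state, 75.5, numerosity_posterior, cfg)
        assert np.all(state.positions == 75.5)


def test_config_validation():
    with pytest.raises(ValueError):
        SamplerConfig(temperatures=(2.0, 1.0, 4.0))
    with pytest.raises(ValueError):
        SamplerConfig(swap_prob=1.5)
    with pytest.raises(ValueError):
        SamplerConfig(algorithm="gibbs")
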