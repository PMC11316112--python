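import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disagreesim.model_core import (
    AgentSpec,
    BeliefSummary,
    GaussianBelief,
    Prior,
    Recommendation,
    StreamSpec,
    combine_streams,
    limit_support,
    posterior_var,
    update_belief,
)
from conftest import grid_posterior_mean

means = st.floats(-5, 5, allow_nan=False)
sds = st.floats(0.05, 3, allow_nan=False)
variances = st.floats(0.01, 5, allow_nan=False)
obs_lists = st.lists(st.floats(-5, 5, allow_nan=False, allow_infinity=False), max_size=30)


class TestTypes:
    def test_stream_spec_rejects_bad_sigma(self):
        with pytest.raises(ValueError, match="sigma"):
            StreamSpec(0.7, 0.0)

    def test_stream_spec_rejects_bad_rate(self):
        with pytest.raises(ValueError, match="rate"):
            StreamSpec(0.7, 0.25, rate=0.0)
        with pytest.raises(ValueError, match="rate"):
            StreamSpec(0.7, 0.25, rate=1.5)

    def test_prior_rejects_nonpositive_variance(self):
        with pytest.raises(ValueError, match="s2"):
            Prior(0.5, 0.0)

    def test_belief_rejects_nonpositive_var(self):
        with pytest.raises(ValueError, match="var"):
            GaussianBelief(0.5, 0.0)

    def test_agent_rejects_bad_weight(self):
        with pytest.raises(ValueError, match="w"):
            AgentSpec(w=1.3)

    def test_agent_rejects_bad_inertia(self):
        with pytest.raises(ValueError, match="inertia"):
            AgentSpec(w=0.5, inertia=1.0)

    def test_summary_sigma_is_sqrt(self):
        s = BeliefSummary(0.4, 0.04, Recommendation.AGAINST)
        assert s.sigma == pytest.approx(0.2)


class TestUpdateBelief:
    def test_no_data_returns_prior(self, prior):
        belief = update_belief(prior, 0.25, [])
        assert (belief.mean, belief.var, belief.n_obs) == (0.5, 1.0, 0)

    def test_single_observation_closed_form(self, prior):
        belief = update_belief(prior, 0.25, [0.7])
        assert belief.mean == pytest.approx(11.7 / 17, abs=1e-12)
        assert belief.var == pytest.approx(1 / 17, abs=1e-12)
        assert belief.n_obs == 1

    def test_single_observation_matches_grid_oracle(self, prior):
        belief = update_belief(prior, 0.25, [0.7])
        oracle = grid_posterior_mean(0.5, 1.0, 0.25, [0.7])
        assert belief.mean == pytest.approx(oracle, abs=1e-6)

    def test_large_n_consistency(self, prior):
        rng = np.random.default_rng(7)
        obs = rng.normal(0.7, 0.25, size=10_000)
        obs = obs - obs.mean() + 0.7  # sample mean exactly 0.7
        belief = update_belief(prior, 0.25, obs)
        assert belief.mean == pytest.approx(0.7, abs=1e-3)

    def test_rejects_nonpositive_sigma(self, prior):
        with pytest.raises(ValueError, match="sigma"):
            update_belief(prior, 0.0, [0.5])

    @given(m=means, s2=variances, sigma=sds, obs=obs_lists)
    @settings(max_examples=40, deadline=None)
    def test_conjugacy_matches_grid_oracle(self, m, s2, sigma, obs):
        belief = update_belief(Prior(m, s2), sigma, obs)
        oracle = grid_posterior_mean(m, s2, sigma, obs)
        assert belief.mean == pytest.approx(oracle, abs=1e-6)

    @given(m=means, s2=variances, sigma=sds, obs1=obs_lists, obs2=obs_lists)
    @settings(max_examples=60, deadline=None)
    def test_sequential_consistency(self, m, s2, sigma, obs1, obs2):
        once = update_belief(Prior(m, s2), sigma, obs1 + obs2)
        first = update_belief(Prior(m, s2), sigma, obs1)
        twice = update_belief(Prior(first.mean, first.var), sigma, obs2)
        assert twice.mean == pytest.approx(once.mean, rel=1e-9, abs=1e-12)
        assert twice.var == pytest.approx(once.var, rel=1e-9, abs=1e-15)

    def test_variance_decreasing_and_value_independent(self, prior):
        rng = np.random.default_rng(0)
        prev = prior.s2
        for n in (1, 2, 5, 10, 100):
            v1 = update_belief(prior, 0.25, rng.normal(0, 1, n)).var
            v2 = update_belief(prior, 0.25, rng.normal(50, 9, n)).var
            assert v1 == pytest.approx(v2, abs=1e-15)
            assert v1 == pytest.approx(posterior_var(prior, 0.25, n))
            assert v1 < prev
            prev = v1


class TestCombineStreams:
    def _belief(self, mean, var=0.01, n=10):
        return GaussianBelief(mean, var, n)

    def test_equal_weights_settles_against(self):
        agent = AgentSpec(w=0.5)
        s = combine_streams(agent, self._belief(0.7), self._belief(0.2), 0.5)
        assert s.mu == pytest.approx(0.45)
        assert s.recommendation is Recommendation.AGAINST

    def test_x_heavy_weights_settles_for(self):
        agent = AgentSpec(w=0.9)
        s = combine_streams(agent, self._belief(0.7), self._belief(0.2), 0.5)
        assert s.mu == pytest.approx(0.65)
        assert s.recommendation is Recommendation.FOR

    def test_degenerate_weight_ignores_stream_y(self):
        agent = AgentSpec(w=1.0)
        bx = self._belief(0.7, var=0.02)
        s = combine_streams(agent, bx, self._belief(-3.0, var=9.0), 0.5)
        assert (s.mu, s.sigma2) == (bx.mean, bx.var)

    def test_tie_recommends_against(self):
        agent = AgentSpec(w=0.5)
        s = combine_streams(agent, self._belief(0.5), self._belief(0.5), 0.5)
        assert s.recommendation is Recommendation.AGAINST

    def test_variance_combines_quadratically(self):
        agent = AgentSpec(w=0.3)
        s = combine_streams(
            agent, self._belief(0.0, var=0.04), self._belief(0.0, var=0.09), 0.5
        )
        assert s.sigma2 == pytest.approx(0.09 * 0.04 + 0.49 * 0.09)

    @given(
        w=st.floats(0, 1, allow_nan=False),
        mx=means,
        my=means,
        vx=variances,
        vy=variances,
    )
    @settings(max_examples=100, deadline=None)
    def test_mu_between_stream_means(self, w, mx, my, vx, vy):
        agent = AgentSpec(w=w)
        s = combine_streams(
            agent, GaussianBelief(mx, vx, 1), GaussianBelief(my, vy, 1), 0.5
        )
        lo, hi = min(mx, my), max(mx, my)
        assert lo - 1e-12 <= s.mu <= hi + 1e-12


class TestLimitSupport:
    def test_pristine_equal_weights(self, fig3_streams):
        assert limit_support(AgentSpec(w=0.5), fig3_streams) == pytest.approx(0.45)

    def test_biased_agent(self, fig3_streams):
        agent = AgentSpec(w=0.5, bias_x=0.2)
        assert limit_support(agent, fig3_streams) == pytest.approx(0.55)

    def test_weight_zero_ignores_x_and_its_bias(self, fig3_streams):
        agent = AgentSpec(w=0.0, bias_x=123.0)
        assert limit_support(agent, fig3_streams) == pytest.approx(0.2)

    def test_simulation_converges_to_limit(self, fig3_streams):
        # empirical final mean within 3 MC standard errors of the limit
        from disagreesim.simulation import SimConfig, run_paired

        sx, sy = fig3_streams
        agent = AgentSpec(w=0.5, bias_x=0.2, name="D")
        cfg = SimConfig(
            stream_x=sx,
            stream_y=sy,
            agents=(agent, AgentSpec(w=0.9, name="R")),
            n_steps=10_000,
            n_runs=30,
            seed=5,
        )
        finals = np.array([t.mu[0, -1] for t in run_paired(cfg)])
        se = finals.std(ddof=1) / math.sqrt(finals.size)
        assert abs(finals.mean() - 0.55) <= 3 * se
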