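import dataclasses

import numpy as np
import pytest

from disagreesim import AgentSpec, Prior, SimConfig, StreamSpec


def grid_posterior_mean(m, s2, sigma, observations, n_grid=400_001, width=10.0):
    """Independent oracle: discretized Bayes rule on a fine grid over the mean.

    Normal prior x product of normal likelihoods, trapezoid-normalised.
    """
    obs = np.asarray(observations, dtype=float)
    pts = np.concatenate(([m], obs)) if obs.size else np.array([m])
    half = width * max(np.sqrt(s2), sigma)
    grid = np.linspace(pts.min() - half, pts.max() + half, n_grid)
    log_post = -((grid - m) ** 2) / (2 * s2)
    for x in obs:
        log_post = log_post - (x - grid) ** 2 / (2 * sigma**2)
    log_post -= log_post.max()
    post = np.exp(log_post)
    return np.trapezoid(grid * post, grid) / np.trapezoid(post, grid)


@pytest.fixture
def prior():
    return Prior(m=0.5, s2=1.0)


@pytest.fixture
def fig3_streams():
    return StreamSpec(0.7, 0.25), StreamSpec(0.2, 0.25)


@pytest.fixture
def small_fig3(fig3_streams):
    """Fig-3 parameters at reduced size for fast integration tests."""
    sx, sy = fig3_streams
    return SimConfig(
        stream_x=sx,
        stream_y=sy,
        agents=(AgentSpec(w=0.5, name="D"), AgentSpec(w=0.9, name="R")),
        n_steps=1_000,
        n_runs=5,
        seed=123,
    )


def with_overrides(config, **kwargs):
    return dataclasses.replace(config, **kwargs)
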