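"""Seeded paired-run Monte Carlo harness.

Both agents consume the *same* raw draws from each stream (their
trajectories are therefore correlated); each agent applies her own additive
bias before updating.  Stream X may emit data more slowly than stream Y:
when Y has delivered ``n_y`` observations, X has delivered
``floor(rate_x / rate_y * n_y)``.

Randomness is organised so that the draws for run ``r`` and stream ``k``
come from an independent substream deterministic in ``(seed, r, k)``;
adding runs never perturbs earlier runs, and two configurations sharing
stream specs and seed see identical data (common random numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.signal import lfilter

from disagreesim.model_core import (
    AgentSpec,
    BeliefSummary,
    Prior,
    Recommendation,
    StreamSpec,
)

__all__ = [
    "SimConfig",
    "Trajectory",
    "draw_shared_data",
    "run_paired",
    "apply_inertia",
    "make_fixture",
    "FIXTURE_NAMES",
]

#: Default number of log-spaced recording points per trajectory.
DEFAULT_N_RECORD = 100


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a paired simulation experiment.

    ``n_steps`` counts observations from stream Y per run (the x-axis of
    the trajectory plots).  ``record_every`` thins the trajectory to every
    k-th step; when ``None`` (default) a log-spaced grid of ``n_record``
    points is used instead, matching the log-scaled evidence axis.
    ``truncate`` renormalises the support posterior onto [0, 1]
    (off by default; the limit formulas are linear).
    """

    stream_x: StreamSpec
    stream_y: StreamSpec
    agents: tuple[AgentSpec, AgentSpec]
    threshold: float = 0.5
    n_steps: int = 10_000
    n_runs: int = 100
    seed: int = 0
    record_every: int | None = None
    n_record: int = DEFAULT_N_RECORD
    truncate: bool = False

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError(f"SimConfig.n_steps must be >= 1, got {self.n_steps}")
        if self.n_runs < 1:
            raise ValueError(f"SimConfig.n_runs must be >= 1, got {self.n_runs}")
        if self.record_every is not None and self.record_every < 1:
            raise ValueError(
                f"SimConfig.record_every must be >= 1, got {self.record_every}"
            )
        if len(self.agents) != 2:
            raise ValueError("SimConfig.agents must hold exactly two agents")

    @property
    def rate_ratio(self) -> float:
        """Observations of X per observation of Y."""
        return self.stream_x.rate / self.stream_y.rate

    def n_x_at(self, n_y: int | np.ndarray) -> int | np.ndarray:
        """Number of X observations available once Y has delivered ``n_y``."""
        return np.floor(self.rate_ratio * np.asarray(n_y) + 1e-12).astype(int)

    def record_grid(self) -> np.ndarray:
        """Recorded steps (values of ``n_y``), monotone, ending at ``n_steps``."""
        if self.record_every is not None:
            grid = np.arange(self.record_every, self.n_steps + 1, self.record_every)
            if grid.size == 0 or grid[-1] != self.n_steps:
                grid = np.append(grid, self.n_steps)
            return grid.astype(int)
        pts = np.logspace(0.0, math.log10(self.n_steps), self.n_record)
        grid = np.unique(np.round(pts).astype(int))
        grid = grid[(grid >= 1) & (grid <= self.n_steps)]
        if grid[-1] != self.n_steps:
            grid = np.append(grid, self.n_steps)
        return grid


@dataclass
class Trajectory:
    """Recorded belief evolution for one paired run.

    Arrays are indexed ``[agent, recorded step]`` except ``steps``/``n_x``
    which are per recorded step.  ``reported`` is the assessment after
    inertia smoothing; with ``inertia == 0`` it equals ``mu``.
    """

    run_id: int
    steps: np.ndarray  # n_y at each recorded step
    n_x: np.ndarray
    mu: np.ndarray  # shape (2, len(steps))
    sigma2: np.ndarray
    reported: np.ndarray
    threshold: float
    agent_names: tuple[str, str] = ("D", "R")

    def recommendation(self, agent: int) -> np.ndarray:
        """FOR/AGAINST per recorded step for one agent."""
        return np.where(
            self.mu[agent] > self.threshold,
            Recommendation.FOR.value,
            Recommendation.AGAINST.value,
        )

    def summary(self, agent: int, step_index: int) -> BeliefSummary:
        """BeliefSummary for one agent at one recorded step."""
        mu = float(self.mu[agent, step_index])
        rec = Recommendation.FOR if mu > self.threshold else Recommendation.AGAINST
        return BeliefSummary(mu=mu, sigma2=float(self.sigma2[agent, step_index]), recommendation=rec)

    @property
    def final_summaries(self) -> tuple[BeliefSummary, BeliefSummary]:
        return self.summary(0, -1), self.summary(1, -1)


def _stream_rng(seed: int, run_index: int, stream_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(run_index, stream_index))
    return np.random.default_rng(ss)


def draw_shared_data(
    config: SimConfig, run_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Raw draws for one run: ``(x_draws, y_draws)``.

    ``y_draws`` has length ``n_steps``; ``x_draws`` has length
    ``n_x_at(n_steps)``.  Deterministic in ``(config.seed, run_index)`` per
    stream; both agents consume these same draws (each adding her own bias).
    """
    n_y = config.n_steps
    n_x = int(config.n_x_at(n_y))
    rng_x = _stream_rng(config.seed, run_index, 0)
    rng_y = _stream_rng(config.seed, run_index, 1)
    x = rng_x.normal(config.stream_x.mu_true, config.stream_x.sigma, size=n_x)
    y = rng_y.normal(config.stream_y.mu_true, config.stream_y.sigma, size=n_y)
    return x, y


def apply_inertia(raw_assessments: Sequence[float], lam: float) -> np.ndarray:
    """Exponentially smooth a sequence of assessments.

    ``reported[t] = lam * reported[t-1] + (1 - lam) * raw[t]`` with
    ``reported[0] = raw[0]``.  With ``lam == 0`` the input is returned
    unchanged.  This smoothing rule is a documented reconstruction: the
    scenario descriptions call for updating inertia without fixing a
    mechanism.
    """
    if not 0 <= lam < 1:
        raise ValueError(f"inertia coefficient must be in [0, 1), got {lam}")
    x = np.asarray(raw_assessments, dtype=float)
    if x.size == 0:
        return x.copy()
    if lam == 0:
        return x.copy()
    # IIR filter y[t] - lam*y[t-1] = (1-lam)*x[t], initialised so y[0]=x[0].
    y, _ = lfilter([1.0 - lam], [1.0, -lam], x, zi=np.array([lam * x[0]]))
    return y


def _posterior_mean_path(
    prior: Prior, sigma: float, cumsum: np.ndarray, n: np.ndarray
) -> np.ndarray:
    """Posterior means after each prefix of observations (vectorised)."""
    precision = 1.0 / prior.s2 + n / sigma**2
    return (prior.m / prior.s2 + cumsum / sigma**2) / precision


def _posterior_var_path(prior: Prior, sigma: float, n: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 / prior.s2 + n / sigma**2)


def _truncated_moments(mu: np.ndarray, sigma2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean/variance of the support posterior renormalised onto [0, 1]."""
    sd = np.sqrt(sigma2)
    a = (0.0 - mu) / sd
    b = (1.0 - mu) / sd
    tmean = stats.truncnorm.mean(a, b, loc=mu, scale=sd)
    tvar = stats.truncnorm.var(a, b, loc=mu, scale=sd)
    return np.asarray(tmean, dtype=float), np.asarray(tvar, dtype=float)


def _run_one(config: SimConfig, run_index: int) -> Trajectory:
    x_raw, y_raw = draw_shared_data(config, run_index)
    steps = np.arange(0, config.n_steps + 1)  # n_y = 0 .. n_steps
    n_x_path = config.n_x_at(steps)
    grid = config.record_grid()

    mu_all = np.empty((2, grid.size))
    sigma2_all = np.empty((2, grid.size))
    reported_all = np.empty((2, grid.size))

    for a, agent in enumerate(config.agents):
        # Prefix sums of biased observations; index k = sum of first k obs.
        cs_x = np.concatenate(([0.0], np.cumsum(x_raw + agent.bias_x)))
        cs_y = np.concatenate(([0.0], np.cumsum(y_raw + agent.bias_y)))
        mean_x = _posterior_mean_path(
            agent.prior_x, config.stream_x.sigma, cs_x[n_x_path], n_x_path
        )
        mean_y = _posterior_mean_path(agent.prior_y, config.stream_y.sigma, cs_y[steps], steps)
        var_x = _posterior_var_path(agent.prior_x, config.stream_x.sigma, n_x_path)
        var_y = _posterior_var_path(agent.prior_y, config.stream_y.sigma, steps)

        w = agent.w
        mu = w * mean_x + (1.0 - w) * mean_y
        sigma2 = w**2 * var_x + (1.0 - w) ** 2 * var_y
        if config.truncate:
            mu, sigma2 = _truncated_moments(mu, sigma2)
        reported = apply_inertia(mu, agent.inertia)

        mu_all[a] = mu[grid]
        sigma2_all[a] = sigma2[grid]
        reported_all[a] = reported[grid]

    names = tuple(
        agent.name or default for agent, default in zip(config.agents, ("D", "R"))
    )
    return Trajectory(
        run_id=run_index,
        steps=grid,
        n_x=config.n_x_at(grid),
        mu=mu_all,
        sigma2=sigma2_all,
        reported=reported_all,
        threshold=config.threshold,
        agent_names=names,  # type: ignore[arg-type]
    )


def run_paired(config: SimConfig) -> list[Trajectory]:
    """Run ``config.n_runs`` paired simulations.

    At each recorded step each agent's beliefs equal the conjugate update
    on the data seen so far (after her bias), combined with her weight;
    the reported assessment additionally applies inertia smoothing.
    """
    return [_run_one(config, r) for r in range(config.n_runs)]


# ---------------------------------------------------------------------------
# Published scenario fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("fig3", "fig4", "fig5_equal", "fig5_slow", "fig5_slow_inertia")

#: Default inertia coefficient for the inertia scenario (a reconstruction;
#: the scenario description does not print one).
DEFAULT_INERTIA = 0.9


def make_fixture(name: str) -> SimConfig:
    """Exact published scenario parameters by name.

    * ``fig3`` — streams (0.7, 0.2), sigma 0.25, weights (0.5, 0.9),
      prior mean 0.5, threshold 0.5, 100 runs.
    * ``fig4`` — same streams; one agent weights equally (0.5), the other
      discounts stream Y entirely (1.0) — the extreme uncertainty contrast.
    * ``fig5_equal`` / ``fig5_slow`` / ``fig5_slow_inertia`` — streams
      (0.8, 0.2), equal weights; the slow variants emit X at one tenth of
      Y's rate; the inertia variant smooths reported assessments.

    Unprinted values (prior variance 1, inertia 0.9, 10_000 steps) are
    documented defaults.
    """
    prior = Prior(m=0.5, s2=1.0)

    def agent(w: float, inertia: float = 0.0, name: str = "") -> AgentSpec:
        return AgentSpec(w=w, prior_x=prior, prior_y=prior, inertia=inertia, name=name)

    if name == "fig3":
        return SimConfig(
            stream_x=StreamSpec(0.7, 0.25),
            stream_y=StreamSpec(0.2, 0.25),
            agents=(agent(0.5, name="D"), agent(0.9, name="R")),
        )
    if name == "fig4":
        return SimConfig(
            stream_x=StreamSpec(0.7, 0.25),
            stream_y=StreamSpec(0.2, 0.25),
            agents=(agent(0.5, name="D"), agent(1.0, name="R")),
        )
    if name in ("fig5_equal", "fig5_slow", "fig5_slow_inertia"):
        rate_x = 1.0 if name == "fig5_equal" else 0.1
        inertia = DEFAULT_INERTIA if name == "fig5_slow_inertia" else 0.0
        return SimConfig(
            stream_x=StreamSpec(0.8, 0.25, rate=rate_x),
            stream_y=StreamSpec(0.2, 0.25),
            agents=(agent(0.5, inertia, name="D"), agent(0.5, inertia, name="R")),
        )
    raise KeyError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )


def with_overrides(config: SimConfig, **kwargs) -> SimConfig:
    """Return a copy of ``config`` with fields replaced."""
    return replace(config, **kwargs)
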