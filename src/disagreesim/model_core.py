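"""Conjugate Gaussian belief updating and weighted belief combination.

Each evidence stream emits i.i.d. Gaussian observations with unknown mean
and known standard deviation.  An agent holds a Gaussian prior over each
stream's mean, updates it by standard normal–normal conjugacy, and
combines the two per-stream posterior means with a personal weight
``w`` into a single posterior over policy support:

    mu     = w * mean_x + (1 - w) * mean_y
    sigma2 = w**2 * var_x + (1 - w)**2 * var_y

(the streams are independent).  The agent recommends FOR the policy when
``mu`` exceeds the decision threshold, AGAINST otherwise (ties resolve
AGAINST — the status-quo default).

A biased agent sees each observation from a stream shifted by an additive
offset ``b``, so her posterior mean for that stream converges to the true
mean plus ``b``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "StreamSpec",
    "Prior",
    "GaussianBelief",
    "AgentSpec",
    "Recommendation",
    "BeliefSummary",
    "update_belief",
    "combine_streams",
    "limit_support",
]


class Recommendation(str, enum.Enum):
    """Binary policy recommendation."""

    FOR = "FOR"
    AGAINST = "AGAINST"


@dataclass(frozen=True)
class StreamSpec:
    """A data-generating evidence stream.

    Parameters
    ----------
    mu_true : float
        True stream mean, unknown to the agents.
    sigma : float
        Known observation standard deviation; must be positive.
    rate : float, default 1.0
        Relative data-emission speed in ``(0, 1]``.  A stream with
        ``rate=0.1`` has delivered ``floor(0.1 * n)`` observations by the
        time the reference stream has delivered ``n``.
    """

    mu_true: float
    sigma: float
    rate: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"StreamSpec.sigma must be positive, got {self.sigma}")
        if not 0 < self.rate <= 1:
            raise ValueError(f"StreamSpec.rate must be in (0, 1], got {self.rate}")


@dataclass(frozen=True)
class Prior:
    """Gaussian prior over a stream's unknown mean."""

    m: float = 0.5
    s2: float = 1.0

    def __post_init__(self) -> None:
        if not self.s2 > 0:
            raise ValueError(f"Prior.s2 must be positive, got {self.s2}")


@dataclass(frozen=True)
class GaussianBelief:
    """Posterior over one stream's unknown mean after ``n_obs`` observations."""

    mean: float
    var: float
    n_obs: int = 0

    def __post_init__(self) -> None:
        if not self.var > 0:
            raise ValueError(f"GaussianBelief.var must be positive, got {self.var}")
        if self.n_obs < 0:
            raise ValueError(f"GaussianBelief.n_obs must be >= 0, got {self.n_obs}")

    @property
    def sd(self) -> float:
        return math.sqrt(self.var)


@dataclass(frozen=True)
class AgentSpec:
    """An agent: stream weight, per-stream observation bias, priors, inertia.

    ``w`` is the weight on stream X; stream Y receives ``1 - w``.
    ``bias_x``/``bias_y`` are additive offsets applied to every observation
    the agent receives from the respective stream (zero in the pristine
    case).  ``inertia`` is the exponential-smoothing coefficient applied to
    the agent's *reported* assessment (0 = report the posterior mean
    directly).
    """

    w: float
    bias_x: float = 0.0
    bias_y: float = 0.0
    prior_x: Prior = field(default_factory=Prior)
    prior_y: Prior = field(default_factory=Prior)
    inertia: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.w <= 1:
            raise ValueError(f"AgentSpec.w must be in [0, 1], got {self.w}")
        if not 0 <= self.inertia < 1:
            raise ValueError(f"AgentSpec.inertia must be in [0, 1), got {self.inertia}")


@dataclass(frozen=True)
class BeliefSummary:
    """Posterior over policy support plus the threshold recommendation."""

    mu: float
    sigma2: float
    recommendation: Recommendation

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise ValueError(f"BeliefSummary.sigma2 must be positive, got {self.sigma2}")

    @property
    def sigma(self) -> float:
        return math.sqrt(self.sigma2)


def update_belief(
    prior: Prior, sigma: float, observations: Sequence[float]
) -> GaussianBelief:
    """Conjugate normal–normal update with known observation SD.

    Returns the Gaussian posterior over the stream mean:

        mean = (m / s2 + n * xbar / sigma**2) / (1 / s2 + n / sigma**2)
        var  = 1 / (1 / s2 + n / sigma**2)

    With no observations the prior is returned unchanged.

    Raises
    ------
    ValueError
        If ``sigma`` is not positive.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    obs = np.asarray(observations, dtype=float)
    n = obs.size
    if n == 0:
        return GaussianBelief(mean=prior.m, var=prior.s2, n_obs=0)
    precision = 1.0 / prior.s2 + n / sigma**2
    mean = (prior.m / prior.s2 + obs.sum() / sigma**2) / precision
    return GaussianBelief(mean=float(mean), var=1.0 / precision, n_obs=int(n))


def posterior_var(prior: Prior, sigma: float, n: int) -> float:
    """Closed-form posterior variance after ``n`` observations.

    Independent of the observed values; strictly decreasing in ``n``.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return 1.0 / (1.0 / prior.s2 + n / sigma**2)


def combine_streams(
    agent: AgentSpec,
    belief_x: GaussianBelief,
    belief_y: GaussianBelief,
    threshold: float,
) -> BeliefSummary:
    """Combine two per-stream posteriors into a posterior over policy support.

    ``mu = w * mean_x + (1 - w) * mean_y`` and, by independence of the
    streams, ``sigma2 = w**2 * var_x + (1 - w)**2 * var_y``.  Recommends
    FOR iff ``mu > threshold``.
    """
    w = agent.w
    mu = w * belief_x.mean + (1.0 - w) * belief_y.mean
    sigma2 = w**2 * belief_x.var + (1.0 - w) ** 2 * belief_y.var
    rec = Recommendation.FOR if mu > threshold else Recommendation.AGAINST
    return BeliefSummary(mu=mu, sigma2=sigma2, recommendation=rec)


def limit_support(agent: AgentSpec, streams: tuple[StreamSpec, StreamSpec]) -> float:
    """Deterministic large-sample limit of the agent's support mean.

    The per-stream posterior mean converges to the true mean plus the
    agent's bias on that stream, so the support mean converges to
    ``w * (mu_x + b_x) + (1 - w) * (mu_y + b_y)``.
    """
    sx, sy = streams
    return agent.w * (sx.mu_true + agent.bias_x) + (1.0 - agent.w) * (
        sy.mu_true + agent.bias_y
    )
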