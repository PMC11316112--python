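"""Classify and quantify support, policy and uncertainty disagreement.

Support disagreement: the agents' posterior support means differ.
Policy disagreement: their threshold recommendations differ (this entails
support disagreement).  Uncertainty disagreement: their posterior standard
deviations differ.

Analytic comparisons use a tiny tolerance ``EPS_ANALYTIC``; for noisy
finite-sample classification a larger documented tolerance
``EPS_EMPIRICAL`` is more appropriate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from disagreesim.model_core import BeliefSummary, Prior, posterior_var

__all__ = [
    "DisagreementRecord",
    "AggregateDisagreement",
    "classify",
    "aggregate",
    "uncertainty_curve",
    "uncertainty_ratio",
    "EPS_ANALYTIC",
    "EPS_EMPIRICAL",
]

EPS_ANALYTIC = 1e-9
EPS_EMPIRICAL = 0.01


@dataclass(frozen=True)
class DisagreementRecord:
    """One pairwise comparison of two agents' belief summaries.

    ``uncertainty_magnitude`` is on the SD scale; the variance-scale
    magnitude is also carried for reporting.
    """

    support: bool
    support_magnitude: float
    policy: bool
    uncertainty: bool
    uncertainty_magnitude: float
    uncertainty_magnitude_var: float = 0.0

    def __post_init__(self) -> None:
        if self.policy and not self.support:
            raise ValueError("policy disagreement entails support disagreement")
        if self.support_magnitude < 0 or self.uncertainty_magnitude < 0:
            raise ValueError("disagreement magnitudes must be non-negative")


@dataclass(frozen=True)
class AggregateDisagreement:
    """Disagreement summarised across runs at one step."""

    policy_rate: float
    support_rate: float
    uncertainty_rate: float
    mean_support_magnitude: float
    mean_uncertainty_magnitude: float
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.policy_rate <= 1:
            raise ValueError(f"policy_rate must be in [0, 1], got {self.policy_rate}")


def classify(
    belief_d: BeliefSummary,
    belief_r: BeliefSummary,
    epsilon: float = EPS_ANALYTIC,
) -> DisagreementRecord:
    """Classify the disagreement between two belief summaries.

    Both summaries must have been computed against the same threshold.
    Support and uncertainty comparisons use ``epsilon``; uncertainty is
    compared on the SD scale.
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be non-negative, got {epsilon}")
    support_mag = abs(belief_d.mu - belief_r.mu)
    support = support_mag > epsilon
    policy = belief_d.recommendation != belief_r.recommendation
    if policy:
        # recommendations can only differ if the means do
        support = True
    unc_mag_sd = abs(belief_d.sigma - belief_r.sigma)
    unc_mag_var = abs(belief_d.sigma2 - belief_r.sigma2)
    return DisagreementRecord(
        support=support,
        support_magnitude=support_mag,
        policy=policy,
        uncertainty=unc_mag_sd > epsilon,
        uncertainty_magnitude=unc_mag_sd,
        uncertainty_magnitude_var=unc_mag_var,
    )


def aggregate(records: Iterable[DisagreementRecord]) -> AggregateDisagreement:
    """Aggregate per-run records at one step into rates and mean magnitudes."""
    recs = list(records)
    if not recs:
        raise ValueError("cannot aggregate an empty set of disagreement records")
    n = len(recs)
    return AggregateDisagreement(
        policy_rate=sum(r.policy for r in recs) / n,
        support_rate=sum(r.support for r in recs) / n,
        uncertainty_rate=sum(r.uncertainty for r in recs) / n,
        mean_support_magnitude=float(np.mean([r.support_magnitude for r in recs])),
        mean_uncertainty_magnitude=float(
            np.mean([r.uncertainty_magnitude for r in recs])
        ),
        n=n,
    )


def uncertainty_curve(
    weight_grid: Sequence[float],
    n: int,
    prior: Prior,
    sigma: float,
    prior_y: Prior | None = None,
    sigma_y: float | None = None,
    n_y: int | None = None,
) -> dict[float, float]:
    """Posterior support variance as a function of the stream weight.

    With equal stream parameters (the default: ``prior_y``, ``sigma_y`` and
    ``n_y`` fall back to the X values) this is

        sigma2(w) = (w**2 + (1 - w)**2) * v(n),   v(n) = 1/(1/s2 + n/sigma**2)

    which is symmetric around ``w = 0.5`` and minimised there: the agent
    weighting the streams equally treats herself as having twice the
    information of an agent who discounts one stream entirely.
    """
    weights = np.asarray(weight_grid, dtype=float)
    if weights.size and (weights.min() < 0 or weights.max() > 1):
        raise ValueError("weights must lie in [0, 1]")
    v_x = posterior_var(prior, sigma, n)
    v_y = posterior_var(
        prior_y if prior_y is not None else prior,
        sigma_y if sigma_y is not None else sigma,
        n_y if n_y is not None else n,
    )
    values = weights**2 * v_x + (1.0 - weights) ** 2 * v_y
    return {float(w): float(v) for w, v in zip(weights, values)}


def uncertainty_ratio(n: int, prior: Prior, sigma: float) -> float:
    """Variance ratio sigma2(w=0 or 1) / sigma2(w=0.5), equal streams.

    Exactly 2 under the linear-combination posterior with equal priors
    and observation SDs, for any n.
    """
    curve = uncertainty_curve([0.0, 0.5], n, prior, sigma)
    return curve[0.0] / curve[0.5]
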