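"""Can a biased agent be told apart from a weights-only agent?

An agent's support mean converges to ``w*(mu_x + b_x) + (1-w)*(mu_y + b_y)``.
Observing only that limit, any value inside the closed interval spanned by
the true stream means is also reachable by some bias-free weight ``w*`` —
so a faulty (biased) configuration and a faultless (weights-only) one are
empirically indistinguishable whenever the limit lies in that interval.
Only limits *outside* the interval force the conclusion that bias was
involved.

Indistinguishability is operationalised as equality of limiting support
means — the only post-hoc observable the model exposes absent disclosure of
weights and interpretations.  Posterior-uncertainty observables could break
ties if reported; they are exposed separately and not folded into the
diagnosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from disagreesim.simulation import SimConfig, run_paired

__all__ = [
    "ObservedLimits",
    "Diagnosis",
    "equivalent_faultless_weight",
    "diagnose",
    "diagnose_estimated",
    "equivalence_check",
]


@dataclass(frozen=True)
class ObservedLimits:
    """Limiting support means of the two agents plus the true stream means."""

    c_d: float
    c_r: float
    mu_x: float
    mu_y: float


@dataclass(frozen=True)
class Diagnosis:
    """Outcome of the indistinguishability analysis for one agent."""

    equivalent_weight: float | None
    indistinguishable: bool
    degenerate: bool
    explanation: str

    def __post_init__(self) -> None:
        ok = self.equivalent_weight is not None and 0 <= self.equivalent_weight <= 1
        if self.indistinguishable != ok:
            raise ValueError(
                "indistinguishable must hold exactly when an equivalent "
                "weight exists in [0, 1]"
            )

    def to_dict(self) -> dict:
        return {
            "equivalent_weight": self.equivalent_weight,
            "indistinguishable": self.indistinguishable,
            "degenerate": self.degenerate,
            "explanation": self.explanation,
        }


def equivalent_faultless_weight(
    c: float, mu_x: float, mu_y: float
) -> float | None:
    """Solve ``w* mu_x + (1 - w*) mu_y = c`` for the bias-free weight.

    Returns ``w* = (c - mu_y) / (mu_x - mu_y)`` when the stream means
    differ (possibly outside [0, 1]); ``None`` when ``mu_x == mu_y != c``
    (no weight can produce ``c``); and 0.5 in the degenerate case
    ``mu_x == mu_y == c`` where every weight works.
    """
    if mu_x == mu_y:
        return 0.5 if c == mu_x else None
    return (c - mu_y) / (mu_x - mu_y)


def _diagnose_one(c: float, mu_x: float, mu_y: float, label: str) -> Diagnosis:
    # Decide by hull membership (exact in floats); the algebraic weight can
    # land a rounding error outside [0, 1] for limits at the hull boundary.
    lo, hi = min(mu_x, mu_y), max(mu_x, mu_y)
    inside = lo <= c <= hi
    w_star = equivalent_faultless_weight(c, mu_x, mu_y)
    if inside and w_star is not None:
        w_star = min(max(w_star, 0.0), 1.0)
    degenerate = mu_x == mu_y and c == mu_x
    if inside and w_star is not None:
        if degenerate:
            expl = (
                f"agent {label}: streams coincide at {mu_x}; every weight "
                f"reproduces the limit {c} without bias (reported as w*=0.5)"
            )
        else:
            expl = (
                f"agent {label}: the bias-free configuration (w*={w_star:.6g}, "
                f"b=0) reproduces the limit {c}; faulty and faultless "
                "explanations are empirically indistinguishable"
            )
        return Diagnosis(w_star, True, degenerate, expl)
    if w_star is None:
        expl = (
            f"agent {label}: streams coincide at {mu_x} but the limit is {c}; "
            "no weight reproduces it — bias must be invoked"
        )
    else:
        expl = (
            f"agent {label}: limit {c} lies outside [{lo}, {hi}] "
            f"(w*={w_star:.6g} not in [0, 1]) — bias must be invoked"
        )
    return Diagnosis(None, False, False, expl)


def diagnose(limits: ObservedLimits) -> tuple[Diagnosis, Diagnosis]:
    """Diagnose each agent's limiting belief for distinguishability."""
    return (
        _diagnose_one(limits.c_d, limits.mu_x, limits.mu_y, "D"),
        _diagnose_one(limits.c_r, limits.mu_x, limits.mu_y, "R"),
    )


def diagnose_estimated(
    limits: ObservedLimits, se_d: float, se_r: float, z: float = 3.0
) -> tuple[Diagnosis, Diagnosis]:
    """Diagnosis variant for finite-sample limit estimates with standard errors.

    An agent is flagged distinguishable only when the whole interval
    ``c ± z*se`` falls outside the convex hull of the stream means; the
    witnessing weight is computed at the point estimate clipped to the hull.
    """
    if se_d < 0 or se_r < 0:
        raise ValueError("standard errors must be non-negative")
    lo, hi = min(limits.mu_x, limits.mu_y), max(limits.mu_x, limits.mu_y)

    def one(c: float, se: float, label: str) -> Diagnosis:
        if c + z * se < lo or c - z * se > hi:
            return _diagnose_one(c, limits.mu_x, limits.mu_y, label)
        return _diagnose_one(
            min(max(c, lo), hi), limits.mu_x, limits.mu_y, label
        )

    return one(limits.c_d, se_d, "D"), one(limits.c_r, se_r, "R")


def _final_means(config: SimConfig, agent: int) -> np.ndarray:
    trajectories = run_paired(config)
    return np.array([t.mu[agent, -1] for t in trajectories])


def equivalence_check(
    config_a: SimConfig,
    config_b: SimConfig,
    n: int | None = None,
    n_runs: int | None = None,
    agent: int = 0,
) -> bool:
    """Numerically test whether two configurations are indistinguishable.

    Runs both configurations on common random numbers (they must share
    stream specs, threshold and seed semantics) and compares the
    run-averaged final support means of the chosen agent: returns ``True``
    when the difference is below three combined Monte Carlo standard
    errors.
    """
    from dataclasses import replace

    if (
        config_a.stream_x != config_b.stream_x
        or config_a.stream_y != config_b.stream_y
        or config_a.threshold != config_b.threshold
    ):
        raise ValueError(
            "equivalence_check requires both configs to share stream specs "
            "and threshold"
        )
    overrides = {}
    if n is not None:
        overrides["n_steps"] = n
    if n_runs is not None:
        overrides["n_runs"] = n_runs
    ca = replace(config_a, **overrides) if overrides else config_a
    cb = replace(config_b, **overrides) if overrides else config_b

    means_a = _final_means(ca, agent)
    means_b = _final_means(cb, agent)
    diff = abs(means_a.mean() - means_b.mean())
    se = math.sqrt(
        means_a.var(ddof=1) / means_a.size + means_b.var(ddof=1) / means_b.size
    )
    # Guard against a zero SE when both configs are literally identical.
    return diff <= 3.0 * se or diff == 0.0
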