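"""Limiting disjunctive power and the information / sample-size search.

The design is powered at the configuration with one arm at the desirable
efficacy effect ``delta``, the remaining ``K-1`` arms at the minimum
clinically important effect ``delta0``, and every arm safe (safety effects
taken to infinity).  In that limit the rejection event reduces to the
selected arm's efficacy statistic clearing ``u_E``, and the power is the
probability that this happens whichever arm is selected.

The search assumes a common information level ``I_E = I_S = I1`` (for
computational convenience), re-solves the boundaries at every candidate
``I1`` and finds the root of ``power(I1) = 1 - beta``.  The fractional
per-arm sample size ``n = 2 max(sigma_E^2, sigma_S^2) I1*`` is rounded up
to a whole patient, and the boundaries are re-computed at the information
levels the rounded size implies — a conservative rounding, since power is
increasing in information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from . import _geometry, model
from .boundaries import Boundaries, solve_boundaries, solve_efficacy_boundary
from .design import DesignSpec, EffectConfiguration

__all__ = ["DesignSolution", "limiting_power", "solve_information", "power_with_finite_safety"]

#: tolerance of the one-dimensional information search (power scale)
POWER_TOL = 1e-4


@dataclass(frozen=True)
class DesignSolution:
    """Solved single-stage design."""

    I_star: float  # common per-arm information at the exact power root
    n_unrounded: float  # 2 max(sigma_E^2, sigma_S^2) I_star
    n_star: int  # rounded-up per-arm sample size
    boundaries_at_I_star: Boundaries
    boundaries: Boundaries  # at the information levels implied by n_star
    attained_power: float  # limiting power at the rounded size


def limiting_power(
    spec: DesignSpec,
    info_E: float,
    info_S: float,
    u_E: float,
    theta_E=None,
    method: str = "integration",
    n_reps: int = 100_000,
    seed=0,
) -> float:
    """Limiting probability of rejection when every arm is safe.

    ``theta_E`` defaults to the powering configuration
    ``(delta0, ..., delta0, delta)``.  The Monte-Carlo route simulates score
    statistics with safety effects at the large surrogate and applies the
    full selection rule.
    """
    if theta_E is None:
        theta_E = EffectConfiguration.power_config(spec).theta_E
    theta_E = np.asarray(theta_E, dtype=float)
    if method == "integration":
        geom = _geometry.SelectionGeometry.from_spec(spec, info_E, info_S)
        return _geometry.efficacy_selected_upper_tail(u_E, spec, geom, theta_E)
    if method == "monte_carlo":
        config = EffectConfiguration(theta_E, np.full(spec.n_arms, spec.gamma_surrogate))
        Z_E, Z_S = model.simulate_scores(spec, config, info_E, info_S, n_reps, seed)
        i_star, any_safe = model.select_vectorized(Z_E, Z_S, spec, info_E, info_S)
        rows = np.arange(n_reps)
        return float((any_safe & (Z_E[rows, i_star] >= u_E)).mean())
    raise ValueError(f"unknown method {method!r}")


def _closed_form_info(spec: DesignSpec) -> float:
    """Classical one-sided fixed-sample information for one comparison."""
    z_a = stats.norm.ppf(1.0 - spec.alpha)
    z_b = stats.norm.ppf(1.0 - spec.beta)
    return (z_a + z_b) ** 2 / spec.delta**2


def solve_information(spec: DesignSpec, method: str = "integration") -> DesignSolution:
    """One-dimensional search for the common information ``I1*`` attaining
    disjunctive power ``1 - beta``, boundaries re-solved at each candidate.
    """
    target = 1.0 - spec.beta

    def attained(info):
        u_E = solve_efficacy_boundary(spec, info, info, method=method)
        return limiting_power(spec, info, info, u_E, method=method)

    # Bracket around the no-selection closed form, expanded geometrically.
    # xtol matches the power tolerance: |dP/dI| is of order 5e-3 per unit
    # information for designs in the validated range.
    base = _closed_form_info(spec)
    lo, hi = 0.8 * base, 3.0 * base
    f_lo, f_hi = attained(lo) - target, attained(hi) - target
    n_expand = 0
    while f_lo > 0.0 and n_expand < 30:
        lo *= 0.5
        f_lo = attained(lo) - target
        n_expand += 1
    while f_hi < 0.0 and n_expand < 30:
        hi *= 2.0
        f_hi = attained(hi) - target
        n_expand += 1
    if f_lo > 0.0 or f_hi < 0.0:
        raise RuntimeError("target power unreachable within information bracket")
    I_star = optimize.brentq(lambda info: attained(info) - target, lo, hi, xtol=2e-3)

    b_star = solve_boundaries(spec, I_star, I_star, method=method)
    n_unrounded = 2.0 * max(spec.sigma_E**2, spec.sigma_S**2) * I_star
    n_star = int(np.ceil(n_unrounded - 1e-9))
    info_E, info_S = spec.information(n_star)
    b_final = solve_boundaries(spec, info_E, info_S, method=method)
    attained_power = limiting_power(spec, info_E, info_S, b_final.u_E, method=method)
    return DesignSolution(
        I_star=float(I_star),
        n_unrounded=float(n_unrounded),
        n_star=n_star,
        boundaries_at_I_star=b_star,
        boundaries=b_final,
        attained_power=float(attained_power),
    )


def power_with_finite_safety(
    config: EffectConfiguration,
    spec: DesignSpec,
    solution: DesignSolution,
    n_reps: int = 100_000,
    seed=0,
):
    """Empirical power of a solved design under finite safety effects.

    With a finite common safety effect the gate may exclude arms and the
    safety margin ``Z_S,i* >= u_S`` genuinely binds, so this is evaluated by
    simulation of the full bivariate rule.  Returns ``(power, s.e.)``.
    """
    b = solution.boundaries
    return model.simulate_rejection_rate(
        spec, config, b, b.info_E, b.info_S, n_reps, seed
    )
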