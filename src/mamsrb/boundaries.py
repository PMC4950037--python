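"""Single-stage rejection boundaries controlling the FWER in the strong
sense.

Boundaries are calibrated in the two worst-case limiting configurations:

* efficacy criterion — efficacy effects at the null boundary, safety
  effects huge and equal: every arm is eligible and the test rejects when
  the selected arm's efficacy statistic clears ``u_E``; the limiting
  probability must equal ``alpha``;
* safety criterion — safety effects at the null boundary, efficacy effects
  huge and equal: conditional on at least one arm passing the gate, the
  selected arm's safety statistic must clear ``u_S`` with limiting
  conditional probability ``alpha / P(N_S >= 1; theta_S = 0)``.

The two root searches are uncoupled.  Each limiting probability has a
deterministic quadrature route (:mod:`mamsrb._geometry`) and a Monte-Carlo
route simulating score statistics at the large-effect surrogate; the
simulator is the independent oracle for the quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from . import _geometry, model
from .design import DesignSpec, EffectConfiguration

__all__ = [
    "Boundaries",
    "LimitingProbabilityEstimate",
    "limiting_efficacy_rejection",
    "limiting_safety_rejection",
    "solve_boundaries",
]

#: absolute tolerance on solved boundaries (score scale)
BOUNDARY_TOL = 1e-4


@dataclass(frozen=True)
class Boundaries:
    u_E: float
    u_S: float
    info_E: float
    info_S: float


@dataclass(frozen=True)
class LimitingProbabilityEstimate:
    value: float
    standard_error: float  # 0 for the integration route
    method: str  # "integration" | "monte_carlo"


def _mc_selected_scores(spec, info_E, info_S, n_reps, seed, limit: str):
    """Selected-arm score statistics under one limiting configuration."""
    K = spec.n_arms
    g = spec.gamma_surrogate
    if limit == "efficacy":  # theta_E = 0, theta_S huge
        config = EffectConfiguration.common(K, 0.0, g)
    elif limit == "safety":  # theta_E huge, theta_S = 0
        config = EffectConfiguration.common(K, g, 0.0)
    else:  # pragma: no cover
        raise ValueError(limit)
    Z_E, Z_S = model.simulate_scores(spec, config, info_E, info_S, n_reps, seed)
    i_star, any_safe = model.select_vectorized(Z_E, Z_S, spec, info_E, info_S)
    rows = np.arange(n_reps)
    return Z_E[rows, i_star], Z_S[rows, i_star], any_safe


def limiting_efficacy_rejection(
    u_E: float,
    spec: DesignSpec,
    info_E: float,
    info_S: float,
    method: str = "integration",
    n_reps: int = 100_000,
    seed=0,
) -> LimitingProbabilityEstimate:
    """Limiting probability that the selected arm's efficacy statistic
    clears ``u_E`` when all arms are eligible and efficacy is null."""
    if method == "integration":
        geom = _geometry.SelectionGeometry.from_spec(spec, info_E, info_S)
        p = _geometry.efficacy_selected_upper_tail(u_E, spec, geom)
        return LimitingProbabilityEstimate(p, 0.0, method)
    if method == "monte_carlo":
        zE, _, any_safe = _mc_selected_scores(spec, info_E, info_S, n_reps, seed, "efficacy")
        hit = (zE >= u_E) & any_safe
        p = float(hit.mean())
        return LimitingProbabilityEstimate(p, float(np.sqrt(p * (1 - p) / n_reps)), method)
    raise ValueError(f"unknown method {method!r}")


def limiting_safety_rejection(
    u_S: float,
    spec: DesignSpec,
    info_E: float,
    info_S: float,
    method: str = "integration",
    n_reps: int = 100_000,
    seed=0,
) -> LimitingProbabilityEstimate:
    """Limiting *conditional* probability (given ``N_S >= 1``) that the
    selected arm's safety statistic clears ``u_S``, safety effects null."""
    p_any = model.prob_any_safe(spec, info_S)
    if method == "integration":
        geom = _geometry.SelectionGeometry.from_spec(spec, info_E, info_S)
        joint = _geometry.safety_selected_upper_tail_joint(u_S, spec, geom)
        return LimitingProbabilityEstimate(joint / p_any, 0.0, method)
    if method == "monte_carlo":
        _, zS, any_safe = _mc_selected_scores(spec, info_E, info_S, n_reps, seed, "safety")
        hit = (zS >= u_S) & any_safe
        p = float(hit.mean()) / p_any
        se = float(np.sqrt(hit.mean() * (1 - hit.mean()) / n_reps)) / p_any
        return LimitingProbabilityEstimate(p, se, method)
    raise ValueError(f"unknown method {method!r}")


def _bracketed_root(f, lo, hi, grow=2.0, max_expand=60):
    """Brentq with geometric bracket expansion; f decreasing in u."""
    flo, fhi = f(lo), f(hi)
    n = 0
    while flo < 0.0 and n < max_expand:  # root below lo
        lo -= grow * (hi - lo)
        flo = f(lo)
        n += 1
    while fhi > 0.0 and n < max_expand:  # root above hi
        hi += grow * (hi - lo)
        fhi = f(hi)
        n += 1
    if flo < 0.0 or fhi > 0.0:
        raise RuntimeError("boundary root bracketing failed")
    return optimize.brentq(f, lo, hi, xtol=BOUNDARY_TOL)


def solve_efficacy_boundary(
    spec: DesignSpec,
    info_E: float,
    info_S: float,
    method: str = "integration",
    n_reps: int = 100_000,
    seed=0,
) -> float:
    """Root ``u_E`` of the limiting efficacy criterion alone."""
    alpha = spec.alpha
    if method == "integration":
        geom = _geometry.SelectionGeometry.from_spec(spec, info_E, info_S)
        scale = np.sqrt(max(info_E, info_S))

        def f_E(u):
            return _geometry.efficacy_selected_upper_tail(u, spec, geom) - alpha

        return float(_bracketed_root(f_E, -8.0 * scale, 8.0 * scale))
    if method == "monte_carlo":
        zE, _, _ = _mc_selected_scores(spec, info_E, info_S, n_reps, seed, "efficacy")
        return float(np.quantile(zE, 1.0 - alpha))
    raise ValueError(f"unknown method {method!r}")


def solve_safety_boundary(
    spec: DesignSpec,
    info_E: float,
    info_S: float,
    method: str = "integration",
    n_reps: int = 100_000,
    seed=0,
) -> float:
    """Root ``u_S`` of the limiting safety criterion alone.

    Solved in joint form ``P(N_S >= 1, Z_S,i* >= u_S; theta_S = 0) = alpha``
    (equivalent to the conditional target ``alpha / P(N_S >= 1)``).  For
    ``u_S <= c`` the joint probability is flat at ``P(N_S >= 1) >= alpha``
    — the gate subsumes the margin; that regime is outside the validated
    designs and ``c`` itself is returned.
    """
    alpha = spec.alpha
    if method == "integration":
        geom = _geometry.SelectionGeometry.from_spec(spec, info_E, info_S)
        scale = np.sqrt(max(info_E, info_S))

        def f_S(u):
            return _geometry.safety_selected_upper_tail_joint(u, spec, geom) - alpha

        c_eff = spec.c if not np.isneginf(spec.c) else -8.0 * scale
        if f_S(c_eff) <= 0.0:
            return float(c_eff)
        return float(_bracketed_root(f_S, c_eff, 8.0 * scale))
    if method == "monte_carlo":
        _, zS, any_safe = _mc_selected_scores(spec, info_E, info_S, n_reps, seed, "safety")
        zS = np.where(any_safe, zS, -np.inf)
        return float(np.quantile(zS, 1.0 - alpha))  # joint tail = alpha
    raise ValueError(f"unknown method {method!r}")


def solve_boundaries(
    spec: DesignSpec,
    info_E: float,
    info_S: float,
    method: str = "integration",
    n_reps: int = 100_000,
    seed=0,
) -> Boundaries:
    """Find ``(u_E, u_S)`` meeting both limiting FWER criteria.

    The two searches are uncoupled.  The Monte-Carlo route uses common
    random numbers: one set of simulated selected-arm statistics per
    criterion, with the boundary read off as the appropriate empirical
    quantile, so the objective is monotone in ``u``.
    """
    ss = np.random.SeedSequence(seed)
    s_eff, s_saf = ss.spawn(2)
    u_E = solve_efficacy_boundary(spec, info_E, info_S, method, n_reps, s_eff)
    u_S = solve_safety_boundary(spec, info_E, info_S, method, n_reps, s_saf)
    return Boundaries(u_E, u_S, info_E, info_S)
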