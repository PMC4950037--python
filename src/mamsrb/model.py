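"""Probability model, score statistics, treatment selection and the
single-stage test.

Patients on arm ``k`` (``k = 0`` is control) contribute bivariate normal
(efficacy, safety) responses with means ``(mu_Ek, mu_Sk)``, known standard
deviations and within-subject correlation ``rho``.  With ``n`` responses per
arm the accumulated data are summarized by the score statistics

    Z_Tk = I_T (muhat_Tk - muhat_T0),   I_T = n / (2 sigma_T^2),

whose marginal variance equals the information ``I_T`` and which share a
correlation of one half across arms through the common control.

Selection at the first analysis keeps arms with ``Z_Sk > c`` (the minimum
safety requirement) and, among those, picks the maximizer of the
risk-benefit objective ``O_k = w_E Z_Ek/sqrt(I_E) + w_S Z_Sk/sqrt(I_S)``.
The single-stage test then rejects for the selected arm when both
``Z_E,i* >= u_E`` and ``Z_S,i* >= u_S``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _geometry
from .design import DesignSpec, EffectConfiguration

__all__ = [
    "ScoreState",
    "SelectionResult",
    "TrialDecision",
    "simulate_responses",
    "score_statistics",
    "select_treatment",
    "run_single_stage_trial",
    "prob_any_safe",
    "simulate_scores",
    "select_vectorized",
]

NONE = -1  # sentinel arm index: no safe arm / no selection


@dataclass(frozen=True)
class ScoreState:
    """Per-arm bivariate score statistics and their information levels."""

    Z_E: np.ndarray
    Z_S: np.ndarray
    info_E: float
    info_S: float

    def __post_init__(self):
        object.__setattr__(self, "Z_E", np.atleast_1d(np.asarray(self.Z_E, float)))
        object.__setattr__(self, "Z_S", np.atleast_1d(np.asarray(self.Z_S, float)))
        if self.Z_E.shape != self.Z_S.shape:
            raise ValueError("Z_E and Z_S must have equal length")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the risk-benefit selection rule at the first analysis.

    ``objective_values`` holds ``O_k`` for every arm; entries for arms
    failing the safety gate are computed but flagged ineligible via
    ``eligible_set``.  ``selected == NONE`` iff no arm passes the gate.
    """

    eligible_set: np.ndarray
    n_eligible: int
    objective_values: np.ndarray
    selected: int


@dataclass(frozen=True)
class TrialDecision:
    outcome: str  # "reject" | "accept_no_safe_arm" | "accept"
    selected: int  # arm index or NONE
    stage_stopped: int = 1


# ---------------------------------------------------------------------------
# Data generation
# ---------------------------------------------------------------------------


def _bivariate_noise(rng, shape, rho):
    """Standard bivariate normal noise with correlation ``rho`` (|rho|<=1)."""
    a = rng.standard_normal(shape)
    if abs(rho) == 1.0:
        b = np.sign(rho) * a
    else:
        b = rho * a + np.sqrt(1.0 - rho**2) * rng.standard_normal(shape)
    return a, b


def simulate_responses(
    spec: DesignSpec,
    config: EffectConfiguration,
    n_per_arm: int,
    seed,
    true_rho: float | None = None,
) -> np.ndarray:
    """Patient-level responses, shape ``(K+1, n_per_arm, 2)``.

    Arm 0 is control with both means fixed at zero; arm ``k >= 1`` has means
    ``(theta_Ek, theta_Sk)``.  ``true_rho`` overrides the design correlation
    for misspecification studies.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    if config.n_arms != spec.n_arms:
        raise ValueError("configuration does not match spec.n_arms")
    rho = spec.rho if true_rho is None else true_rho
    rng = np.random.default_rng(seed)
    a, b = _bivariate_noise(rng, (spec.n_arms + 1, n_per_arm), rho)
    out = np.empty((spec.n_arms + 1, n_per_arm, 2))
    out[..., 0] = spec.sigma_E * a
    out[..., 1] = spec.sigma_S * b
    out[1:, :, 0] += config.theta_E[:, None]
    out[1:, :, 1] += config.theta_S[:, None]
    return out


def score_statistics(responses: np.ndarray, spec: DesignSpec) -> ScoreState:
    """Score statistics from patient-level responses (1:1 allocation)."""
    responses = np.asarray(responses, dtype=float)
    if responses.ndim != 3 or responses.shape[2] != 2:
        raise ValueError("responses must have shape (K+1, n, 2)")
    if responses.shape[1] == 0:
        raise ValueError("no responses on at least one arm")
    n = responses.shape[1]
    info_E, info_S = spec.information(n)
    means = responses.mean(axis=1)  # (K+1, 2)
    Z_E = info_E * (means[1:, 0] - means[0, 0])
    Z_S = info_S * (means[1:, 1] - means[0, 1])
    return ScoreState(Z_E, Z_S, info_E, info_S)


# ---------------------------------------------------------------------------
# Selection and the single-stage decision rule
# ---------------------------------------------------------------------------


def objective_values(state: ScoreState, spec: DesignSpec) -> np.ndarray:
    return spec.w_E * state.Z_E / np.sqrt(state.info_E) + spec.w_S * state.Z_S / np.sqrt(
        state.info_S
    )


def select_treatment(state: ScoreState, spec: DesignSpec) -> SelectionResult:
    """Apply the safety gate and pick the objective-maximizing arm.

    Ties in the argmax (probability zero under the continuous model) go to
    the lowest arm index for reproducibility.
    """
    O = objective_values(state, spec)
    eligible = np.flatnonzero(state.Z_S > spec.c)
    if eligible.size == 0:
        return SelectionResult(eligible, 0, O, NONE)
    best = eligible[np.argmax(O[eligible])]
    return SelectionResult(eligible, eligible.size, O, int(best))


def run_single_stage_trial(
    spec: DesignSpec,
    config: EffectConfiguration,
    boundaries,
    n_per_arm: int,
    seed,
) -> TrialDecision:
    """Simulate one trial and apply the single-stage stopping rule.

    ``boundaries`` is anything with ``u_E`` and ``u_S`` attributes, or an
    ``(u_E, u_S)`` pair.
    """
    u_E, u_S = _unpack_boundaries(boundaries)
    responses = simulate_responses(spec, config, n_per_arm, seed)
    state = score_statistics(responses, spec)
    sel = select_treatment(state, spec)
    if sel.selected == NONE:
        return TrialDecision("accept_no_safe_arm", NONE)
    if state.Z_E[sel.selected] >= u_E and state.Z_S[sel.selected] >= u_S:
        return TrialDecision("reject", sel.selected)
    return TrialDecision("accept", sel.selected)


def _unpack_boundaries(boundaries):
    if hasattr(boundaries, "u_E"):
        return boundaries.u_E, boundaries.u_S
    u_E, u_S = boundaries
    return u_E, u_S


def prob_any_safe(
    spec: DesignSpec,
    info_S: float,
    method: str = "integration",
    n_reps: int = 100_000,
    seed=0,
) -> float:
    """``P(N_S >= 1; theta_S = 0)`` — at least one arm passes the gate.

    The shared control makes the safety statistics equicorrelated at one
    half; the integration route integrates over the control noise, the
    Monte-Carlo route simulates it.
    """
    if method == "integration":
        return _geometry.prob_any_safe(spec, info_S)
    if method == "monte_carlo":
        config = EffectConfiguration.null(spec.n_arms)
        _, Z_S = simulate_scores(spec, config, info_S, info_S, n_reps, seed)
        return float((Z_S > spec.c).any(axis=1).mean())
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Vectorized score-level simulation (the Monte-Carlo oracle backbone)
# ---------------------------------------------------------------------------


def simulate_scores(
    spec: DesignSpec,
    config: EffectConfiguration,
    info_E: float,
    info_S: float,
    n_reps: int,
    seed,
    true_rho: float | None = None,
):
    """Draw ``n_reps`` replicates of the stage-1 score statistics directly.

    Exploits the exact joint normal law of the ``Z``'s (shared-control
    covariance structure) instead of summing patient-level responses, so
    fractional information levels are allowed.  Returns ``(Z_E, Z_S)`` of
    shape ``(n_reps, K)``.
    """
    rho = spec.rho if true_rho is None else true_rho
    rng = np.random.default_rng(seed)
    a, b = _bivariate_noise(rng, (n_reps, spec.n_arms + 1), rho)
    W_E = np.sqrt(info_E / 2.0) * a
    W_S = np.sqrt(info_S / 2.0) * b
    Z_E = info_E * config.theta_E + W_E[:, 1:] - W_E[:, :1]
    Z_S = info_S * config.theta_S + W_S[:, 1:] - W_S[:, :1]
    return Z_E, Z_S


def select_vectorized(Z_E, Z_S, spec: DesignSpec, info_E: float, info_S: float):
    """Gate + argmax over replicate rows.

    Returns ``(i_star, any_safe)``; ``i_star`` is meaningful only where
    ``any_safe``.  ``numpy.argmax`` takes the first maximizer, matching the
    lowest-index tie-break.
    """
    O = spec.w_E * Z_E / np.sqrt(info_E) + spec.w_S * Z_S / np.sqrt(info_S)
    eligible = Z_S > spec.c
    any_safe = eligible.any(axis=1)
    O_masked = np.where(eligible, O, -np.inf)
    return O_masked.argmax(axis=1), any_safe


def simulate_rejection_rate(
    spec: DesignSpec,
    config: EffectConfiguration,
    boundaries,
    info_E: float,
    info_S: float,
    n_reps: int,
    seed,
    true_rho: float | None = None,
    chunk: int = 200_000,
):
    """Empirical single-stage rejection probability with its binomial s.e.

    Replicates are generated in fixed-size chunks, each from an independent
    child of the master seed, so results do not depend on execution order.
    """
    u_E, u_S = _unpack_boundaries(boundaries)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_chunks = -(-n_reps // chunk)
    children = ss.spawn(n_chunks)
    hits = 0
    total = 0
    for i, child in enumerate(children):
        m = min(chunk, n_reps - i * chunk)
        Z_E, Z_S = simulate_scores(spec, config, info_E, info_S, m, child, true_rho)
        i_star, any_safe = select_vectorized(Z_E, Z_S, spec, info_E, info_S)
        rows = np.arange(m)
        rej = any_safe & (Z_E[rows, i_star] >= u_E) & (Z_S[rows, i_star] >= u_S)
        hits += int(rej.sum())
        total += m
    p = hits / total
    return p, float(np.sqrt(p * (1.0 - p) / total))
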