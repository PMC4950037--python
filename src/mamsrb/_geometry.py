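"""Gaussian geometry of the post-selection score statistics.

Write the stage-1 score statistics as ``Z_Tk = I_T theta_Tk + W_Tk - W_T0``
with ``W_Tk ~ N(0, I_T/2)`` independent across arms, correlated ``rho``
across endpoints within an arm.  Because the control terms are common to all
arms, the argmax of the selection objective ``O_k`` equals the argmax of the
iid latent scores

    V_k = w_E W_Ek / sqrt(I_E) + w_S W_Sk / sqrt(I_S)
        ~ N(0, 0.5 + w_E w_S rho),

and every limiting rejection probability reduces to low-dimensional normal
integrals conditional on ``V_k`` (and, where the safety gate is active, on
the control safety noise ``W_S0``).  This module holds those reductions; the
Monte-Carlo simulator in :mod:`mamsrb.model` is the independent oracle for
all of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

# Infinite integration ranges are truncated at this many standard deviations
# of the integrand variable; quadratures use Gauss-Legendre rules.
_RANGE_SD = 8.5
_NV = 600  # nodes for selection-score integrals
_NZ = 160  # nodes for the control safety-noise integral


@dataclass(frozen=True)
class SelectionGeometry:
    """Conditional-moment constants of the selection problem at fixed
    information levels.

    ``s`` is the standard deviation of the latent selection score ``V_k``;
    ``b_T`` the regression slope of ``W_Tk`` on ``V_k``; ``tau_E`` the
    conditional standard deviation of ``Z_Ek`` given ``V_k`` (control noise
    folded in); ``tau_S`` that of ``W_Sk`` given ``V_k`` (control noise kept
    separate because the safety gate couples arms through ``W_S0``).
    """

    info_E: float
    info_S: float
    s: float
    b_E: float
    tau_E: float
    b_S: float
    tau_S: float
    sd0_S: float  # sd of the control safety noise W_S0

    @classmethod
    def from_spec(cls, spec, info_E: float, info_S: float) -> "SelectionGeometry":
        if info_E <= 0.0 or info_S <= 0.0:
            raise ValueError("information levels must be positive")
        wE, wS, rho = spec.w_E, spec.w_S, spec.rho
        s2 = 0.5 + wE * wS * rho
        cov_E = np.sqrt(info_E) * (wE + wS * rho) / 2.0
        cov_S = np.sqrt(info_S) * (wS + wE * rho) / 2.0
        tau_E2 = max(info_E - cov_E**2 / s2, 0.0)
        tau_S2 = max(info_S / 2.0 - cov_S**2 / s2, 0.0)
        return cls(
            info_E=float(info_E),
            info_S=float(info_S),
            s=float(np.sqrt(s2)),
            b_E=float(cov_E / s2),
            tau_E=float(np.sqrt(tau_E2)),
            b_S=float(cov_S / s2),
            tau_S=float(np.sqrt(tau_S2)),
            sd0_S=float(np.sqrt(info_S / 2.0)),
        )


@lru_cache(maxsize=8)
def _leggauss(n: int):
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


def _gauss_nodes(n: int, sd: float):
    """Gauss-Legendre nodes/weights for a N(0, sd^2) expectation."""
    x, w = _leggauss(n)
    half = _RANGE_SD * sd
    nodes = x * half
    wts = w * half * stats.norm.pdf(nodes, 0.0, sd)
    return nodes, wts


def _phi_ratio(arg: np.ndarray, tau: float, lower_tail: bool) -> np.ndarray:
    """``Phi(arg/tau)`` robust to ``tau == 0`` (degenerate conditional)."""
    if tau > 0.0:
        z = arg / tau
        return stats.norm.cdf(z) if lower_tail else stats.norm.sf(z)
    ind = (arg > 0).astype(float) + 0.5 * (arg == 0)
    return ind if lower_tail else 1.0 - ind


# ---------------------------------------------------------------------------
# Efficacy-side quantities (safety gate vacuous: all arms eligible)
# ---------------------------------------------------------------------------


def _efficacy_win_probs(v: np.ndarray, geom: SelectionGeometry, spec, theta_E):
    """P(arm k selected | V_k = v) for each arm, all arms eligible.

    Equal safety effects shift every ``O_k`` identically, so arm ``k`` wins
    when ``V_k + w_E sqrt(I_E) theta_Ek`` beats every rival.
    """
    theta_E = np.asarray(theta_E, dtype=float)
    K = theta_E.size
    shift = spec.w_E * np.sqrt(geom.info_E) * theta_E  # mean of the ranking score
    # win[k, i] = prod_{j != k} Phi((v_i + shift_k - shift_j) / s)
    diffs = shift[:, None] - shift[None, :]  # (K, K)
    logs = stats.norm.logcdf((v[None, None, :] + diffs[:, :, None]) / geom.s)
    logs[np.arange(K), np.arange(K), :] = 0.0
    return np.exp(logs.sum(axis=1))  # (K, nv)


def efficacy_selected_upper_tail_by_arm(u, spec, geom: SelectionGeometry, theta_E):
    """``P(i* = k, Z_E,i* >= u)`` per arm in the all-safe limit."""
    theta_E = np.asarray(theta_E, dtype=float)
    v, wv = _gauss_nodes(_NV, geom.s)
    win = _efficacy_win_probs(v, geom, spec, theta_E)  # (K, nv)
    mean = geom.b_E * v[None, :] + geom.info_E * theta_E[:, None]
    clear = _phi_ratio(mean - u, geom.tau_E, lower_tail=True)
    return np.sum(wv[None, :] * win * clear, axis=1)


def efficacy_selected_upper_tail(u, spec, geom: SelectionGeometry, theta_E=None):
    """``P(Z_E,i* >= u)`` in the all-safe limit, arbitrary efficacy effects.

    With ``theta_E = 0`` this is the limiting efficacy FWER criterion; with
    the powering configuration it is the limiting disjunctive power.
    """
    if theta_E is None:
        theta_E = np.zeros(spec.n_arms)
    return float(efficacy_selected_upper_tail_by_arm(u, spec, geom, theta_E).sum())


def efficacy_selected_components(x, spec, geom: SelectionGeometry, theta_E):
    """Per-arm sub-densities ``d/dx P(i* = k, Z_E,i* <= x)`` on a grid.

    Returns an array of shape ``(K, len(x))``; summing over arms gives the
    stage-1 density of the selected arm's efficacy score statistic.  Used by
    the multi-stage recursion, which must track the selected arm's drift.
    """
    x = np.asarray(x, dtype=float)
    theta_E = np.asarray(theta_E, dtype=float)
    if geom.tau_E <= 0.0:
        raise ValueError("degenerate efficacy conditional; density undefined")
    v, wv = _gauss_nodes(_NV, geom.s)
    win = _efficacy_win_probs(v, geom, spec, theta_E)  # (K, nv)
    mean = geom.b_E * v[None, :] + geom.info_E * theta_E[:, None]  # (K, nv)
    out = np.empty((theta_E.size, x.size))
    for k in range(theta_E.size):
        kern = stats.norm.pdf((x[None, :] - mean[k][:, None]) / geom.tau_E) / geom.tau_E
        out[k] = (wv * win[k]) @ kern
    return out


# ---------------------------------------------------------------------------
# Safety-side quantities (gate active, theta_S = 0)
# ---------------------------------------------------------------------------


def _safety_win_weights(spec, geom: SelectionGeometry):
    """Pre-compute the (z, v) quadrature layout for gated-selection integrals.

    Conditional on the control safety noise ``W_S0 = z`` the arms are iid;
    arm 1 is selected with its ``V_1 = v`` when no rival is both eligible
    (``W_S > c + z``) and ranked higher.  ``q(v, z)`` is the rival
    elig-and-better probability, accumulated from the top of the v-grid with
    a half-node (midpoint) correction.
    """
    z, wz = _gauss_nodes(_NZ, geom.sd0_S)
    v, wv = _gauss_nodes(_NV, geom.s)
    order = np.argsort(v)[::-1]
    v, wv = v[order], wv[order]
    elig = _phi_ratio(
        (spec.c + z[:, None]) - geom.b_S * v[None, :], geom.tau_S, lower_tail=False
    )  # (nz, nv): P(W_S1 > c + z | V = v)
    terms = wv[None, :] * elig
    q = np.cumsum(terms, axis=1) - 0.5 * terms
    win = np.clip(1.0 - q, 0.0, 1.0) ** (spec.n_arms - 1)
    return z, wz, v, wv, win


def prob_any_safe(spec, info_S: float) -> float:
    """``P(N_S >= 1; theta_S = 0)`` accounting for the shared control.

    The safety statistics are equicorrelated (correlation 1/2) through the
    control arm; integrating over the control noise makes them independent.
    """
    geom = SelectionGeometry.from_spec(spec, info_S, info_S)
    if np.isneginf(spec.c):
        return 1.0
    sd = geom.sd0_S
    z, wz = _gauss_nodes(_NZ, sd)
    none_safe = stats.norm.cdf((spec.c + z) / sd) ** spec.n_arms
    return float(1.0 - np.sum(wz * none_safe))


def safety_selected_upper_tail_joint(u, spec, geom: SelectionGeometry) -> float:
    """``P(N_S >= 1, Z_S,i* >= u; theta_S = 0)`` under the gated selection.

    In the limiting safety configuration (efficacy effects huge and equal)
    the ranking score is unchanged, so the selected arm is the gated argmax
    of ``V_k``.  Divide by :func:`prob_any_safe` for the conditional version.
    """
    if not np.isneginf(spec.c) and u <= spec.c:
        # the gate subsumes the margin: the event is exactly {N_S >= 1}
        return prob_any_safe(spec, geom.info_S)
    z, wz, v, wv, win = _safety_win_weights(spec, geom)
    thr = max(spec.c, u) if not np.isneginf(spec.c) else u
    clear = _phi_ratio(
        (thr + z[:, None]) - geom.b_S * v[None, :], geom.tau_S, lower_tail=False
    )
    inner = np.sum(wv[None, :] * win * clear, axis=1)
    return float(spec.n_arms * np.sum(wz * inner))


def safety_selected_density(x, spec, geom: SelectionGeometry) -> np.ndarray:
    """Conditional density of ``Z_S,i*`` given ``N_S >= 1`` (theta_S = 0).

    Supported on ``(c, inf)`` because the selected arm passed the gate.
    """
    x = np.asarray(x, dtype=float)
    if geom.tau_S <= 0.0:
        raise ValueError("degenerate safety conditional; density undefined")
    z, wz, v, wv, win = _safety_win_weights(spec, geom)
    p_any = prob_any_safe(spec, geom.info_S)
    out = np.zeros(x.size)
    mask = x > spec.c
    xs = x[mask]
    acc = np.zeros(xs.size)
    for zi, wzi, wini in zip(z, wz, win):
        mean = geom.b_S * v - zi
        kern = stats.norm.pdf((xs[None, :] - mean[:, None]) / geom.tau_S) / geom.tau_S
        acc += wzi * ((wv * wini) @ kern)
    out[mask] = spec.n_arms * acc / p_any
    return out
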