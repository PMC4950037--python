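"""Multi-stage extension: error-spending boundary schedules, the
maximum-information search and a trial simulator.

The selected arm (chosen at the first analysis exactly as in the
single-stage design) is monitored against control at ``J`` analyses.  For
each endpoint the post-selection score-statistic sequence has independent
Gaussian increments distributed as in a univariate group-sequential test,
so upper/lower boundaries are found by an error-spending recursion: the
stage-1 exit probabilities use the post-selection marginal density, later
stages a standard convolution recursion over the continuation region.

Both schedules spend error as a function of the observed *efficacy*
information fraction ``t_j = I_Ej / I_EJ``, with safety information tied to
the same patients through ``I_Sj = sigma_E^2 I_Ej / sigma_S^2``; cumulative
spends reach their totals at ``t = 1``, which forces ``u_J = l_J`` on both
endpoints so the trial always terminates at analysis ``J``.  Futility is
binding.  The efficacy schedule targets total upper spend ``alpha`` (given
at least one safe arm, in the all-arms-safe limit); the safety schedule
targets ``alpha / P(N_S >= 1; theta_S = 0)`` under the same conditioning as
the single-stage safety criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _geometry, model
from .design import DesignSpec, EffectConfiguration
from .model import NONE, TrialDecision
from .power import _closed_form_info

__all__ = [
    "SpendingFunction",
    "BoundarySchedule",
    "parse_spending",
    "solve_stagewise_boundaries",
    "solve_max_information",
    "multistage_power",
    "run_multistage_trial",
    "simulate_multistage",
]

_NX = 221  # grid nodes per continuation region
_SPEND_TOL = 1e-6


@dataclass(frozen=True)
class SpendingFunction:
    """Cumulative error spent as a function of the information fraction.

    ``pow`` is the power family ``level * min(t, 1)**kappa``; ``obf`` an
    O'Brien-Fleming-type spend ``2 level' (1 - Phi(z / sqrt(t)))`` scaled to
    reach ``level`` at ``t = 1``.
    """

    kind: str
    level: float
    param: float = 2.0

    def __call__(self, t: float) -> float:
        t = min(max(float(t), 0.0), 1.0)
        if t == 0.0:
            return 0.0
        if self.kind == "pow":
            return self.level * t**self.param
        if self.kind == "obf":
            z = stats.norm.ppf(1.0 - self.level / 2.0)
            return 2.0 * (1.0 - stats.norm.cdf(z / np.sqrt(t)))
        raise ValueError(f"unknown spending family {self.kind!r}")


def parse_spending(ident: str, level: float) -> SpendingFunction:
    """Parse identifiers like ``"pow:2"`` or ``"obf"`` at a given level."""
    parts = ident.split(":")
    kind = parts[0]
    if kind == "pow":
        param = float(parts[1]) if len(parts) > 1 else 2.0
        if param <= 0:
            raise ValueError("power-family exponent must be positive")
        return SpendingFunction("pow", level, param)
    if kind == "obf":
        return SpendingFunction("obf", level)
    raise ValueError(f"unknown spending identifier {ident!r}")


@dataclass(frozen=True)
class BoundarySchedule:
    """Full multi-stage design: per-stage boundaries and information."""

    t: np.ndarray  # efficacy information fractions, t_J = 1
    info_E: np.ndarray
    info_S: np.ndarray
    l_E: np.ndarray
    u_E: np.ndarray
    l_S: np.ndarray
    u_S: np.ndarray
    n_star: int  # recruitment ceiling per arm
    max_info_E: float

    @property
    def n_stages(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": np.arange(1, self.n_stages + 1),
                "t": self.t,
                "info_E": self.info_E,
                "info_S": self.info_S,
                "l_E": self.l_E,
                "u_E": self.u_E,
                "l_S": self.l_S,
                "u_S": self.u_S,
            }
        )


# ---------------------------------------------------------------------------
# Stage-1 exit probabilities and densities (post-selection)
# ---------------------------------------------------------------------------


class _Stage1:
    """Endpoint-specific stage-1 tail/cdf/density under the boundary
    calibration configuration (efficacy: all safe, theta_E = 0; safety:
    theta_S = 0 with the gate, conditional on N_S >= 1)."""

    def __init__(self, spec: DesignSpec, geom, endpoint: str):
        self.spec = spec
        self.geom = geom
        self.endpoint = endpoint
        if endpoint == "safety":
            self.p_any = model.prob_any_safe(spec, geom.info_S)

    def upper_tail(self, u: float) -> float:
        if self.endpoint == "efficacy":
            return _geometry.efficacy_selected_upper_tail(u, self.spec, self.geom)
        joint = _geometry.safety_selected_upper_tail_joint(u, self.spec, self.geom)
        return joint / self.p_any

    def lower_cdf(self, x: float) -> float:
        return 1.0 - self.upper_tail(x)

    def density(self, x: np.ndarray) -> np.ndarray:
        if self.endpoint == "efficacy":
            comp = _geometry.efficacy_selected_components(
                x, self.spec, self.geom, np.zeros(self.spec.n_arms)
            )
            return comp.sum(axis=0)

        return _geometry.safety_selected_density(x, self.spec, self.geom)

    @property
    def info(self) -> float:
        return self.geom.info_E if self.endpoint == "efficacy" else self.geom.info_S

    @property
    def floor(self) -> float:
        # lower boundaries cannot undercut the gate on the safety endpoint
        return self.spec.c if self.endpoint == "safety" else -np.inf


def _grid(lo: float, hi: float):
    x, w = np.polynomial.legendre.leggauss(_NX)
    half = 0.5 * (hi - lo)
    return 0.5 * (hi + lo) + half * x, half * w


def _root(f, lo, hi):
    return optimize.brentq(f, lo, hi, xtol=1e-6)


def solve_stagewise_boundaries(
    spec: DesignSpec,
    info_seq_E,
    endpoint: str = "efficacy",
    return_diagnostics: bool = False,
):
    """Error-spending boundary schedule for one endpoint.

    ``info_seq_E`` is the (increasing) efficacy information sequence; the
    safety schedule derives its own increments from the sigma-squared ratio
    but spends against the efficacy fractions.  Returns ``(l, u)`` arrays,
    plus achieved stagewise crossing probabilities if requested.
    """
    info_E = np.asarray(info_seq_E, dtype=float)
    if info_E.ndim != 1 or info_E.size < 1 or np.any(np.diff(info_E) <= 0.0):
        raise ValueError("info_seq_E must be a strictly increasing sequence")
    if endpoint not in ("efficacy", "safety"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    J = info_E.size
    t = info_E / info_E[-1]
    info_S = spec.info_S_from_info_E(info_E)
    geom1 = _geometry.SelectionGeometry.from_spec(spec, info_E[0], info_S[0])
    stage1 = _Stage1(spec, geom1, endpoint)
    own_info = info_E if endpoint == "efficacy" else info_S

    level_U = spec.alpha if endpoint == "efficacy" else spec.alpha / stage1.p_any
    f_U = parse_spending(spec.spending_upper, level_U)
    f_L = parse_spending(spec.spending_lower, 1.0 - level_U)
    pi_U = np.diff([f_U(tj) for tj in np.concatenate(([0.0], t))])
    pi_L = np.diff([f_L(tj) for tj in np.concatenate(([0.0], t))])
    if np.any(pi_U <= 0.0) or np.any(pi_L <= 0.0):
        raise ValueError("infeasible spend: non-positive stagewise increment")

    sd1 = np.sqrt(own_info[0])
    lo_floor = max(stage1.floor, -10.0 * sd1)
    u = np.empty(J)
    l = np.empty(J)
    ach_U = np.empty(J)
    ach_L = np.empty(J)

    u[0] = _root(lambda x: stage1.upper_tail(x) - pi_U[0], lo_floor + 1e-9, 10.0 * sd1)
    ach_U[0] = pi_U[0]
    if J == 1:
        l[0] = u[0]
        ach_L[0] = stage1.lower_cdf(u[0])
        out = (l, u)
        return (*out, {"pi_U": ach_U, "pi_L": ach_L}) if return_diagnostics else out
    l[0] = _root(lambda x: stage1.lower_cdf(x) - pi_L[0], lo_floor + 1e-9, u[0])
    ach_L[0] = pi_L[0]
    if not l[0] < u[0]:
        raise ValueError("infeasible spend: boundaries cross at stage 1")

    x, w = _grid(l[0], u[0])
    gw = w * stage1.density(x)

    for j in range(1, J):
        delta = own_info[j] - own_info[j - 1]
        sd = np.sqrt(delta)

        def up(uj):
            return float(gw @ stats.norm.sf((uj - x) / sd)) - pi_U[j]

        def low(lj):
            return float(gw @ stats.norm.cdf((lj - x) / sd)) - pi_L[j]

        hi = x.max() + 10.0 * sd
        lo = x.min() - 10.0 * sd
        u[j] = _root(up, lo, hi)
        ach_U[j] = up(u[j]) + pi_U[j]
        if j == J - 1:
            l[j] = u[j]
            ach_L[j] = low(u[j]) + pi_L[j]
            # proper termination: the remaining mass below u_J is the lower spend
            if abs(ach_L[j] - pi_L[j]) > 50 * _SPEND_TOL + 1e-4:
                raise RuntimeError("spend accounting failed at the final analysis")
            break
        l[j] = _root(low, lo, hi)
        ach_L[j] = pi_L[j]
        if not l[j] < u[j]:
            raise ValueError(f"infeasible spend: boundaries cross at stage {j + 1}")
        y, wy = _grid(l[j], u[j])
        kern = stats.norm.pdf((y[:, None] - x[None, :]) / sd) / sd
        gw = wy * (kern @ gw)
        x, w = y, wy

    out = (l, u)
    return (*out, {"pi_U": ach_U, "pi_L": ach_L}) if return_diagnostics else out


# ---------------------------------------------------------------------------
# Power of a multi-stage design and the maximum-information search
# ---------------------------------------------------------------------------


def multistage_power(spec: DesignSpec, info_seq_E, l_E, u_E, theta_E=None) -> float:
    """Limiting disjunctive power of an efficacy schedule (all arms safe).

    Tracks the selected arm's drift: the stage-1 post-selection density is a
    mixture over which arm was selected, and each mixture component accrues
    its own mean increment thereafter.
    """
    info_E = np.asarray(info_seq_E, dtype=float)
    l_E = np.asarray(l_E, dtype=float)
    u_E = np.asarray(u_E, dtype=float)
    if theta_E is None:
        theta_E = EffectConfiguration.power_config(spec).theta_E
    theta_E = np.asarray(theta_E, dtype=float)
    J = info_E.size
    info_S1 = spec.info_S_from_info_E(info_E[0])
    geom1 = _geometry.SelectionGeometry.from_spec(spec, info_E[0], info_S1)

    power = float(
        _geometry.efficacy_selected_upper_tail_by_arm(u_E[0], spec, geom1, theta_E).sum()
    )
    if J == 1:
        return power

    x, w = _grid(l_E[0], u_E[0])
    comps = _geometry.efficacy_selected_components(x, spec, geom1, theta_E)  # (K, nx)
    gw = comps * w[None, :]
    for j in range(1, J):
        delta = info_E[j] - info_E[j - 1]
        sd = np.sqrt(delta)
        shift = theta_E * delta  # per selected arm
        up = stats.norm.sf((u_E[j] - x[None, :] - shift[:, None]) / sd)
        power += float((gw * up).sum())
        if j == J - 1:
            break
        y, wy = _grid(l_E[j], u_E[j])
        kern = stats.norm.pdf(
            (y[None, :, None] - x[None, None, :] - shift[:, None, None]) / sd
        ) / sd
        gw = np.einsum("kx,kyx->ky", gw, kern) * wy[None, :]
        x, w = y, wy
    return power


def solve_max_information(spec: DesignSpec, fractions=None) -> BoundarySchedule:
    """Search the final efficacy information ``I_EJ`` attaining power
    ``1 - beta``, then assemble the full boundary schedule.

    ``fractions`` are the anticipated information fractions ``t_1..t_J``
    (default equally spaced); per-arm recruitment ceiling
    ``n* = ceil(2 sigma_E^2 I_EJ)``.
    """
    J = spec.n_stages
    if fractions is None:
        fractions = np.arange(1, J + 1) / J
    t = np.asarray(fractions, dtype=float)
    if t.size != J or np.any(np.diff(t) <= 0) or not np.isclose(t[-1], 1.0):
        raise ValueError("fractions must be increasing with t_J = 1")
    target = 1.0 - spec.beta

    def attained(I_EJ):
        info_seq = t * I_EJ
        l_e, u_e = solve_stagewise_boundaries(spec, info_seq, "efficacy")
        return multistage_power(spec, info_seq, l_e, u_e) - target

    base = _closed_form_info(spec)
    lo, hi = 0.5 * base, 4.0 * base
    n_expand = 0
    while attained(lo) > 0.0 and n_expand < 30:
        lo *= 0.5
        n_expand += 1
    while attained(hi) < 0.0 and n_expand < 30:
        hi *= 2.0
        n_expand += 1
    I_EJ = optimize.brentq(attained, lo, hi, xtol=2e-3)

    info_E = t * I_EJ
    info_S = spec.info_S_from_info_E(info_E)
    l_E, u_E = solve_stagewise_boundaries(spec, info_E, "efficacy")
    l_S, u_S = solve_stagewise_boundaries(spec, info_E, "safety")
    n_star = int(np.ceil(2.0 * spec.sigma_E**2 * I_EJ - 1e-9))
    return BoundarySchedule(
        t=t,
        info_E=info_E,
        info_S=info_S,
        l_E=l_E,
        u_E=u_E,
        l_S=l_S,
        u_S=u_S,
        n_star=n_star,
        max_info_E=float(I_EJ),
    )


# ---------------------------------------------------------------------------
# Trial execution
# ---------------------------------------------------------------------------


def simulate_multistage(
    spec: DesignSpec,
    config: EffectConfiguration,
    schedule: BoundarySchedule,
    n_reps: int,
    seed,
    true_rho: float | None = None,
):
    """Vectorized execution of ``n_reps`` multi-stage trials.

    Scores are drawn exactly from their joint normal law (selection and
    gate at stage 1; independent bivariate increments with the selected
    arm's drift thereafter).  Returns a dict of per-replicate arrays:
    ``reject``, ``stage``, ``selected``.
    """
    rho = spec.rho if true_rho is None else true_rho
    ss = np.random.SeedSequence(seed)
    child = iter(ss.spawn(schedule.n_stages + 1))
    Z_E, Z_S = model.simulate_scores(
        spec, config, schedule.info_E[0], schedule.info_S[0], n_reps, next(child), rho
    )
    i_star, any_safe = model.select_vectorized(
        Z_E, Z_S, spec, schedule.info_E[0], schedule.info_S[0]
    )
    rows = np.arange(n_reps)
    reject = np.zeros(n_reps, dtype=bool)
    stage = np.ones(n_reps, dtype=int)
    selected = np.where(any_safe, i_star, NONE)

    zE = Z_E[rows, i_star]
    zS = Z_S[rows, i_star]
    drift_E = config.theta_E[i_star]
    drift_S = config.theta_S[i_star]
    alive = any_safe.copy()
    rng_stages = [np.random.default_rng(s) for s in child]

    for j in range(schedule.n_stages):
        if j > 0:
            dIE = schedule.info_E[j] - schedule.info_E[j - 1]
            dIS = schedule.info_S[j] - schedule.info_S[j - 1]
            a, b = model._bivariate_noise(rng_stages[j - 1], n_reps, rho)
            zE = zE + dIE * drift_E + np.sqrt(dIE) * a
            zS = zS + dIS * drift_S + np.sqrt(dIS) * b
        final = j == schedule.n_stages - 1
        win = alive & (zE >= schedule.u_E[j]) & (zS >= schedule.u_S[j])
        lose = (
            alive & ~win
            if final
            else alive & ~win & ((zE <= schedule.l_E[j]) | (zS <= schedule.l_S[j]))
        )
        reject[win] = True
        stage[win | lose] = j + 1
        alive &= ~(win | lose)
    return {"reject": reject, "stage": stage, "selected": selected}


def run_multistage_trial(
    spec: DesignSpec,
    config: EffectConfiguration,
    schedule: BoundarySchedule,
    seed,
) -> TrialDecision:
    """Execute a single multi-stage trial and return its decision."""
    res = simulate_multistage(spec, config, schedule, 1, seed)
    sel = int(res["selected"][0])
    if sel == NONE:
        return TrialDecision("accept_no_safe_arm", NONE, 1)
    outcome = "reject" if bool(res["reject"][0]) else "accept"
    return TrialDecision(outcome, sel, int(res["stage"][0]))
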