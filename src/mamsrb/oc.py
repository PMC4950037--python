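"""Operating-characteristics engine: seeded Monte-Carlo sweeps over effect
configurations, weights and correlations, with tabular (long CSV) output.

Every empirical probability is reported with its binomial standard error
and replicate count; re-running a sweep with the same master seed
reproduces every number bit-for-bit (replicates are generated in fixed-size
chunks, each from an independent child stream of the master seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from . import model
from .design import DesignSpec, EffectConfiguration
from .power import DesignSolution, solve_information

__all__ = [
    "OCResult",
    "sweep_weights",
    "fwer_power_grid",
    "mixed_null_fwer",
    "rho_misspecification",
    "power_vs_safety_and_n_effective",
]


@dataclass(frozen=True)
class OCResult:
    """One empirical operating characteristic."""

    label: str
    theta_E: np.ndarray
    theta_S: np.ndarray
    true_rho: float
    design_rho: float
    metric: str  # "fwer" | "power"
    estimate: float
    standard_error: float
    n_reps: int
    seed: int


def _rate(spec, config, solution: DesignSolution, n_reps, seed, true_rho=None):
    b = solution.boundaries
    return model.simulate_rejection_rate(
        spec, config, b, b.info_E, b.info_S, n_reps, seed, true_rho=true_rho
    )


def _results_frame(results: list[OCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "configuration": [r.label for r in results],
            "theta_E": [np.array2string(r.theta_E, precision=3) for r in results],
            "theta_S": [np.array2string(r.theta_S, precision=3) for r in results],
            "true_rho": [r.true_rho for r in results],
            "design_rho": [r.design_rho for r in results],
            "metric": [r.metric for r in results],
            "estimate": [r.estimate for r in results],
            "se": [r.standard_error for r in results],
            "n_reps": [r.n_reps for r in results],
            "seed": [r.seed for r in results],
        }
    )


def sweep_weights(spec: DesignSpec, w_E_grid) -> pd.DataFrame:
    """Re-solve the single-stage design along a grid of efficacy weights.

    Returns one row per weight: ``(w_E, I_star, n_unrounded, u_E, u_S)``.
    The information requirement decreases, and the efficacy boundary falls
    relative to the safety boundary, as more weight goes to efficacy.
    """
    rows = []
    for w_E in np.asarray(w_E_grid, dtype=float):
        s = spec.replace(w_E=w_E, w_S=float(np.sqrt(max(0.0, 1.0 - w_E**2))))
        sol = solve_information(s)
        b = sol.boundaries_at_I_star
        rows.append(
            {
                "w_E": w_E,
                "I_star": sol.I_star,
                "n_unrounded": sol.n_unrounded,
                "u_E": b.u_E,
                "u_S": b.u_S,
            }
        )
    return pd.DataFrame(rows)


def fwer_power_grid(
    spec: DesignSpec,
    solution: DesignSolution,
    gamma_E_grid,
    gamma_S_grid,
    n_reps: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical rejection rates over a grid of common effect pairs.

    All arms share ``(gamma_E, gamma_S)``; points with ``gamma_E <= 0`` (or
    unsafe arms) probe the FWER, points in the alternative probe power.
    """
    results = []
    ss = np.random.SeedSequence(seed)
    pairs = list(product(gamma_E_grid, gamma_S_grid))
    for (gE, gS), child in zip(pairs, ss.spawn(len(pairs))):
        config = EffectConfiguration.common(spec.n_arms, gE, gS)
        p, se = _rate(spec, config, solution, n_reps, child)
        metric = "fwer" if (gE <= 0.0 or gS <= 0.0) else "power"
        results.append(
            OCResult(
                f"gamma_E={gE:g},gamma_S={gS:g}",
                config.theta_E,
                config.theta_S,
                spec.rho,
                spec.rho,
                metric,
                p,
                se,
                n_reps,
                seed,
            )
        )
    return _results_frame(results)


def mixed_null_fwer(
    spec: DesignSpec,
    solution: DesignSolution,
    n_reps: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical FWER under every mixed worst-case pattern.

    Enumerates all ``2^K`` assignments where each arm has one endpoint's
    effect at zero and the other at the large surrogate.  Strong control
    requires every rate to stay at or below ``alpha`` (within MC error).
    """
    K = spec.n_arms
    results = []
    ss = np.random.SeedSequence(seed)
    patterns = list(product([False, True], repeat=K))
    for pattern, child in zip(patterns, ss.spawn(len(patterns))):
        config = EffectConfiguration.mixed_pattern(spec, pattern)
        p, se = _rate(spec, config, solution, n_reps, child)
        label = "".join("E" if b else "S" for b in pattern)
        results.append(
            OCResult(
                f"pattern={label}",
                config.theta_E,
                config.theta_S,
                spec.rho,
                spec.rho,
                "fwer",
                p,
                se,
                n_reps,
                seed,
            )
        )
    return _results_frame(results)


def _worst_case_configs(spec: DesignSpec):
    """Global null plus the worst-case patterns graded by how many arms
    put their large effect on efficacy (0..K): K+1 worst cases, the two
    extremes being the pure limiting configurations."""
    K = spec.n_arms
    configs = [("global_null", EffectConfiguration.null(K))]
    for m in range(K + 1):
        pattern = [k < m for k in range(K)]
        label = f"worst_case_{m}E{K - m}S"
        configs.append((label, EffectConfiguration.mixed_pattern(spec, pattern)))
    return configs


def rho_misspecification(
    spec: DesignSpec,
    solution: DesignSolution,
    true_rho_grid,
    n_reps: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """FWER when the design's correlation is wrong.

    The design (boundaries, sample size) stays fixed at ``spec.rho``; data
    are generated at each ``true_rho`` under the global null and the
    worst-case configurations.
    """
    results = []
    ss = np.random.SeedSequence(seed)
    configs = _worst_case_configs(spec)
    cells = list(product(true_rho_grid, configs))
    for (true_rho, (label, config)), child in zip(cells, ss.spawn(len(cells))):
        p, se = _rate(spec, config, solution, n_reps, child, true_rho=float(true_rho))
        results.append(
            OCResult(
                label,
                config.theta_E,
                config.theta_S,
                float(true_rho),
                spec.rho,
                "fwer",
                p,
                se,
                n_reps,
                seed,
            )
        )
    return _results_frame(results)


def power_vs_safety_and_n_effective(
    spec: DesignSpec,
    solution: DesignSolution,
    gamma_S_grid,
    n_effective_range=None,
    n_reps: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical disjunctive power against the common safety effect.

    ``n_effective`` arms carry the desirable efficacy effect ``delta``, the
    rest the minimum clinically important ``delta0``; all arms share the
    safety effect ``gamma_S``.  Power rises with both ``gamma_S`` and
    ``n_effective``.
    """
    if n_effective_range is None:
        n_effective_range = range(1, spec.n_arms + 1)
    results = []
    ss = np.random.SeedSequence(seed)
    cells = list(product(list(n_effective_range), list(gamma_S_grid)))
    for (j, gS), child in zip(cells, ss.spawn(len(cells))):
        config = EffectConfiguration.power_config(spec, n_effective=j, gamma_S=float(gS))
        p, se = _rate(spec, config, solution, n_reps, child)
        results.append(
            OCResult(
                f"n_effective={j},gamma_S={gS:g}",
                config.theta_E,
                config.theta_S,
                spec.rho,
                spec.rho,
                "power",
                p,
                se,
                n_reps,
                seed,
            )
        )
    return _results_frame(results)
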