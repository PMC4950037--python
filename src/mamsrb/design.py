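"""Design parameters and effect configurations.

A trial compares ``K`` experimental arms against a shared control on a
bivariate (efficacy, safety) endpoint measured per patient.  Responses are
bivariate normal with known standard deviations ``sigma_E``, ``sigma_S`` and
within-subject correlation ``rho``.  At the first analysis the arm with the
best weighted risk-benefit trade-off among those meeting a minimum safety
requirement is selected and carried forward against control.

:class:`DesignSpec` collects every user-chosen quantity of such a design;
:class:`EffectConfiguration` describes a true state of nature (per-arm
efficacy and safety advantages over control) under which the design is
evaluated.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = ["DesignSpec", "EffectConfiguration"]

_W_TOL = 1e-10


@dataclass(frozen=True)
class DesignSpec:
    """All user-chosen parameters of a risk-benefit MAMS design.

    Parameters
    ----------
    n_arms
        Number of experimental arms ``K`` (control is extra).
    delta
        Desirable standardized efficacy effect used for powering.
    delta0
        Minimum clinically important efficacy effect.
    alpha
        Familywise error rate to be controlled in the strong sense.
    beta
        One minus the target disjunctive power.
    w_E, w_S
        Non-negative selection weights with ``w_E**2 + w_S**2 = 1``.
    rho
        Within-subject correlation of the efficacy and safety responses.
    sigma_E, sigma_S
        Known response standard deviations.
    c
        Minimum safety threshold on the safety score-statistic scale.  Only
        arms with ``Z_S > c`` are eligible for selection; ``-inf`` disables
        the gate (co-primary efficacy use).
    n_stages
        Number of analyses ``J`` (1 = single-stage design).
    spending_upper, spending_lower
        Error-spending function identifiers, e.g. ``"pow:2"`` or ``"obf"``.
    gamma_surrogate
        Large finite effect standing in for infinity in limiting
        configurations.
    """

    n_arms: int
    delta: float
    delta0: float
    alpha: float = 0.05
    beta: float = 0.1
    w_E: float = math.sqrt(0.5)
    w_S: float = math.sqrt(0.5)
    rho: float = 0.0
    sigma_E: float = 1.0
    sigma_S: float = 1.0
    c: float = 0.0
    n_stages: int = 1
    spending_upper: str = "pow:2"
    spending_lower: str = "pow:2"
    gamma_surrogate: float = 1.0e6

    def __post_init__(self) -> None:
        if self.n_arms < 1:
            raise ValueError("n_arms must be a positive integer")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if self.w_E < 0.0 or self.w_S < 0.0:
            raise ValueError("selection weights must be non-negative")
        if abs(self.w_E**2 + self.w_S**2 - 1.0) > _W_TOL:
            raise ValueError("selection weights must satisfy w_E^2 + w_S^2 = 1")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("correlation rho must lie in [-1, 1]")
        if self.sigma_E <= 0.0 or self.sigma_S <= 0.0:
            raise ValueError("response standard deviations must be positive")
        if self.n_stages < 1:
            raise ValueError("n_stages must be a positive integer")
        if not self.gamma_surrogate > 0.0:
            raise ValueError("gamma_surrogate must be positive")

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def with_efficacy_weight(cls, w_E: float, **kwargs) -> "DesignSpec":
        """Build a spec from the efficacy weight alone (``w_S`` implied)."""
        if not 0.0 <= w_E <= 1.0:
            raise ValueError("w_E must lie in [0, 1]")
        return cls(w_E=w_E, w_S=math.sqrt(max(0.0, 1.0 - w_E**2)), **kwargs)

    def replace(self, **changes) -> "DesignSpec":
        return replace(self, **changes)

    # -- information bookkeeping --------------------------------------------------

    def information(self, n_per_arm: float) -> tuple[float, float]:
        """Fisher information per comparison, ``I_T = n / (2 sigma_T^2)``."""
        return n_per_arm / (2.0 * self.sigma_E**2), n_per_arm / (2.0 * self.sigma_S**2)

    def n_from_info(self, info_E: float) -> float:
        """Per-arm sample size implied by an efficacy information level."""
        return 2.0 * self.sigma_E**2 * info_E

    def info_S_from_info_E(self, info_E: float) -> float:
        """Safety information accrued by the patients giving ``info_E``."""
        return self.sigma_E**2 * info_E / self.sigma_S**2

    # -- config round-trip --------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_config(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_config(cls, path, **overrides) -> "DesignSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        d.update(overrides)
        return cls.from_dict(d)


@dataclass(frozen=True)
class EffectConfiguration:
    """True per-arm effects ``theta_E``, ``theta_S`` versus control.

    Control means are fixed at zero, so entries are advantages over control.
    Infinite effects are represented by a large finite surrogate, never by
    ``inf`` itself.
    """

    theta_E: np.ndarray
    theta_S: np.ndarray

    def __post_init__(self) -> None:
        tE = np.atleast_1d(np.asarray(self.theta_E, dtype=float))
        tS = np.atleast_1d(np.asarray(self.theta_S, dtype=float))
        if tE.shape != tS.shape or tE.ndim != 1:
            raise ValueError("theta_E and theta_S must be 1-d vectors of equal length")
        if not (np.isfinite(tE).all() and np.isfinite(tS).all()):
            raise ValueError("effects must be finite; use a large surrogate for infinity")
        object.__setattr__(self, "theta_E", tE)
        object.__setattr__(self, "theta_S", tS)

    @property
    def n_arms(self) -> int:
        return self.theta_E.size

    # -- canonical configurations -------------------------------------------------

    @classmethod
    def null(cls, K: int) -> "EffectConfiguration":
        """Global null: every arm ineffective and exactly as safe as control."""
        return cls(np.zeros(K), np.zeros(K))

    @classmethod
    def common(cls, K: int, gamma_E: float, gamma_S: float) -> "EffectConfiguration":
        """All arms share the same effect pair ``(gamma_E, gamma_S)``."""
        return cls(np.full(K, float(gamma_E)), np.full(K, float(gamma_S)))

    @classmethod
    def worst_case_efficacy(cls, spec: DesignSpec) -> "EffectConfiguration":
        """Efficacy at the null boundary, all arms overwhelmingly safe."""
        return cls.common(spec.n_arms, 0.0, spec.gamma_surrogate)

    @classmethod
    def worst_case_safety(cls, spec: DesignSpec) -> "EffectConfiguration":
        """Safety at the null boundary, all arms overwhelmingly effective."""
        return cls.common(spec.n_arms, spec.gamma_surrogate, 0.0)

    @classmethod
    def mixed_pattern(cls, spec: DesignSpec, pattern) -> "EffectConfiguration":
        """One endpoint per arm at zero, the other huge.

        ``pattern[k]`` truthy means arm ``k`` has a huge *efficacy* effect and
        zero safety effect; falsy means zero efficacy and huge safety.
        """
        pattern = np.asarray(pattern, dtype=bool)
        if pattern.size != spec.n_arms:
            raise ValueError("pattern length must equal n_arms")
        g = spec.gamma_surrogate
        return cls(np.where(pattern, g, 0.0), np.where(pattern, 0.0, g))

    @classmethod
    def power_config(
        cls,
        spec: DesignSpec,
        n_effective: int = 1,
        gamma_S: float | None = None,
    ) -> "EffectConfiguration":
        """Powering configuration: ``n_effective`` arms at ``delta``, the rest
        at ``delta0``; common safety effect ``gamma_S`` (surrogate infinity by
        default, i.e. all arms safe)."""
        if not 1 <= n_effective <= spec.n_arms:
            raise ValueError("n_effective must lie in 1..K")
        if gamma_S is None:
            gamma_S = spec.gamma_surrogate
        tE = np.full(spec.n_arms, spec.delta0)
        tE[spec.n_arms - n_effective :] = spec.delta
        return cls(tE, np.full(spec.n_arms, float(gamma_S)))
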