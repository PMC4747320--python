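"""Life-cycle parameters and stage-distribution containers.

The 5-stage life cycle orders stages as (m1, m2, f1, f2, u): juvenile males,
single adult males, juvenile females, single adult females, and mated unions.
The 4-stage no-union variant drops the union stage, keeping (m1, m2, f1, f2).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

STAGES_5 = ("m1", "m2", "f1", "f2", "u")
STAGES_4 = ("m1", "m2", "f1", "f2")

#: Indices into the 5-stage ordering.
M1, M2, F1, F2, UN = range(5)


class InvalidInputError(ValueError):
    """Raised when a demographic input violates its domain constraints."""


@dataclass(frozen=True)
class LifeCycleParams:
    """Demographic rates of the two-sex life cycle (all per unit time).

    Attributes
    ----------
    mu_m1, mu_f1 : juvenile male/female mortality rates.
    mu_m2, mu_f2 : adult male/female mortality rates.
    alpha_m, alpha_f : male/female maturation rates.
    d : divorce rate (rate at which a pair bond breaks).
    R : total resource investment rate of a union.
    """

    mu_m1: float
    mu_f1: float
    mu_m2: float
    mu_f2: float
    alpha_m: float
    alpha_f: float
    d: float
    R: float

    def __post_init__(self) -> None:
        for name in ("mu_m1", "mu_f1", "mu_m2", "mu_f2", "alpha_m", "alpha_f", "d", "R"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise InvalidInputError(f"{name} must be finite and >= 0, got {value!r}")

    def replace(self, **changes: float) -> "LifeCycleParams":
        return replace(self, **changes)

    def sex_swapped(self) -> "LifeCycleParams":
        """Exchange all male and female rates (used in symmetry checks)."""
        return LifeCycleParams(
            mu_m1=self.mu_f1, mu_f1=self.mu_m1,
            mu_m2=self.mu_f2, mu_f2=self.mu_m2,
            alpha_m=self.alpha_f, alpha_f=self.alpha_m,
            d=self.d, R=self.R,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "mu_m1": self.mu_m1, "mu_f1": self.mu_f1,
            "mu_m2": self.mu_m2, "mu_f2": self.mu_f2,
            "alpha_m": self.alpha_m, "alpha_f": self.alpha_f,
            "d": self.d, "R": self.R,
        }


#: Scenario presets for union quality: persistent, well-resourced unions
#: ("productive") versus transient, poorly resourced ones ("poor").
PRESETS: dict[str, LifeCycleParams] = {
    "productive": LifeCycleParams(
        mu_m1=0.1, mu_f1=0.1, mu_m2=0.1, mu_f2=0.1,
        alpha_m=0.5, alpha_f=0.5, d=0.0, R=20.0,
    ),
    "poor": LifeCycleParams(
        mu_m1=0.1, mu_f1=0.1, mu_m2=0.1, mu_f2=0.1,
        alpha_m=0.5, alpha_f=0.5, d=1.0, R=10.0,
    ),
}


def preset(name: str) -> LifeCycleParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None


@dataclass
class StageDistribution:
    """A point on the stage-frequency simplex.

    Entries are non-negative and sum to one (within 1e-12 on construction).
    Optional solver metadata (residual, integration horizon) is attached by
    the equilibrium solver.
    """

    p: np.ndarray
    stage_labels: tuple[str, ...] = STAGES_5
    residual: float | None = None
    horizon: float | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1 or self.p.size != len(self.stage_labels):
            raise InvalidInputError(
                f"expected {len(self.stage_labels)} stage frequencies, got shape {self.p.shape}"
            )
        if np.any(self.p < -1e-12):
            raise InvalidInputError(f"negative stage frequency in {self.p}")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise InvalidInputError(f"stage frequencies sum to {self.p.sum()!r}, not 1")

    def __getitem__(self, key: int | str) -> float:
        if isinstance(key, str):
            key = self.stage_labels.index(key)
        return float(self.p[key])

    @classmethod
    def uniform(cls, s: int = 5) -> "StageDistribution":
        labels = STAGES_5 if s == 5 else STAGES_4 if s == 4 else tuple(f"x{i}" for i in range(s))
        return cls(np.full(s, 1.0 / s), stage_labels=labels)


@dataclass
class PopulationState:
    """Absolute stage abundances at a given time."""

    n: np.ndarray
    time: float = 0.0
    stage_labels: tuple[str, ...] = STAGES_5

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        if np.any(self.n < 0):
            raise InvalidInputError("abundances must be >= 0")

    def frequencies(self) -> StageDistribution:
        return StageDistribution(self.n / self.n.sum(), stage_labels=self.stage_labels)


def as_frequencies(p) -> np.ndarray:
    """Accept a StageDistribution or a bare array; return the frequency vector.

    Tiny negative entries (above -1e-9, as produced by adaptive ODE steps)
    are clipped to zero; anything more negative is an input error.
    """
    if isinstance(p, StageDistribution):
        return p.p
    arr = np.asarray(p, dtype=float)
    if np.any(arr < -1e-9):
        raise InvalidInputError("stage frequencies must be >= 0")
    if np.any(arr < 0):
        arr = np.clip(arr, 0.0, None)
    return arr
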