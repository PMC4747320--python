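"""Offspring-cost models and their closed-form baselines.

Five interpretations of sex-biased offspring costs are supported:

* case 0 — identical sexes (equivalent to case 1 with Cm == Cf);
* case 1 — fixed resource cost per birth, Cm vs Cf;
* case 2 — mortality during parental investment: per-birth costs follow
  from investment rate I accrued until independence or death;
* case 3 — mortality after parental investment: unit costs, sex-biased
  mortality acts through the transition rates instead;
* case 4 — parental mortality cost: offspring raise mated-adult mortality
  in proportion to the per-offspring costs Dm, Df scaled by c.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .params import InvalidInputError, LifeCycleParams

VALID_CASES = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class CostModel:
    """Parameters of one offspring-cost interpretation.

    Only the fields relevant to ``case_id`` are consulted: (Cm, Cf) for
    cases 0-1, I for case 2, and (Dm, Df, c) for case 4. Case 3 carries no
    cost parameters; unit costs are enforced for cases 3 and 4.
    """

    case_id: int
    Cm: float = 1.0
    Cf: float = 1.0
    I: float = 1.0
    Dm: float = 0.0
    Df: float = 0.0
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.case_id not in VALID_CASES:
            raise InvalidInputError(f"case_id must be one of {VALID_CASES}")
        for name in ("Cm", "Cf", "I", "Dm", "Df", "c"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidInputError(f"{name} must be finite and >= 0, got {v!r}")
        if self.case_id == 0 and self.Cm != self.Cf:
            raise InvalidInputError("case 0 requires Cm == Cf")

    def sex_swapped(self) -> "CostModel":
        return CostModel(
            case_id=self.case_id, Cm=self.Cf, Cf=self.Cm, I=self.I,
            Dm=self.Df, Df=self.Dm, c=self.c,
        )


def average_cost(s1: float, Cm: float, Cf: float) -> float:
    """Mean resource cost per birth at primary sex ratio ``s1``."""
    if not 0.0 <= s1 <= 1.0:
        raise InvalidInputError(f"s1 must lie in [0, 1], got {s1!r}")
    return s1 * Cm + (1.0 - s1) * Cf


def equal_investment_ss(Cm: float, Cf: float) -> float:
    """Fisherian equal-investment prediction Cf / (Cm + Cf)."""
    if Cm + Cf <= 0:
        raise InvalidInputError("Cm + Cf must be positive")
    return Cf / (Cm + Cf)


def charnov_ss(Dm: float, Df: float) -> float:
    """Parental-mortality analogue of the equal-investment baseline.

    Solves s1 / (1 - s1) = Df / Dm, i.e. s1 = Df / (Dm + Df).
    """
    if Dm + Df <= 0:
        raise InvalidInputError("Dm + Df must be positive")
    return Df / (Dm + Df)


def expected_investment_cost(I: float, mu: float, alpha: float) -> float:
    """Expected cumulative parental investment per offspring born.

    A parent invests at constant rate ``I`` until the offspring dies
    (mortality rate ``mu``) or reaches independence at age 1/``alpha``:
    (I/mu) * (1 - exp(-mu/alpha)), with continuous extension I/alpha at
    mu -> 0.
    """
    if I < 0:
        raise InvalidInputError("I must be >= 0")
    if alpha <= 0:
        raise InvalidInputError("alpha must be > 0")
    if mu < 0:
        raise InvalidInputError("mu must be >= 0")
    a = 1.0 / alpha
    if mu * a < 1e-12:
        return I * a
    return (I / mu) * (1.0 - math.exp(-mu * a))


def parental_costs(Um: float, Uf: float, R: float, s1: float,
                   Dm: float, Df: float) -> tuple[float, float]:
    """Expected reproduction costs (Em, Ef) per mated male / female parent.

    Proportional to the per-capita mating rate, the resource investment
    rate, and the sex-ratio-weighted per-offspring parental mortality cost.
    """
    weight = s1 * Dm + (1.0 - s1) * Df
    return Um * R * weight, Uf * R * weight


def mated_mortality(mu_m2: float, mu_f2: float, c: float,
                    Em: float, Ef: float) -> tuple[float, float]:
    """Mortality rates of mated adults, raised linearly by reproduction costs."""
    return mu_m2 + c * Em, mu_f2 + c * Ef


def effective_costs(cost: CostModel, params: LifeCycleParams,
                    s1: float) -> tuple[float, float, float]:
    """Resolve (Cm, Cf, Ca) for a cost model at sex ratio ``s1``.

    Cases 0-1 use the configured per-birth costs; case 2 derives them from
    the juvenile mortality and maturation rates; cases 3-4 normalise all
    per-birth costs to 1.
    """
    if cost.case_id in (0, 1):
        Cm, Cf = cost.Cm, cost.Cf
    elif cost.case_id == 2:
        Cm = expected_investment_cost(cost.I, params.mu_m1, params.alpha_m)
        Cf = expected_investment_cost(cost.I, params.mu_f1, params.alpha_f)
    else:
        Cm = Cf = 1.0
    Ca = average_cost(s1, Cm, Cf)
    return Cm, Cf, Ca
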