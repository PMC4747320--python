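"""Offspring-cost case studies, reproductive-value identities, and sweeps."""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .costs import (CostModel, average_cost, charnov_ss, effective_costs,
                    equal_investment_ss, expected_investment_cost,
                    mated_mortality, parental_costs)
from .demography import eigen_triple, mating_rates
from .model import FiveStageModel, FourStageModel, FourStageSpec, ModelSpec
from .params import InvalidInputError, LifeCycleParams

log = logging.getLogger(__name__)

__all__ = [
    "CostModel", "average_cost", "equal_investment_ss", "charnov_ss",
    "expected_investment_cost", "parental_costs", "mated_mortality",
    "effective_costs", "build_case_model", "four_stage_model",
    "rv_ratio_at_ss", "equal_investment_baseline", "sweep_case",
]


def build_case_model(case_id: int, params: LifeCycleParams,
                     cost: CostModel | None = None) -> FiveStageModel:
    """The 5-stage model wired for one offspring-cost interpretation."""
    if cost is None:
        cost = CostModel(case_id=case_id)
    if cost.case_id != case_id:
        raise InvalidInputError(
            f"cost model is for case {cost.case_id}, requested case {case_id}")
    return FiveStageModel(params, cost)


def four_stage_model(spec: FourStageSpec | LifeCycleParams,
                     s1: float | None = None) -> FourStageModel:
    """The no-union contrast model (the optional ``s1`` is unused state;
    sex ratios are passed per call on the returned model)."""
    return FourStageModel(spec)


def rv_ratio_at_ss(model: ModelSpec, s1_star: float,
                   tol: float = 1e-10) -> tuple[float, float]:
    """Juvenile reproductive-value ratio v_m1/v_f1 at a singular strategy,
    and the defect of the case's closed-form identity.

    Cases 1-2: the ratio equals Cm/Cf (case 2 with investment-derived
    costs). Case 3 and the 4-stage model: v_m1 == v_f1. Case 4: v_m1
    deviates from v_f1 by c*(Df-Dm)*(Uf*v_m2 + Um*v_f2 - (Uf+Um)*v_u).
    """
    dist = model.equilibrium(s1_star, tol=tol)
    triple = eigen_triple(model.A(s1_star, dist.p))
    v = triple.v
    v_m1, v_f1 = float(v[model.idx_m1]), float(v[model.idx_f1])
    if v_f1 == 0.0:
        raise ZeroDivisionError("juvenile female reproductive value is zero")
    ratio = v_m1 / v_f1

    if isinstance(model, FourStageModel):
        residual = abs(v_m1 - v_f1) / (abs(v_m1) + abs(v_f1))
        return ratio, residual

    case = model.cost.case_id
    if case in (0, 1, 2):
        Cm, Cf, _ = effective_costs(model.cost, model.params, s1_star)
        residual = abs(ratio - Cm / Cf)
    elif case == 3:
        residual = abs(v_m1 - v_f1) / (abs(v_m1) + abs(v_f1))
    else:  # case 4
        _, Um, Uf = mating_rates(dist.p)
        c, Dm, Df = model.cost.c, model.cost.Dm, model.cost.Df
        v_m2, v_f2, v_u = float(v[1]), float(v[3]), float(v[4])
        predicted = v_f1 + c * (Df - Dm) * (Uf * v_m2 + Um * v_f2 - (Uf + Um) * v_u)
        residual = abs(v_m1 - predicted)
    return ratio, residual


def equal_investment_baseline(model: ModelSpec, s1: float = 0.5) -> float:
    """Closed-form no-structure prediction for the singular sex ratio.

    Cases 0-2 use the equal-investment ratio of the (effective) per-birth
    costs; case 4 uses its parental-mortality analogue; case 3 and the
    4-stage model have unit costs, predicting 0.5.
    """
    if isinstance(model, FourStageModel):
        return 0.5
    case = model.cost.case_id
    if case in (0, 1, 2):
        Cm, Cf, _ = effective_costs(model.cost, model.params, s1)
        return equal_investment_ss(Cm, Cf)
    if case == 4 and model.cost.Dm + model.cost.Df > 0:
        return charnov_ss(model.cost.Dm, model.cost.Df)
    return 0.5


#: Default complement constraint for each sweepable parameter, mirroring the
#: cost trade-offs used in the case studies (the female-side value is 1 minus
#: the male-side value).
COMPLEMENTS = {
    "Cm": "Cf",
    "mu_m1": "mu_f1",
    "mu_m2": "mu_f2",
    "Dm": "Df",
}

_PARAM_FIELDS = {"mu_m1", "mu_f1", "mu_m2", "mu_f2", "alpha_m", "alpha_f", "d", "R"}
_COST_FIELDS = {"Cm", "Cf", "I", "Dm", "Df", "c"}


def _apply_sweep_value(params: LifeCycleParams, cost: CostModel, name: str,
                       value: float, complement: bool) -> tuple[LifeCycleParams, CostModel]:
    updates: dict[str, float] = {name: value}
    if complement and name in COMPLEMENTS:
        updates[COMPLEMENTS[name]] = 1.0 - value
    p_updates = {k: v for k, v in updates.items() if k in _PARAM_FIELDS}
    c_updates = {k: v for k, v in updates.items() if k in _COST_FIELDS}
    unknown = set(updates) - _PARAM_FIELDS - _COST_FIELDS
    if unknown:
        raise InvalidInputError(f"unknown sweep parameter(s) {sorted(unknown)}")
    new_params = params.replace(**p_updates) if p_updates else params
    if c_updates:
        d = {f: getattr(cost, f) for f in _COST_FIELDS}
        d.update(c_updates)
        new_cost = CostModel(case_id=cost.case_id, **d)
    else:
        new_cost = cost
    return new_params, new_cost


def sweep_case(case_id: int | str, params: LifeCycleParams, swept_param: str,
               values: Sequence[float] | Iterable[float],
               cost: CostModel | None = None, complement: bool = True,
               preset_label: str = "", with_stability: bool = True,
               bracket: tuple[float, float] = (0.01, 0.99)) -> pd.DataFrame:
    """Singular-strategy summary across a grid of one cost parameter.

    By default the complementary female-side parameter is constrained to one
    minus the swept value (Cf = 1 - Cm and so on). Per-point failures are
    logged and flagged via the ``converged`` column rather than aborting.
    """
    from .dynamics import NoInteriorSS, find_singular_strategy  # local: avoids cycle

    rows = []
    for value in values:
        row = {
            "case": case_id, "preset": preset_label,
            "swept_param": swept_param, "value": float(value),
            "s1_star": np.nan, "s2_star": np.nan, "rv_ratio": np.nan,
            "es_value": np.nan, "convergence_value": np.nan,
            "baseline_equal_investment": np.nan, "converged": False,
        }
        try:
            if case_id == "four-stage":
                pr, _ = _apply_sweep_value(params, CostModel(case_id=3), swept_param,
                                           value, complement)
                model: ModelSpec = FourStageModel(FourStageSpec(pr))
            else:
                base_cost = cost if cost is not None else CostModel(case_id=int(case_id))
                pr, ct = _apply_sweep_value(params, base_cost, swept_param,
                                            value, complement)
                model = build_case_model(int(case_id), pr, ct)
            row["baseline_equal_investment"] = equal_investment_baseline(model)
            report = find_singular_strategy(model, bracket=bracket,
                                            with_stability=with_stability)
            if isinstance(report, NoInteriorSS):
                log.warning("no interior SS at %s=%s (gradient %s)",
                            swept_param, value, report.direction)
            else:
                row.update(s1_star=report.s1_star, s2_star=report.s2_star,
                           rv_ratio=report.rv_ratio, es_value=report.es_value,
                           convergence_value=report.convergence_value,
                           converged=True)
        except Exception as exc:
            log.warning("sweep point %s=%s failed: %s", swept_param, value, exc)
        rows.append(row)
    return pd.DataFrame(rows)
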