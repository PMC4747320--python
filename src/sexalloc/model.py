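"""Model specifications binding demography to a cost interpretation.

A ``ModelSpec`` exposes the projection matrix A(s1, p), its analytic first
and second derivatives with respect to the (mutant) sex ratio, and a cached
equilibrium solver. Evaluating ``A`` at the mutant sex ratio with the
resident equilibrium frequencies yields the mutant projection matrix, so a
single builder serves both roles.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import demography
from .costs import CostModel, effective_costs
from .params import (F1, F2, M1, M2, STAGES_4, STAGES_5, UN,
                     InvalidInputError, LifeCycleParams, StageDistribution,
                     as_frequencies)


@dataclass(frozen=True)
class FourStageSpec:
    """Life-cycle parameters of the no-union contrast model (divorce unused)."""

    params: LifeCycleParams

    @property
    def stage_labels(self) -> tuple[str, ...]:
        return STAGES_4


class ModelSpec:
    """Common surface of the 5-stage and 4-stage models."""

    s: int
    stage_labels: tuple[str, ...]
    #: indices of the juvenile male / female stages (reproductive values)
    idx_m1: int = M1
    idx_f1: int = F1

    def __init__(self) -> None:
        self._eq_cache: dict[tuple[float, float], StageDistribution] = {}

    # -- builders -----------------------------------------------------
    def rate_matrices(self, s1: float, p) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        raise NotImplementedError

    def A(self, s1: float, p) -> np.ndarray:
        """Projection matrix at sex ratio ``s1`` and frequencies ``p``."""
        return demography.assemble_A(*self.rate_matrices(s1, p))

    def dvecA_ds1(self, s1: float, p) -> np.ndarray:
        """Analytic d vec A(s1, p) / d s1 at fixed frequencies (length s^2)."""
        raise NotImplementedError

    def d2vecA_ds1(self, s1: float, p) -> np.ndarray:
        """Analytic second derivative of vec A w.r.t. s1 at fixed frequencies."""
        raise NotImplementedError

    # -- equilibrium --------------------------------------------------
    def equilibrium(self, s1: float, tol: float = 1e-10,
                    p0=None) -> StageDistribution:
        """Equilibrium stage distribution of the resident at sex ratio ``s1``.

        Results are cached per (s1, tol); passing an explicit start ``p0``
        bypasses the cache.
        """
        key = (float(s1), float(tol))
        if p0 is None and key in self._eq_cache:
            return self._eq_cache[key]
        start = as_frequencies(p0) if p0 is not None else None
        dist = demography.equilibrate(lambda q: self.A(s1, q), self.s, p0=start,
                                      tol=tol, stage_labels=self.stage_labels)
        if p0 is None:
            self._eq_cache[key] = dist
        return dist

    def secondary_sex_ratio(self, p_hat) -> float:
        raise NotImplementedError

    def is_viable(self, p) -> bool:
        """Whether any reproduction occurs at frequencies ``p``."""
        raise NotImplementedError


class FiveStageModel(ModelSpec):
    """The full two-sex model with a union stage, under one cost case."""

    s = 5
    stage_labels = STAGES_5

    def __init__(self, params: LifeCycleParams, cost: CostModel):
        super().__init__()
        self.params = params
        self.cost = cost

    def __repr__(self) -> str:
        return f"FiveStageModel(case={self.cost.case_id}, params={self.params})"

    def rate_matrices(self, s1, p):
        return demography.build_rate_matrices(self.params, self.cost, s1, p)

    def dvecA_ds1(self, s1, p):
        q = as_frequencies(p)
        R = self.params.R
        dv = np.zeros(25)
        Cm, Cf, Ca = effective_costs(self.cost, self.params, s1)
        if self.cost.case_id in (0, 1, 2):
            # birth entries R*s1/Ca and R*(1-s1)/Ca with Ca linear in s1
            dv[self.s * UN + M1] = R * Cf / Ca ** 2
            dv[self.s * UN + F1] = -R * Cm / Ca ** 2
        else:
            dv[self.s * UN + M1] = R
            dv[self.s * UN + F1] = -R
        if self.cost.case_id == 4:
            _, Um, Uf = demography.mating_rates(q)
            gm = self.cost.c * Um * R * (self.cost.Dm - self.cost.Df)
            gf = self.cost.c * Uf * R * (self.cost.Dm - self.cost.Df)
            dv[self.s * UN + M2] += gf        # widowed-male inflow rate mu_f2c + d
            dv[self.s * UN + F2] += gm
            dv[self.s * UN + UN] += -(gm + gf)
        return dv / 3.0

    def d2vecA_ds1(self, s1, p):
        dv = np.zeros(25)
        if self.cost.case_id in (0, 1, 2):
            Cm, Cf, Ca = effective_costs(self.cost, self.params, s1)
            dv[self.s * UN + M1] = -2.0 * self.params.R * Cf * (Cm - Cf) / Ca ** 3
            dv[self.s * UN + F1] = 2.0 * self.params.R * Cm * (Cm - Cf) / Ca ** 3
        # cases 3-4: A is linear in s1 at fixed frequencies
        return dv / 3.0

    def secondary_sex_ratio(self, p_hat) -> float:
        return demography.secondary_sex_ratio(p_hat)

    def is_viable(self, p) -> bool:
        # a collapsed sex leaves u numerically zero (~1e-11 at solver
        # tolerance) while genuine biased equilibria keep u well above 1e-8
        q = as_frequencies(p)
        return q[UN] > 1e-8

    def sex_swapped(self) -> "FiveStageModel":
        return FiveStageModel(self.params.sex_swapped(), self.cost.sex_swapped())


class FourStageModel(ModelSpec):
    """No-union contrast model: adults reproduce directly.

    The union-formation matrix is zero; the total birth rate is R times the
    harmonic-mean mating function, split between adult males and females via
    per-capita fertilities Fm = B/(2 m2) and Ff = B/(2 f2) (the half prevents
    double-counting each birth from both parents). Offspring costs are unit
    (as in case 3); sex bias enters through the mortality rates.
    """

    s = 4
    stage_labels = STAGES_4

    def __init__(self, spec: FourStageSpec | LifeCycleParams):
        super().__init__()
        self.spec = spec if isinstance(spec, FourStageSpec) else FourStageSpec(spec)
        self.params = self.spec.params

    def __repr__(self) -> str:
        return f"FourStageModel(params={self.params})"

    def _fertilities(self, q: np.ndarray) -> tuple[float, float]:
        m2, f2 = q[M2], q[F2]
        if m2 <= 0.0 or f2 <= 0.0:
            return 0.0, 0.0
        Bn = self.params.R * 2.0 * m2 * f2 / (m2 + f2)
        return Bn / (2.0 * m2), Bn / (2.0 * f2)

    def rate_matrices(self, s1, p):
        if not 0.0 <= s1 <= 1.0:
            raise InvalidInputError(f"s1 must lie in [0, 1], got {s1!r}")
        q = as_frequencies(p)
        pr = self.params
        Fm, Ff = self._fertilities(q)
        U = np.zeros((4, 4))
        B = np.zeros((4, 4))
        B[M1, M2] = s1 * Fm
        B[M1, F2] = s1 * Ff
        B[F1, M2] = (1.0 - s1) * Fm
        B[F1, F2] = (1.0 - s1) * Ff
        T = np.zeros((4, 4))
        T[M1, M1] = -(pr.mu_m1 + pr.alpha_m)
        T[M2, M1] = pr.alpha_m
        T[M2, M2] = -pr.mu_m2
        T[F1, F1] = -(pr.mu_f1 + pr.alpha_f)
        T[F2, F1] = pr.alpha_f
        T[F2, F2] = -pr.mu_f2
        return U, B, T

    def dvecA_ds1(self, s1, p):
        q = as_frequencies(p)
        Fm, Ff = self._fertilities(q)
        dv = np.zeros(16)
        dv[self.s * M2 + M1] = Fm
        dv[self.s * F2 + M1] = Ff
        dv[self.s * M2 + F1] = -Fm
        dv[self.s * F2 + F1] = -Ff
        return dv / 3.0

    def d2vecA_ds1(self, s1, p):
        return np.zeros(16)

    def secondary_sex_ratio(self, p_hat) -> float:
        q = as_frequencies(p_hat)
        denom = q[M2] + q[F2]
        if denom <= 0:
            raise InvalidInputError("no adults present; secondary sex ratio undefined")
        return float(q[M2] / denom)

    def is_viable(self, p) -> bool:
        q = as_frequencies(p)
        return q[M2] > 1e-8 and q[F2] > 1e-8

    def sex_swapped(self) -> "FourStageModel":
        return FourStageModel(FourStageSpec(self.params.sex_swapped()))
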