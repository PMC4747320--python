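"""Adaptive dynamics: invasion fitness, singular strategies, stability, PIPs."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .demography import EigenTriple, eigen_triple
from .matcalc import (DerivativeBundle, SensitivityContext, StabilityConditions,
                      d2lambda_mixed, d2lambda_mutant, eigenvalue_gradient)
from .model import ModelSpec
from .params import StageDistribution

log = logging.getLogger(__name__)

ESS_LABEL = "ESS"
NEUTRAL_LABEL = "weak-form-ESS (selectively neutral)"
BRANCHING_LABEL = "branching-point"
ATTRACTOR_LABEL = "attractor"
REPELLER_LABEL = "repeller"

#: relative neutrality band for the evolutionary-stability value
NEUTRALITY_BAND = 1e-4
#: finite-difference step for resident-direction derivatives through p_hat
RESIDENT_FD_STEP = 1e-5


@dataclass
class ResidentState:
    """Resident equilibrium bundle at a given sex ratio."""

    s1: float
    dist: StageDistribution
    A: np.ndarray
    triple: EigenTriple


@dataclass
class SingularStrategyReport:
    s1_star: float
    gradient_residual: float
    es_value: float
    convergence_value: float
    es_label: str
    convergence_label: str
    s2_star: float
    rv_ratio: float
    d2_mixed: float
    d2_resident: float
    lambda_star: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "s1_star", "gradient_residual", "es_value", "convergence_value",
            "es_label", "convergence_label", "s2_star", "rv_ratio",
            "d2_mixed", "d2_resident", "lambda_star")}


@dataclass
class NoInteriorSS:
    """Outcome when the selection gradient has no sign change on the bracket."""

    bracket: tuple[float, float]
    gradient_lo: float
    gradient_hi: float

    @property
    def direction(self) -> str:
        if self.gradient_lo > 0 and self.gradient_hi > 0:
            return "increasing"
        if self.gradient_lo < 0 and self.gradient_hi < 0:
            return "decreasing"
        return "indeterminate"


@dataclass
class PIPGrid:
    """Invasion-fitness values over a resident x mutant grid."""

    resident_values: np.ndarray
    mutant_values: np.ndarray
    fitness: np.ndarray
    zero_band: float = 1e-8
    failures: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def sign(self) -> np.ndarray:
        sgn = np.zeros_like(self.fitness)
        sgn[self.fitness > self.zero_band] = 1.0
        sgn[self.fitness < -self.zero_band] = -1.0
        return sgn


def resident_state(model: ModelSpec, s1: float, tol: float = 1e-10) -> ResidentState:
    from .demography import NonviableEquilibriumError

    dist = model.equilibrium(s1, tol=tol)
    if not model.is_viable(dist.p):
        raise NonviableEquilibriumError(
            f"equilibrium at s1={s1} has no reproduction (one sex has "
            "collapsed); selection is undefined here", dist.p,
            dist.residual or 0.0)
    A = model.A(s1, dist.p)
    return ResidentState(s1=s1, dist=dist, A=A, triple=eigen_triple(A))


def invasion_fitness(model: ModelSpec, s1_res: float, s1_mut: float,
                     tol: float = 1e-10) -> float:
    """Growth-rate advantage of a rare mutant in the resident's equilibrium.

    The mutant matrix is the model builder evaluated at the mutant sex ratio
    with frequencies frozen at the resident equilibrium (rare mutants mate
    only with residents and do not perturb the stage structure).
    """
    res = resident_state(model, s1_res, tol=tol)
    lam_mut = eigen_triple(model.A(s1_mut, res.dist.p)).growth_rate
    return float(lam_mut - res.triple.growth_rate)


def selection_gradient(model: ModelSpec, s1: float, tol: float = 1e-10) -> float:
    """Derivative of invasion fitness in the mutant direction at s1' = s1."""
    res = resident_state(model, s1, tol=tol)
    ctx = SensitivityContext(A=res.A, triple=res.triple)
    return eigenvalue_gradient(ctx, model.dvecA_ds1(s1, res.dist.p))


def _resident_direction_bundle(model: ModelSpec, s1: float,
                               h: float = RESIDENT_FD_STEP,
                               tol: float = 1e-10) -> DerivativeBundle:
    """Analytic mutant-direction derivatives plus FD resident-direction ones.

    The resident equilibrium sensitivity is obtained by central finite
    differences of the equilibrium solver; the mutant sex ratio is held
    fixed at ``s1`` while the resident (hence p_hat) moves.
    """
    if h <= 0 or s1 - h <= 0 or s1 + h >= 1:
        raise ValueError(f"FD step {h} invalid at s1={s1}")
    p_hat = model.equilibrium(s1, tol=tol).p
    C = model.dvecA_ds1(s1, p_hat)
    Hvec = model.d2vecA_ds1(s1, p_hat)
    p_plus = model.equilibrium(s1 + h, tol=tol).p
    p_minus = model.equilibrium(s1 - h, tol=tol).p
    A_plus = model.A(s1, p_plus)
    A_minus = model.A(s1, p_minus)
    dvecA_res = (A_plus - A_minus).reshape(-1, order="F") / (2.0 * h)
    dC = (model.dvecA_ds1(s1, p_plus) - model.dvecA_ds1(s1, p_minus)) / (2.0 * h)
    return DerivativeBundle(dvecA_ds1p=C, H_A_s1p=Hvec,
                            dvecA_res_ds1=dvecA_res, dC_ds1=dC)


def stability_labels(es_value: float, convergence_value: float,
                     neutrality_band: float = NEUTRALITY_BAND) -> tuple[str, str]:
    """Map second-derivative signs to stability labels.

    The evolutionary-stability value is never exactly zero in floating
    point, so values within ``neutrality_band * (1 + |convergence_value|)``
    are labelled selectively neutral.
    """
    band = neutrality_band * (1.0 + abs(convergence_value))
    if abs(es_value) < band:
        es_label = NEUTRAL_LABEL
    elif es_value < 0:
        es_label = ESS_LABEL
    else:
        es_label = BRANCHING_LABEL
    conv_label = ATTRACTOR_LABEL if convergence_value < 0 else REPELLER_LABEL
    return es_label, conv_label


def classify(model: ModelSpec, s1_star: float, grad_tol: float = 1e-6,
             h: float = RESIDENT_FD_STEP, tol: float = 1e-10,
             ) -> tuple[StabilityConditions, str, str]:
    """Evolutionary and convergence stability at a verified singular strategy."""
    g = selection_gradient(model, s1_star, tol=tol)
    if abs(g) > grad_tol:
        raise ValueError(
            f"selection gradient {g:.3e} at s1={s1_star} exceeds {grad_tol:g}; "
            "refusing to classify a non-singular point")
    res = resident_state(model, s1_star, tol=tol)
    ctx = SensitivityContext(A=res.A, triple=res.triple)
    bundle = _resident_direction_bundle(model, s1_star, h=h, tol=tol)
    d2_mut = d2lambda_mutant(ctx, bundle)
    d2_mix = d2lambda_mixed(ctx, bundle)
    conds = StabilityConditions(d2_mutant=d2_mut, d2_mixed=d2_mix)
    es_label, conv_label = stability_labels(conds.d2_mutant, conds.convergence_value)
    return conds, es_label, conv_label


def find_singular_strategy(model: ModelSpec,
                           bracket: tuple[float, float] = (0.01, 0.99),
                           tol: float = 1e-8, n_scan: int = 25,
                           eq_tol: float = 1e-10, with_stability: bool = True,
                           ) -> SingularStrategyReport | NoInteriorSS:
    """Locate the singular sex ratio by bracketing the selection gradient.

    The gradient is scanned on ``n_scan`` grid points; the first sign change
    is refined by root bracketing until |gradient| < ``tol``. A monotone
    gradient with no sign change yields a :class:`NoInteriorSS` result
    rather than a fabricated root.
    """
    from .demography import EigenvalueError, EquilibriumError

    lo, hi = bracket
    grid = np.linspace(lo, hi, n_scan)
    grads = np.full(n_scan, np.nan)
    for i, x in enumerate(grid):
        try:
            grads[i] = selection_gradient(model, x, tol=eq_tol)
        except (EigenvalueError, EquilibriumError) as exc:
            # extreme sex ratios can render the population nonviable, with a
            # degenerate (tied) dominant eigenvalue; skip those grid points
            log.debug("gradient undefined at s1=%.4f: %s", x, exc)

    valid = np.flatnonzero(np.isfinite(grads))
    if valid.size == 0:
        raise EquilibriumError("selection gradient undefined on the whole bracket",
                               np.array([]), float("nan"))

    s1_star = None
    for a, b in zip(valid, valid[1:]):
        if b != a + 1:
            continue
        if grads[a] == 0.0:
            s1_star = float(grid[a])
            break
        if grads[a] * grads[b] < 0.0:
            s1_star = float(brentq(lambda x: selection_gradient(model, x, tol=eq_tol),
                                   grid[a], grid[b], xtol=1e-13, rtol=1e-15))
            break
    else:
        if grads[valid[-1]] == 0.0:
            s1_star = float(grid[valid[-1]])
    if s1_star is None:
        return NoInteriorSS(bracket=bracket, gradient_lo=float(grads[valid[0]]),
                            gradient_hi=float(grads[valid[-1]]))

    g_res = selection_gradient(model, s1_star, tol=eq_tol)
    if abs(g_res) > tol:
        log.warning("gradient residual %.3e at s1*=%.6f exceeds tol %.1e",
                    g_res, s1_star, tol)
    res = resident_state(model, s1_star, tol=eq_tol)
    v = res.triple.v
    rv_ratio = float(v[model.idx_m1] / v[model.idx_f1])

    if with_stability:
        conds, es_label, conv_label = classify(model, s1_star, grad_tol=max(10 * tol, 1e-6),
                                               tol=eq_tol)
        es_value, conv_value = conds.d2_mutant, conds.convergence_value
        d2_mixed, d2_res = conds.d2_mixed, conds.d2_resident
    else:
        es_value = conv_value = d2_mixed = d2_res = float("nan")
        es_label = conv_label = "unclassified"

    return SingularStrategyReport(
        s1_star=s1_star, gradient_residual=float(g_res), es_value=es_value,
        convergence_value=conv_value, es_label=es_label,
        convergence_label=conv_label,
        s2_star=model.secondary_sex_ratio(res.dist.p), rv_ratio=rv_ratio,
        d2_mixed=d2_mixed, d2_resident=d2_res,
        lambda_star=res.triple.growth_rate,
    )


def pairwise_invasion_plot(model: ModelSpec, n_grid: int = 41,
                           bracket: tuple[float, float] = (0.01, 0.99),
                           eq_tol: float = 1e-10,
                           zero_band: float = 1e-8) -> PIPGrid:
    """Invasion-fitness sign map over the resident x mutant plane.

    Resident equilibria are computed once per resident grid value and
    reused across the mutant axis; per-cell failures are recorded as NaN
    rather than aborting the grid.
    """
    if n_grid < 11:
        raise ValueError("n_grid must be >= 11")
    values = np.linspace(bracket[0], bracket[1], n_grid)
    fitness = np.full((n_grid, n_grid), np.nan)
    failures: list[tuple[int, int, str]] = []
    for i, x in enumerate(values):
        try:
            res = resident_state(model, x, tol=eq_tol)
        except Exception as exc:
            failures.extend((i, j, str(exc)) for j in range(n_grid))
            continue
        lam_res = res.triple.growth_rate
        for j, y in enumerate(values):
            try:
                lam_mut = eigen_triple(model.A(y, res.dist.p)).growth_rate
                fitness[i, j] = lam_mut - lam_res
            except Exception as exc:
                failures.append((i, j, str(exc)))
    return PIPGrid(resident_values=values, mutant_values=values.copy(),
                   fitness=fitness, zero_band=zero_band, failures=failures)
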