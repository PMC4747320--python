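"""Resident demography: rate matrices, frequency dynamics, and eigenanalysis.

The projection matrix is the average of three continuous-time rate
matrices — union formation U(p), births B(s1), and transitions T —
and is homogeneous of degree zero in abundances, so all dynamics are
driven by stage *frequencies*. The population converges to an
equilibrium stage distribution p_hat at which the long-term growth rate
is the dominant eigenvalue of A(p_hat).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import eig
from scipy.optimize import root

from .costs import CostModel, effective_costs, mated_mortality, parental_costs
from .params import (F1, F2, M1, M2, UN, InvalidInputError, LifeCycleParams,
                     StageDistribution, as_frequencies)

log = logging.getLogger(__name__)

ONE_THIRD = 1.0 / 3.0


class EquilibriumError(RuntimeError):
    """Raised when frequency dynamics fail to converge; carries the last iterate."""

    def __init__(self, message: str, last_p: np.ndarray, residual: float):
        super().__init__(message)
        self.last_p = last_p
        self.residual = residual


class EigenvalueError(RuntimeError):
    """Raised when the dominant eigenvalue is complex or not simple."""


class NonviableEquilibriumError(EquilibriumError):
    """The frequency dynamics converged, but to a state without reproduction.

    At extreme sex ratios one sex can fail to persist, collapsing the
    equilibrium onto a boundary where no matings occur; selection gradients
    are structurally zero there and carry no information.
    """


def mating_rates(p) -> tuple[float, float, float]:
    """Harmonic-mean union-formation rates (M, Um, Uf) at frequencies ``p``.

    M = 2*m2*f2/(m2+f2) is the total pair-formation rate; Um = M/m2 and
    Uf = M/f2 are the per-capita rates. All three are zero when either
    single-adult class is absent (continuity convention: the harmonic mean
    vanishes in that limit, and 0/0 per-capita rates are defined as 0).
    """
    q = as_frequencies(p)
    m2, f2 = q[M2], q[F2]
    if m2 <= 0.0 or f2 <= 0.0:
        return 0.0, 0.0, 0.0
    M = 2.0 * m2 * f2 / (m2 + f2)
    return M, M / m2, M / f2


def build_rate_matrices(params: LifeCycleParams, cost: CostModel, s1: float,
                        p) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (U, B, T) for the 5-stage life cycle.

    ``p`` supplies the frequencies that set the nonlinear mating rates (and,
    for case 4, the mated-adult mortality rates). Evaluating this builder at
    the mutant sex ratio with the *resident* equilibrium frequencies yields
    the mutant rate matrices, since rare mutants mate only with residents.
    """
    if not 0.0 <= s1 <= 1.0:
        raise InvalidInputError(f"s1 must lie in [0, 1], got {s1!r}")
    q = as_frequencies(p)
    _, Um, Uf = mating_rates(q)

    s = 5
    U = np.zeros((s, s))
    U[M2, M2] = -Um
    U[F2, F2] = -Uf
    U[UN, M2] = 0.5 * Um
    U[UN, F2] = 0.5 * Uf

    _, _, Ca = effective_costs(cost, params, s1)
    if Ca == 0.0:
        raise ZeroDivisionError(
            f"average offspring cost Ca is 0 at s1={s1} (cost model case {cost.case_id}); "
            "the union reproductive rate R/Ca is undefined"
        )
    B = np.zeros((s, s))
    B[M1, UN] = params.R * s1 / Ca
    B[F1, UN] = params.R * (1.0 - s1) / Ca

    if cost.case_id == 4:
        Em, Ef = parental_costs(Um, Uf, params.R, s1, cost.Dm, cost.Df)
        mu_m2c, mu_f2c = mated_mortality(params.mu_m2, params.mu_f2, cost.c, Em, Ef)
    else:
        mu_m2c, mu_f2c = params.mu_m2, params.mu_f2

    T = np.zeros((s, s))
    T[M1, M1] = -(params.mu_m1 + params.alpha_m)
    T[M2, M1] = params.alpha_m
    T[M2, M2] = -params.mu_m2
    T[M2, UN] = mu_f2c + params.d          # widowed / divorced males return
    T[F1, F1] = -(params.mu_f1 + params.alpha_f)
    T[F2, F1] = params.alpha_f
    T[F2, F2] = -params.mu_f2
    T[F2, UN] = mu_m2c + params.d
    T[UN, UN] = -(mu_m2c + mu_f2c + params.d)
    return U, B, T


def assemble_A(U: np.ndarray, B: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Projection matrix: the average (T + B + U) / 3 of the rate matrices."""
    if not (U.shape == B.shape == T.shape) or U.shape[0] != U.shape[1]:
        raise InvalidInputError(
            f"rate matrices must share a square shape, got {U.shape}, {B.shape}, {T.shape}"
        )
    return ONE_THIRD * (T + B + U)


def projection_matrix(params: LifeCycleParams, cost: CostModel, s1: float,
                      p) -> np.ndarray:
    return assemble_A(*build_rate_matrices(params, cost, s1, p))


def frequency_dynamics(p, s1: float, params: LifeCycleParams,
                       cost: CostModel) -> np.ndarray:
    """Right-hand side of the frequency dynamics, (I - p 1^T) A(p) p."""
    q = as_frequencies(p)
    return _frequency_rhs(lambda x: projection_matrix(params, cost, s1, x), q)


def _frequency_rhs(A_fn: Callable[[np.ndarray], np.ndarray],
                   q: np.ndarray) -> np.ndarray:
    Ap = A_fn(q) @ q
    return Ap - q * Ap.sum()


def equilibrate(A_fn: Callable[[np.ndarray], np.ndarray], s: int,
                p0: np.ndarray | None = None, tol: float = 1e-10,
                window: float = 25.0, max_horizon: float = 5000.0,
                stage_labels: tuple[str, ...] | None = None) -> StageDistribution:
    """Integrate frequency dynamics to the equilibrium stage distribution.

    Integration proceeds in fixed-duration windows until the residual
    ||(I - p 1^T) A(p) p||_inf falls below a loose threshold, after which a
    Newton solve polishes the root to (near) machine precision. If the
    polish fails the integration continues until the residual meets ``tol``
    outright; exceeding ``max_horizon`` raises ``EquilibriumError`` carrying
    the last iterate.
    """
    if tol <= 0:
        raise InvalidInputError("tol must be > 0")
    p = np.full(s, 1.0 / s) if p0 is None else np.asarray(p0, dtype=float).copy()
    if p.shape != (s,) or np.any(p < 0):
        raise InvalidInputError(f"p0 must be a nonnegative vector of length {s}")
    p = p / p.sum()

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        # adaptive steps may probe microscopically negative frequencies
        return _frequency_rhs(A_fn, np.clip(y, 0.0, None))

    coarse = max(tol, 1e-7)
    t = 0.0
    residual = float(np.max(np.abs(rhs(0.0, p))))
    while residual >= coarse and t < max_horizon:
        sol = solve_ivp(rhs, (0.0, window), p, method="LSODA",
                        rtol=1e-10, atol=1e-13)
        if not sol.success:  # pragma: no cover - LSODA essentially never fails here
            raise EquilibriumError(f"ODE integration failed: {sol.message}", p, residual)
        p = np.clip(sol.y[:, -1], 0.0, None)
        p /= p.sum()
        t += window
        residual = float(np.max(np.abs(rhs(0.0, p))))

    polished = _newton_polish(A_fn, s, p)
    if polished is not None and float(np.max(np.abs(polished - p))) < 0.02:
        # accept only a local refinement: a large jump means the root solve
        # found a different (typically boundary, non-attracting) fixed point
        res_new = float(np.max(np.abs(rhs(0.0, polished))))
        if res_new <= residual:
            p, residual = polished, res_new

    while residual >= tol:
        if t >= max_horizon:
            raise EquilibriumError(
                f"frequency dynamics did not reach residual {tol:g} within "
                f"horizon {max_horizon:g} (residual {residual:.3e})", p, residual)
        sol = solve_ivp(rhs, (0.0, window), p, method="LSODA",
                        rtol=1e-12, atol=1e-14)
        p = np.clip(sol.y[:, -1], 0.0, None)
        p /= p.sum()
        t += window
        residual = float(np.max(np.abs(rhs(0.0, p))))

    labels = stage_labels or StageDistribution.uniform(s).stage_labels
    return StageDistribution(np.clip(p, 0.0, None) / p.sum(), stage_labels=labels,
                             residual=residual, horizon=t)


def _newton_polish(A_fn, s: int, p: np.ndarray) -> np.ndarray | None:
    """Polish an approximate equilibrium with a root solve on the simplex."""

    def F(q: np.ndarray) -> np.ndarray:
        g = _frequency_rhs(A_fn, np.clip(q, 0.0, None))
        out = np.empty(s)
        out[: s - 1] = g[: s - 1]
        out[s - 1] = q.sum() - 1.0
        return out

    try:
        sol = root(F, p, method="hybr", tol=1e-14)
    except Exception:  # pragma: no cover - defensive
        return None
    if not sol.success or np.any(sol.x < -1e-12):
        return None
    q = np.clip(sol.x, 0.0, None)
    return q / q.sum()


def solve_equilibrium(params: LifeCycleParams, cost: CostModel, s1: float,
                      p0=None, tol: float = 1e-10,
                      max_horizon: float = 5000.0) -> StageDistribution:
    """Equilibrium stage distribution of the 5-stage resident model."""
    start = as_frequencies(p0) if p0 is not None else None
    return equilibrate(lambda q: projection_matrix(params, cost, s1, q), 5,
                       p0=start, tol=tol, max_horizon=max_horizon)


@dataclass
class EigenTriple:
    """Dominant eigenvalue with normalised right/left eigenvectors.

    ``w`` is scaled to sum to one (the stable stage distribution) and ``v``
    (stage reproductive values) so that v @ w == 1.
    """

    growth_rate: float
    w: np.ndarray
    v: np.ndarray


def eigen_triple(A: np.ndarray, imag_tol: float = 1e-9,
                 gap_tol: float = 1e-10) -> EigenTriple:
    """Dominant eigen-triple of a real matrix with a simple real dominant root.

    The eigenvalue of maximal real part is selected (the matrix acts as a
    continuous-time generator). A complex dominant eigenvalue, or a tie in
    maximal real part, indicates a model violation and raises
    ``EigenvalueError``.
    """
    A = np.asarray(A, dtype=float)
    scale = max(1.0, float(np.max(np.abs(A))))
    lam, vl, vr = eig(A, left=True, right=True)
    order = np.argsort(lam.real)[::-1]
    i = order[0]
    if abs(lam[i].imag) > imag_tol * scale:
        raise EigenvalueError(f"dominant eigenvalue {lam[i]} is complex")
    if len(lam) > 1 and lam[order[1]].real > lam[i].real - gap_tol * scale:
        raise EigenvalueError(
            f"dominant eigenvalue {lam[i].real:.6g} is not simple "
            f"(runner-up {lam[order[1]]})"
        )
    w = vr[:, i].real
    wsum = w.sum()
    if abs(wsum) < 1e-300:
        raise EigenvalueError("right eigenvector sums to zero; cannot normalise")
    w = w / wsum
    v = vl[:, i].real
    vw = v @ w
    if abs(vw) < 1e-300:
        raise EigenvalueError("left/right eigenvectors are orthogonal; defective matrix")
    v = v / vw
    return EigenTriple(growth_rate=float(lam[i].real), w=w, v=v)


def secondary_sex_ratio(p_hat) -> float:
    """Proportion of adults that are male at the equilibrium distribution.

    Union members are counted as adults (one adult of each sex per union):
    s2 = (m2 + u) / (m2 + f2 + 2u).
    """
    q = as_frequencies(p_hat)
    if q.size != 5:
        raise InvalidInputError("secondary_sex_ratio expects a 5-stage distribution")
    denom = q[M2] + q[F2] + 2.0 * q[UN]
    if denom <= 0:
        raise InvalidInputError("no adults present; secondary sex ratio undefined")
    return float((q[M2] + q[UN]) / denom)
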