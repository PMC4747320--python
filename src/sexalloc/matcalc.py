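"""Matrix-calculus machinery for eigenvalue perturbation.

vec/Kronecker utilities and analytic first/second derivatives of a simple
dominant eigenvalue and its eigenvectors with respect to matrix entries and
to a scalar trait. These feed the evolutionary- and convergence-stability
conditions evaluated at singular strategies.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .demography import EigenTriple, eigen_triple

log = logging.getLogger(__name__)

COND_WARN_THRESHOLD = 1e10


class SingularResolventError(np.linalg.LinAlgError):
    """Raised when a bracketed resolvent matrix cannot be inverted."""


def vec(X: np.ndarray) -> np.ndarray:
    """Column-stacking vec operator."""
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError(f"vec expects a matrix, got ndim={X.ndim}")
    return X.reshape(-1, order="F")


def unvec(x: np.ndarray, m: int, n: int) -> np.ndarray:
    """Inverse of :func:`vec` for an m-by-n matrix."""
    x = np.asarray(x)
    if x.size != m * n:
        raise ValueError(f"cannot unvec length-{x.size} vector into {m}x{n}")
    return x.reshape((m, n), order="F")


def commutation_matrix(m: int, n: int) -> np.ndarray:
    """Permutation K_{m,n} with K_{m,n} vec(X) = vec(X^T) for m-by-n X."""
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    K = np.zeros((m * n, m * n))
    for i in range(m):
        for j in range(n):
            K[i * n + j, j * m + i] = 1.0
    return K


@dataclass
class SensitivityContext:
    """A (mutant) matrix together with its dominant eigen-triple.

    Built at the evaluation point A' = A'(s1', p_hat); all eigen-derivatives
    are taken around this matrix.
    """

    A: np.ndarray
    triple: EigenTriple

    @classmethod
    def from_matrix(cls, A: np.ndarray) -> "SensitivityContext":
        return cls(A=np.asarray(A, dtype=float), triple=eigen_triple(A))

    @property
    def s(self) -> int:
        return self.A.shape[0]

    def check_normalisation(self, tol: float = 1e-8) -> None:
        t = self.triple
        if abs(t.v @ t.w - 1.0) > tol:
            raise ValueError(f"v^T w = {t.v @ t.w!r}; eigenvectors not normalised")


@dataclass
class DerivativeBundle:
    """Derivatives of the mutant matrix needed for the stability conditions.

    ``dvecA_ds1p`` / ``H_A_s1p`` are the first and second derivatives of
    vec A' with respect to the mutant sex ratio (C and H[vec A'; s1']).
    ``dvecA_res_ds1`` and ``dC_ds1`` capture how the mutant matrix and C
    shift with the *resident* sex ratio through the equilibrium p_hat
    (finite-differenced by the caller).
    """

    dvecA_ds1p: np.ndarray
    H_A_s1p: np.ndarray
    dvecA_res_ds1: np.ndarray | None = None
    dC_ds1: np.ndarray | None = None

    @property
    def C(self) -> np.ndarray:
        return self.dvecA_ds1p

    def to_dict(self) -> dict:
        out = {"dvecA_ds1p": self.dvecA_ds1p.tolist(), "H_A_s1p": self.H_A_s1p.tolist()}
        if self.dvecA_res_ds1 is not None:
            out["dvecA_res_ds1"] = self.dvecA_res_ds1.tolist()
        if self.dC_ds1 is not None:
            out["dC_ds1"] = self.dC_ds1.tolist()
        return out


@dataclass
class StabilityConditions:
    """Second-derivative values classifying a singular strategy.

    ``d2_mutant`` is the pure mutant curvature of invasion fitness,
    ``d2_mixed`` the mixed resident/mutant second derivative, ``d2_resident``
    the pure resident curvature recovered from the singular-strategy
    identity, and ``convergence_value`` their attractor/repeller criterion
    (d2_mutant + d2_mixed).
    """

    d2_mutant: float
    d2_mixed: float
    d2_resident: float = field(init=False)
    convergence_value: float = field(init=False)

    def __post_init__(self) -> None:
        self.d2_resident = resident_curvature_from_identity(self.d2_mutant, self.d2_mixed)
        self.convergence_value = self.d2_mutant + self.d2_mixed

    def identity_residual(self) -> float:
        return abs(self.d2_mutant + 2.0 * self.d2_mixed + self.d2_resident)


def eigenvalue_gradient(ctx: SensitivityContext, dvecA_ds1p: np.ndarray) -> float:
    """First derivative of the dominant eigenvalue along a matrix direction.

    (w^T (x) v^T) dvecA/ds1', the classic eigenvalue sensitivity contracted
    with the trait derivative of the matrix.
    """
    ctx.check_normalisation()
    t = ctx.triple
    return float(np.kron(t.w, t.v) @ np.asarray(dvecA_ds1p, dtype=float))


def _solve_logged(M: np.ndarray, rhs: np.ndarray, label: str) -> np.ndarray:
    cond = np.linalg.cond(M)
    if not np.isfinite(cond):
        raise SingularResolventError(f"singular resolvent in {label}")
    if cond > COND_WARN_THRESHOLD:
        log.warning("ill-conditioned solve in %s: cond=%.3e", label, cond)
    try:
        return np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise SingularResolventError(f"singular resolvent in {label}: {exc}") from exc


def eigenvector_derivatives(ctx: SensitivityContext) -> tuple[np.ndarray, np.ndarray]:
    """Jacobians (dw/dvec^T A, dv/dvec^T A) of the dominant eigenvectors.

    Uses the normalisations e^T w = 1 and v^T w = 1; each Jacobian is s x s^2
    with columns ordered like vec(A).
    """
    ctx.check_normalisation()
    A, t, s = ctx.A, ctx.triple, ctx.s
    lam, w, v = t.growth_rate, t.w, t.v
    I = np.eye(s)
    e = np.ones(s)

    M = lam * I - A + np.outer(w, e) @ A
    dw = _solve_logged(M, np.kron(w[None, :], I - np.outer(w, e)), "dw/dvecA")

    N = lam * I - A.T + lam * np.outer(v, w)
    rhs = np.kron(I - np.outer(v, w), v[None, :]) - lam * np.outer(v, v) @ dw
    dv = _solve_logged(N, rhs, "dv/dvecA")
    return dw, dv


def lambda_hessian_wrt_A(ctx: SensitivityContext) -> np.ndarray:
    """Symmetrised Hessian of the dominant eigenvalue w.r.t. vec(A)."""
    dw, dv = eigenvector_derivatives(ctx)
    t, s = ctx.triple, ctx.s
    I = np.eye(s)
    H1 = np.kron(I, t.v[:, None]) @ dw + np.kron(t.w[:, None], I) @ dv
    return 0.5 * (H1 + H1.T)


def d2lambda_mutant(ctx: SensitivityContext, bundle: DerivativeBundle) -> float:
    """Pure second derivative of the mutant eigenvalue w.r.t. the mutant trait.

    (w^T (x) v^T) H[vecA'; s1'] + C^T H[lambda'; vecA'] C for a scalar trait.
    """
    t = ctx.triple
    C = np.asarray(bundle.C, dtype=float)
    Hvec = np.asarray(bundle.H_A_s1p, dtype=float)
    if C.shape != (ctx.s ** 2,) or Hvec.shape != (ctx.s ** 2,):
        raise ValueError(f"expected length-{ctx.s ** 2} derivative vectors")
    H = lambda_hessian_wrt_A(ctx)
    return float(np.kron(t.w, t.v) @ Hvec + C @ H @ C)


def d2lambda_mixed(ctx: SensitivityContext, bundle: DerivativeBundle) -> float:
    """Mixed second derivative of the mutant eigenvalue (resident x mutant).

    Differentiates the selection gradient (w'^T (x) v'^T) C along the
    resident trait: the eigenvectors move with the mutant matrix as the
    resident equilibrium shifts (chain rule through the eigenvector
    Jacobians) and C itself may shift when it depends on the equilibrium
    frequencies. The resident-direction derivatives in ``bundle`` are
    finite-differenced through the equilibrium solver by the caller.
    """
    if bundle.dvecA_res_ds1 is None or bundle.dC_ds1 is None:
        raise ValueError("bundle lacks resident-direction derivatives")
    t, s = ctx.triple, ctx.s
    C = np.asarray(bundle.C, dtype=float)
    dw_jac, dv_jac = eigenvector_derivatives(ctx)
    dw_ds1 = dw_jac @ bundle.dvecA_res_ds1
    dv_ds1 = dv_jac @ bundle.dvecA_res_ds1
    I = np.eye(s)
    term_C = float(np.kron(t.w, t.v) @ bundle.dC_ds1)
    term_vec = float(C @ (np.kron(I, t.v[:, None]) @ dw_ds1
                          + np.kron(t.w[:, None], I) @ dv_ds1))
    return term_C + term_vec


def resident_curvature_from_identity(d2_mutant: float, d2_mixed: float) -> float:
    """Pure resident curvature of invasion fitness at a singular strategy.

    At a singular strategy the three second derivatives satisfy
    d2_mutant + 2*d2_mixed + d2_resident = 0; callers must verify the
    selection gradient vanishes before relying on this.
    """
    return -(d2_mutant + 2.0 * d2_mixed)
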