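"""Independent finite-difference and eigen oracles used by the tests.

These deliberately avoid the package's analytic derivative code paths: the
dominant eigenvalue comes straight from ``numpy.linalg.eigvals`` and all
derivatives are central finite differences, so they can serve as oracles
for the matrix-calculus implementation.
"""
from __future__ import annotations

import numpy as np


def dominant_eigenvalue(A: np.ndarray) -> float:
    ev = np.linalg.eigvals(A)
    return float(ev[np.argmax(ev.real)].real)


def dominant_pair(A: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """(lambda, w, v) with w summing to 1 and v @ w = 1, via numpy only."""
    ev, V = np.linalg.eig(A)
    i = int(np.argmax(ev.real))
    w = V[:, i].real
    w = w / w.sum()
    evl, Vl = np.linalg.eig(A.T)
    j = int(np.argmax(evl.real))
    v = Vl[:, j].real
    v = v / (v @ w)
    return float(ev[i].real), w, v


def fd_gradient_mutant(model, p_hat: np.ndarray, s1_mut: float,
                       h: float = 1e-6) -> float:
    """Central FD of the mutant dominant eigenvalue over the mutant trait."""
    lp = dominant_eigenvalue(model.A(s1_mut + h, p_hat))
    lm = dominant_eigenvalue(model.A(s1_mut - h, p_hat))
    return (lp - lm) / (2.0 * h)


def fd_d2_mutant(model, p_hat: np.ndarray, s1_mut: float,
                 h: float = 1e-3) -> float:
    """Five-point central FD of the mutant eigenvalue curvature."""
    f = lambda y: dominant_eigenvalue(model.A(y, p_hat))
    return (-f(s1_mut + 2 * h) + 16 * f(s1_mut + h) - 30 * f(s1_mut)
            + 16 * f(s1_mut - h) - f(s1_mut - 2 * h)) / (12.0 * h * h)


def fd_mixed(model, s1: float, h: float = 1e-4, eq_tol: float = 1e-10) -> float:
    """Central FD over the resident trait of the mutant-direction gradient.

    The inner gradient is itself a finite difference, so this oracle shares
    no code with the analytic eigenvalue-perturbation route.
    """

    def grad(resident: float) -> float:
        p_hat = model.equilibrium(resident, tol=eq_tol).p
        return fd_gradient_mutant(model, p_hat, s1)

    return (grad(s1 + h) - grad(s1 - h)) / (2.0 * h)


def fd_d2_resident(model, s1_star: float, h: float = 2e-3,
                   eq_tol: float = 1e-10) -> float:
    """Five-point FD of the pure resident curvature of invasion fitness.

    phi(x) = lambda'(mutant fixed at s1*; p_hat(x)) - lambda(x), second
    derivative at x = s1*.
    """

    def phi(x: float) -> float:
        p_hat = model.equilibrium(x, tol=eq_tol).p
        lam_mut = dominant_eigenvalue(model.A(s1_star, p_hat))
        lam_res = dominant_eigenvalue(model.A(x, p_hat))
        return lam_mut - lam_res

    return (-phi(s1_star + 2 * h) + 16 * phi(s1_star + h) - 30 * phi(s1_star)
            + 16 * phi(s1_star - h) - phi(s1_star - 2 * h)) / (12.0 * h * h)


def fd_entry_jacobians(A: np.ndarray, h: float = 1e-6
                       ) -> tuple[np.ndarray, np.ndarray]:
    """FD Jacobians of (w, v) w.r.t. each matrix entry, vec-ordered columns."""
    s = A.shape[0]
    Jw = np.zeros((s, s * s))
    Jv = np.zeros((s, s * s))
    for j in range(s):
        for i in range(s):
            col = j * s + i
            Ap = A.copy(); Ap[i, j] += h
            Am = A.copy(); Am[i, j] -= h
            _, wp, vp = dominant_pair(Ap)
            _, wm, vm = dominant_pair(Am)
            Jw[:, col] = (wp - wm) / (2.0 * h)
            Jv[:, col] = (vp - vm) / (2.0 * h)
    return Jw, Jv


def fd_lambda_hessian(A: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """FD Hessian of the dominant eigenvalue w.r.t. matrix entries."""
    s = A.shape[0]
    n2 = s * s

    def lam(dx: dict[tuple[int, int], float]) -> float:
        B = A.copy()
        for (i, j), delta in dx.items():
            B[i, j] += delta
        return dominant_eigenvalue(B)

    H = np.zeros((n2, n2))
    entries = [(i, j) for j in range(s) for i in range(s)]
    base = lam({})
    for a, (i1, j1) in enumerate(entries):
        H[a, a] = (lam({(i1, j1): h}) - 2 * base + lam({(i1, j1): -h})) / h ** 2
        for b in range(a + 1, n2):
            i2, j2 = entries[b]
            pp = lam({(i1, j1): h, (i2, j2): h})
            pm = lam({(i1, j1): h, (i2, j2): -h})
            mp = lam({(i1, j1): -h, (i2, j2): h})
            mm = lam({(i1, j1): -h, (i2, j2): -h})
            H[a, b] = H[b, a] = (pp - pm - mp + mm) / (4.0 * h ** 2)
    return H


def random_perron_matrix(rng: np.random.Generator, s: int = 5) -> np.ndarray:
    """Random strictly positive matrix: simple real dominant eigenvalue."""
    return rng.uniform(0.1, 1.0, size=(s, s))
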