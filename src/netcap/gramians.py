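"""Observability and controllability Gramians of the network channel.

For the channel ``dx/dt = A x + B sum_k u_k delta(t - kT)``,
``y = C x`` with stable ``A``:

* the **finite-horizon observability Gramian**
  ``O(T) = int_0^T exp(A.T t) C.T C exp(A t) dt`` measures the output
  energy that a unit initial state generates within one transmission
  window, and

* the **infinite-horizon discrete controllability Gramian**
  ``W = sum_{k>=0} exp(A k T) B Sigma B.T exp(A.T k T)`` is the
  steady-state covariance of the network state sampled at transmission
  instants, when packets with input covariance ``Sigma`` arrive every
  ``T`` time units.

``W - B Sigma B.T`` is the covariance of intersymbol interference: the
residue of all previously transmitted packets that pollutes the current
window.  It equals ``E W E.T`` with ``E = exp(A T)`` exactly.

Both Gramians are obtained from Lyapunov equations.  ``O(T)`` uses the
stable-case closed form ``Q - E.T Q E`` where ``Q`` solves
``A.T Q + Q A + C.T C = 0``; an adaptive ODE integration of the matrix
flow ``X' = A.T X + X A + C.T C`` is available as a fallback for
near-marginally-stable dynamics.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, linalg

__all__ = [
    "observability_gramian",
    "controllability_gramian_discrete",
    "interference_covariance",
    "solve_stein",
    "solve_stein_factor",
    "psd_project",
]

#: eigenvalues of nominally PSD outputs above this (negative) level are
#: clipped to zero; anything below signals a genuine PSD violation.
PSD_CLIP_TOL = -1e-10


def psd_project(X: np.ndarray, clip_tol: float = PSD_CLIP_TOL) -> np.ndarray:
    """Symmetrize and clip small negative eigenvalues (floating-point
    PSD hygiene for Gramian outputs)."""
    X = 0.5 * (X + X.T)
    w, V = linalg.eigh(X)
    if w[0] >= 0.0:
        return X
    scale = max(abs(w[-1]), 1.0)
    if w[0] < clip_tol * scale:
        raise linalg.LinAlgError(
            f"matrix is not PSD: min eigenvalue {w[0]:.3e} (scale {scale:.3e})"
        )
    return (V * np.clip(w, 0.0, None)) @ V.T


def _require_stable(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    ab = float(np.max(np.real(np.linalg.eigvals(A))))
    if ab >= -1e-12:
        raise linalg.LinAlgError(
            f"A must be stable (spectral abscissa {ab:.3e} >= 0); "
            "shift the spectrum first"
        )
    return A


def _obs_gramian_doubling(A, CtC, T):
    """O(T) by interval doubling: a truncated Taylor expansion of the
    integral on a short initial interval ``h`` (``||A h|| <= 1/2``),
    then ``O(2t) = O(t) + exp(A t)' O(t) exp(A t)`` up to ``T``.

    Every accumulation is a PSD congruence, so the result stays
    accurate for strongly non-normal ``A`` whose transients span many
    orders of magnitude — regimes where the difference of
    infinite-horizon Lyapunov solutions cancels catastrophically.
    """
    nrm = np.linalg.norm(A, 2)
    k = max(0, int(np.ceil(np.log2(max(nrm * T, 1e-30) / 0.5))))
    h = T / 2**k
    # O(h) = sum_j h^{j+1}/(j+1)! M_j,  M_0 = C'C,  M_j = A'M_{j-1} + M_{j-1}A
    M = CtC.copy()
    O = CtC * h
    coef = h
    for j in range(1, 60):
        M = A.T @ M + M @ A
        coef *= h / (j + 1)
        term = coef * M
        O += term
        if np.linalg.norm(term, "fro") <= 1e-17 * np.linalg.norm(O, "fro"):
            break
    O = 0.5 * (O + O.T)
    Eh = linalg.expm(A * h)
    for _ in range(k):
        upd = Eh.T @ O @ Eh
        O = 0.5 * (O + O.T + upd + upd.T)
        Eh = Eh @ Eh
    return O


def observability_gramian(A, C=None, T: float = 1.0, method: str = "doubling") -> np.ndarray:
    """Finite-horizon observability Gramian ``O(T)``.

    Parameters
    ----------
    A : (n, n) array
        Stable state matrix.
    C : (p, n) array, optional
        Output selector; identity when omitted.
    T : float
        Window length (> 0).
    method : {"doubling", "lyapunov", "ode"}
        ``doubling`` (default): cancellation-free PSD accumulation,
        robust under strong transient amplification.  ``lyapunov``:
        closed form ``Q - exp(A T)' Q exp(A T)`` from the
        infinite-horizon continuous Lyapunov solution (exact up to the
        solver, but cancels badly for strongly non-normal ``A``).
        ``ode``: adaptive integration of the matrix flow
        ``X' = A'X + XA + C'C`` (slow; reference/fallback).
    """
    A = _require_stable(A)
    n = A.shape[0]
    if T <= 0:
        raise ValueError("T must be positive")
    C = np.eye(n) if C is None else np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[1] != n:
        raise ValueError(f"C has {C.shape[1]} columns, expected {n}")
    CtC = C.T @ C
    if method == "doubling":
        O = _obs_gramian_doubling(A, CtC, T)
    elif method == "lyapunov":
        # Q solves A.T Q + Q A = -C.T C  (infinite-horizon Gramian)
        Q = linalg.solve_continuous_lyapunov(A.T, -CtC)
        E = linalg.expm(A * T)
        O = Q - E.T @ Q @ E
    elif method == "ode":
        def flow(_t, x):
            X = x.reshape(n, n)
            return (A.T @ X + X @ A + CtC).ravel()

        sol = integrate.solve_ivp(
            flow, (0.0, T), np.zeros(n * n), rtol=1e-10, atol=1e-12, method="DOP853"
        )
        if not sol.success:  # pragma: no cover
            raise linalg.LinAlgError(f"Gramian ODE integration failed: {sol.message}")
        O = sol.y[:, -1].reshape(n, n)
    else:
        raise ValueError(f"unknown method {method!r}")
    return psd_project(O)


def solve_stein(E: np.ndarray, Q: np.ndarray, rel_tol: float = 1e-15,
                max_doublings: int = 100) -> np.ndarray:
    """Solve the discrete (Stein) equation ``X - E X E.T = Q`` for
    symmetric ``Q`` and ``rho(E) < 1`` by the squared Smith iteration
    ``X <- X + E X E.T``, ``E <- E @ E``.

    Every update is a congruence of the PSD iterate, so for PSD ``Q``
    the sum accumulates without cancellation — this stays accurate for
    strongly non-normal ``E`` whose transients grow by many orders of
    magnitude before decaying, where dense kron-based solvers lose
    positive definiteness.  Convergence is quadratic in the number of
    doublings.
    """
    X = 0.5 * (Q + Q.T)
    Ek = E.copy()
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(max_doublings):
            upd = Ek @ X @ Ek.T
            X = 0.5 * (X + X.T + upd + upd.T)
            Ek = Ek @ Ek
            nX = np.linalg.norm(X, "fro")
            if not np.isfinite(nX):
                raise linalg.LinAlgError(
                    "Smith iteration diverged: spectral radius of E is >= 1"
                )
            if np.linalg.norm(upd, "fro") <= rel_tol * nX and \
                    np.linalg.norm(Ek, "fro") ** 2 <= rel_tol:
                return X
    raise linalg.LinAlgError(
        "Smith iteration did not converge: spectral radius of E too close to 1"
    )


def solve_stein_factor(E: np.ndarray, F0: np.ndarray, rel_tol: float = 1e-15,
                       max_doublings: int = 100) -> np.ndarray:
    """Factored Smith iteration: return ``F`` with ``F F' = X`` solving
    ``X - E X E' = F0 F0'``.

    Doubling acts on the factor (``F <- [F, E^{2^j} F]`` followed by an
    LQ compression back to ``n`` columns), so singular values of the
    solution factor are accurate at the *factor* scale — crucial when
    the Gramian's condition number squares that of its factor, and
    small-but-transiently-amplified directions would otherwise be lost
    to rounding.
    """
    n = E.shape[0]
    F = np.asarray(F0, dtype=float)
    Ek = E.copy()
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(max_doublings):
            new = Ek @ F
            F = np.hstack([F, new])
            if F.shape[1] > n:
                # F = R' Q' from QR of F', so F F' = R'R is preserved
                R = linalg.qr(F.T, mode="economic")[1]
                F = R.T
            Ek = Ek @ Ek
            nF = np.linalg.norm(F, "fro")
            if not np.isfinite(nF):
                raise linalg.LinAlgError(
                    "factored Smith iteration diverged: spectral radius of E is >= 1"
                )
            if np.linalg.norm(new, "fro") <= rel_tol * nF and \
                    np.linalg.norm(Ek, "fro") ** 2 <= rel_tol:
                return F
    raise linalg.LinAlgError(
        "factored Smith iteration did not converge: spectral radius of E too close to 1"
    )


def controllability_gramian_discrete(A, B=None, Sigma=None, T: float = 1.0) -> np.ndarray:
    """Infinite-horizon controllability Gramian of the T-sampled dynamics.

    Solves the discrete (Stein) equation
    ``W - E W E.T = B Sigma B.T`` with ``E = exp(A T)``.
    """
    A = _require_stable(A)
    n = A.shape[0]
    if T <= 0:
        raise ValueError("T must be positive")
    B = np.eye(n) if B is None else np.atleast_2d(np.asarray(B, dtype=float))
    if B.shape[0] != n:
        raise ValueError(f"B has {B.shape[0]} rows, expected {n}")
    m = B.shape[1]
    Sigma = np.eye(m) if Sigma is None else np.atleast_2d(np.asarray(Sigma, dtype=float))
    E = linalg.expm(A * T)
    rho = float(np.max(np.abs(np.linalg.eigvals(E))))
    if rho >= 1.0:  # cannot happen for stable A; guards bad inputs
        raise linalg.LinAlgError(f"spectral radius of exp(A T) is {rho:.6f} >= 1")
    Q = 0.5 * ((B @ Sigma @ B.T) + (B @ Sigma @ B.T).T)
    W = solve_stein(E, Q)
    return psd_project(W)


def interference_covariance(A, B=None, Sigma=None, T: float = 1.0) -> np.ndarray:
    """Covariance of intersymbol interference, ``W - B Sigma B.T``
    (equivalently ``sum_{k>=1} exp(AkT) B Sigma B.T exp(A.T kT)``)."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    B = np.eye(n) if B is None else np.atleast_2d(np.asarray(B, dtype=float))
    m = B.shape[1]
    Sigma = np.eye(m) if Sigma is None else np.atleast_2d(np.asarray(Sigma, dtype=float))
    W = controllability_gramian_discrete(A, B, Sigma, T)
    return psd_project(W - B @ Sigma @ B.T)
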