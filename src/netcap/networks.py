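"""Network families and structural manipulations.

Two parametric families of stable state matrices are provided:

* **Chain networks** — tridiagonal matrices with node decay ``gamma`` on
  the diagonal, forward coupling ``alpha*beta`` and backward coupling
  ``beta/alpha``.  The directionality strength ``alpha`` tunes the
  departure from normality *without changing the spectrum* (the chain is
  diagonally similar to its symmetric ``alpha=1`` version), which makes
  the family a clean probe of non-normal transient amplification.

* **Random non-normal ensembles** — ``A = (-I + S) P`` with ``S`` skew
  symmetric (i.i.d. normal upper triangle, variance ``sigma_S**2``) and
  ``P`` inverse-Wishart positive definite.  Every draw is stable, and
  ``sigma_S`` controls the degree of non-normality of heterogeneous,
  disordered graphs.

Also provided: spectral-shift stabilization ``(A - gamma*I)/tau``,
symmetrization, random reversal of edge directions, and a normality
test, as used to probe whether directed biological wiring benefits
information flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

__all__ = [
    "ChainSpec",
    "RandomEnsembleSpec",
    "build_chain",
    "chain_blocks",
    "build_random_nonnormal",
    "symmetrize",
    "randomize_edge_directions",
    "stabilize_shift",
    "is_normal",
    "is_stable",
    "spectral_abscissa",
]

#: eigenvalue real-part threshold for the "stable" flag; guards the
#: Lyapunov solvers against marginally stable inputs.
STABILITY_TOL = -1e-12


def spectral_abscissa(A: np.ndarray) -> float:
    """Largest real part among the eigenvalues of ``A``."""
    return float(np.max(np.real(np.linalg.eigvals(np.asarray(A, dtype=float)))))


def is_stable(A: np.ndarray, tol: float = STABILITY_TOL) -> bool:
    """True iff every eigenvalue of ``A`` has real part below ``tol``."""
    return spectral_abscissa(A) < tol


def _check_square(A) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix has non-finite entries")
    return A


@dataclass(frozen=True)
class ChainSpec:
    """Parameters of a directed chain network.

    Parameters
    ----------
    n : int
        Chain length (number of nodes).
    alpha : float
        Directionality strength (> 0).  ``alpha = 1`` gives a symmetric,
        hence normal, graph; larger values strengthen the forward
        direction at the expense of the backward one while leaving the
        eigenvalues untouched.
    beta : float
        Overall coupling strength (> 0).
    gamma : float
        Diagonal node decay; must satisfy ``gamma < -2*beta`` so the
        chain is stable for every ``alpha``.
    """

    n: int
    alpha: float
    beta: float = 1.0
    gamma: float = -2.5

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("chain length n must be >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.gamma >= -2.0 * self.beta:
            raise ValueError(
                f"gamma={self.gamma} must be < -2*beta={-2*self.beta} for stability"
            )


def build_chain(spec: ChainSpec) -> np.ndarray:
    """Tridiagonal chain matrix: ``gamma`` on the diagonal, ``alpha*beta``
    below it (forward edges) and ``beta/alpha`` above it (backward edges)."""
    n, a, b, g = spec.n, spec.alpha, spec.beta, spec.gamma
    A = np.diag(np.full(n, g))
    if n > 1:
        A += np.diag(np.full(n - 1, a * b), k=-1)
        A += np.diag(np.full(n - 1, b / a), k=1)
    return A


def chain_blocks(specs) -> np.ndarray:
    """Block-diagonal composition of several chains.

    Chopping one long chain into sets of shorter ones reduces the
    network's non-normality while preserving diagonal decay; the
    block-diagonal matrix represents such a set as a single network.
    """
    blocks = [build_chain(s) for s in specs]
    if not blocks:
        raise ValueError("need at least one chain spec")
    return linalg.block_diag(*blocks)


@dataclass(frozen=True)
class RandomEnsembleSpec:
    """Parameters of the random stable ensemble ``A = (-I + S) P``.

    ``nu`` and the inverse scale ``omega_sq_inv`` default to
    ``nu = 24 + n`` and ``omega^-2 = nu - n - 1``, which makes the
    inverse-Wishart mean of ``P`` the identity while keeping its
    eigenvalues heterogeneous.
    """

    n: int
    sigma_S: float
    nu: int | None = None
    omega_sq_inv: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sigma_S < 0:
            raise ValueError("sigma_S must be nonnegative")
        if self.nu is None:
            object.__setattr__(self, "nu", 24 + self.n)
        if self.omega_sq_inv is None:
            object.__setattr__(self, "omega_sq_inv", float(self.nu - self.n - 1))
        if self.nu <= self.n + 1:
            raise ValueError("need nu > n + 1 for the inverse-Wishart mean to exist")
        if self.omega_sq_inv <= 0:
            raise ValueError("omega_sq_inv must be positive")


def sample_inverse_wishart(n, nu, scale_diag, rng, max_retries: int = 10) -> np.ndarray:
    """Draw from the inverse-Wishart with scale ``scale_diag * I`` and
    ``nu`` degrees of freedom, by sampling a Wishart and inverting via
    Cholesky.  Resamples (up to ``max_retries``) in the numerically
    degenerate case of a non-positive-definite draw."""
    W_scale = np.eye(n) / scale_diag
    for _ in range(max_retries):
        Wm = stats.wishart.rvs(df=nu, scale=W_scale, random_state=rng)
        Wm = np.atleast_2d(Wm)
        try:
            cf = linalg.cho_factor(Wm)
        except linalg.LinAlgError:
            continue
        P = linalg.cho_solve(cf, np.eye(n))
        return 0.5 * (P + P.T)
    raise RuntimeError("failed to draw a positive-definite Wishart sample")


def build_random_nonnormal(spec: RandomEnsembleSpec) -> np.ndarray:
    """Draw ``A = (-I + S) P`` from the random stable ensemble.

    ``S = L - L.T`` with ``L`` strictly upper triangular, entries i.i.d.
    ``N(0, sigma_S**2)``; ``P`` inverse-Wishart with scale
    ``omega_sq_inv**-1 * I`` (i.e. ``omega^2 I``) and ``nu`` d.o.f.
    The product is stable for every draw: ``x'(-I+S)Px < 0`` in the
    P-inner product since ``S`` is skew.
    """
    n = spec.n
    rng = np.random.default_rng(spec.seed)
    L = np.triu(rng.normal(0.0, spec.sigma_S or 0.0, size=(n, n)), k=1)
    S = L - L.T
    P = sample_inverse_wishart(n, spec.nu, spec.omega_sq_inv, rng)
    A = (-np.eye(n) + S) @ P
    if not is_stable(A):  # pragma: no cover - holds by construction
        raise RuntimeError("random ensemble produced an unstable matrix")
    return A


def symmetrize(A: np.ndarray) -> np.ndarray:
    """Return ``(A + A.T)/2``, the normal surrogate of a directed graph."""
    A = _check_square(A)
    return 0.5 * (A + A.T)


def randomize_edge_directions(A: np.ndarray, p: float = 0.5, seed: int = 0) -> np.ndarray:
    """Swap each entry pair ``(A[i, j], A[j, i])``, ``i < j``, independently
    with probability ``p``.

    Destroys directed structure while preserving the diagonal and the
    multiset of off-diagonal values exactly.
    """
    A = _check_square(A)
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    rng = np.random.default_rng(seed)
    out = A.copy()
    n = A.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    swap = rng.random(iu.size) < p
    si, sj = iu[swap], ju[swap]
    out[si, sj], out[sj, si] = A[sj, si], A[si, sj]
    return out


def stabilize_shift(A: np.ndarray, tau: float = 0.5, target_realpart: float = -0.1):
    """Spectral-shift stabilization: return ``((A - gamma*I)/tau, gamma)``
    with ``gamma`` chosen so the slowest mode of the result decays at
    rate ``-target_realpart``.

    Models leaky first-order node dynamics ``tau x' = (A - gamma I) x``
    where ``gamma`` plays the role of a membrane leak conductance.
    """
    A = _check_square(A)
    if tau <= 0:
        raise ValueError("tau must be positive")
    if target_realpart >= 0:
        raise ValueError("target_realpart must be negative")
    gamma = spectral_abscissa(A) - target_realpart * tau
    return (A - gamma * np.eye(A.shape[0])) / tau, float(gamma)


def is_normal(A: np.ndarray, tol: float = 1e-10) -> bool:
    """True iff ``A`` commutes with its transpose, i.e.
    ``||A A.T - A.T A||_F <= tol * ||A||_F**2``."""
    A = _check_square(A)
    nrm = np.linalg.norm(A, "fro")
    if nrm == 0.0:
        return True
    comm = A @ A.T - A.T @ A
    return bool(np.linalg.norm(comm, "fro") <= tol * nrm**2)
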