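"""Information capacity and rate of a noisy linear network channel.

A channel is the tuple ``(A, B, C, T, sigma2)``: packets ``u_k`` (zero
mean Gaussians with covariance ``Sigma``, ``tr Sigma = 1``) are
injected as impulses through ``B`` every ``T`` time units into the
stable linear dynamics ``dx/dt = A x``, read out through ``C`` and
corrupted by white Gaussian readout noise of variance ``sigma2`` per
output.  Residual activity from earlier packets acts as structured
noise (intersymbol interference).  The per-window capacity is

    C_T = 1/2 max_{Sigma >= 0, tr Sigma = 1}
          log2 det(sigma2 I + O W) / det(sigma2 I + O (W - B Sigma B')),

with ``O`` the finite-horizon observability Gramian and ``W`` the
T-sampled infinite-horizon controllability Gramian, and the rate is
``R_T = C_T / T`` (bits per unit time of ``A``'s time scale).

The determinant ratio is evaluated through the symmetric congruence
``det(sigma2 I + O X) = det(sigma2 I + O^{1/2} X O^{1/2})`` and a
rank-m reduction to an m x m determinant, which keeps the computation
stable even for strongly non-normal networks whose Gramians span many
orders of magnitude.  Because ``W`` depends linearly on ``Sigma`` through a
discrete Lyapunov operator, the exact gradient of the objective is
available via adjoint Lyapunov solves; the optimizer uses it directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, optimize as sp_optimize

from .gramians import observability_gramian, solve_stein, solve_stein_factor
from .diagnostics import participation_ratio
from .networks import is_stable, spectral_abscissa
from .optimize import OptimizerOptions, convexity_certificate, optimize_input_covariance

__all__ = [
    "NetworkChannel",
    "CapacityResult",
    "RateMaximum",
    "scalar_capacity",
    "capacity_given_input",
    "capacity",
    "rate",
    "max_rate_over_T",
    "normal_rate_bound",
    "low_noise_rate",
    "high_noise_rate",
]

LN2 = float(np.log(2.0))
#: shortest transmission window evaluated numerically; the objective is
#: ill-conditioned as T -> 0 (use the analytic small-T limits instead).
T_MIN = 1e-3


def _sym(X):
    return 0.5 * (X + X.T)


@dataclass(frozen=True)
class NetworkChannel:
    """Stable linear network channel ``(A, B, C, T, sigma2)``.

    ``B`` (n x m input selector) and ``C`` (p x n output selector)
    default to the identity ("full communication": every node both
    receives and is read out).
    """

    A: np.ndarray
    T: float
    sigma2: float = 1.0
    B: np.ndarray | None = None
    C: np.ndarray | None = None

    def __post_init__(self):
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if A.shape[0] != A.shape[1]:
            raise ValueError("A must be square")
        if not is_stable(A):
            raise ValueError(
                f"A must be stable (spectral abscissa {spectral_abscissa(A):.3e})"
            )
        object.__setattr__(self, "A", A)
        n = A.shape[0]
        B = np.eye(n) if self.B is None else np.atleast_2d(np.asarray(self.B, dtype=float))
        C = np.eye(n) if self.C is None else np.atleast_2d(np.asarray(self.C, dtype=float))
        if B.shape[0] != n:
            raise ValueError(f"B must have {n} rows")
        if C.shape[1] != n:
            raise ValueError(f"C must have {n} columns")
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "C", C)
        if not self.T >= T_MIN:
            raise ValueError(f"T must be >= {T_MIN} (analytic limits cover T -> 0)")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive (noiseless regime: low_noise_rate)")
        if np.linalg.matrix_rank(B) < B.shape[1]:
            warnings.warn("B is column-rank deficient; some input directions are redundant")
        if np.linalg.matrix_rank(C) < C.shape[0]:
            warnings.warn("C is row-rank deficient; some outputs are redundant")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def m(self) -> int:
        return self.B.shape[1]

    @property
    def p(self) -> int:
        return self.C.shape[0]

    @property
    def full_io(self) -> bool:
        n = self.n
        return (
            self.B.shape == (n, n) and self.C.shape == (n, n)
            and np.allclose(self.B, np.eye(n)) and np.allclose(self.C, np.eye(n))
        )


@dataclass
class CapacityResult:
    """Optimized capacity with the achieving input covariance."""

    capacity_bits: float
    rate_bits_per_time: float
    sigma_opt: np.ndarray
    n_restarts_used: int
    converged: bool
    convex_certificate: bool
    input_dimensionality: float  # participation ratio of sigma_opt

    def __post_init__(self):
        if self.capacity_bits < 0 and self.capacity_bits > -1e-9:
            self.capacity_bits = 0.0
            self.rate_bits_per_time = 0.0


@dataclass
class RateMaximum:
    """Result of maximizing the rate over the transmission window."""

    R_max: float
    T_opt: float
    boundary: bool  # True when the best grid point is the smallest T
    T_grid: np.ndarray
    rates: np.ndarray
    result: CapacityResult  # capacity result at T_opt


def scalar_capacity(a: float, sigma2: float, T: float, power: float = 1.0) -> float:
    """Closed-form capacity of a single node with decay rate ``a``:
    ``1/2 log2[(2 a sigma2 + p) / (2 a sigma2 + p e^{-2 a T})]``."""
    if a <= 0 or sigma2 <= 0 or T <= 0 or power <= 0:
        raise ValueError("a, sigma2, T, power must all be positive")
    x = 2.0 * a * sigma2
    return 0.5 * np.log2((x + power) / (x + power * np.exp(-2.0 * a * T)))


class _CapacityObjective:
    """Eq.-style log-det objective with its exact adjoint gradient.

    Precomputes ``E = exp(A T)`` and ``O^{1/2}`` once per channel; each
    evaluation costs one discrete Lyapunov solve (plus two adjoint
    solves for the gradient).
    """

    def __init__(self, ch: NetworkChannel):
        self.ch = ch
        self.E = linalg.expm(ch.A * ch.T)
        O = observability_gramian(ch.A, ch.C, ch.T)
        w, V = linalg.eigh(O)
        self.Oh = (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T
        self._cache_key = None
        self._cache = None

    def _pieces(self, Sigma):
        """Low-rank spectral form of the capacity objective.

        The two determinant arguments differ by the rank-m update
        ``M1 = M2 + K K'`` with ``K = Oh B Sigma^{1/2}``, so the
        objective equals ``1/2 log2 det(I_m + K' M2^{-1} K)`` — an
        m x m determinant of moderate scale.  ``M2^{-1}`` is applied
        through the SVD of ``G2 = Oh E L_W`` (``W = L_W L_W'``,
        interference ``= E W E'``), i.e. ``M2 = sigma2 I + G2 G2'``.
        No difference of large log-determinants is ever formed, which
        keeps the evaluation accurate under transient amplification
        spanning many orders of magnitude.
        """
        Sigma = np.atleast_2d(Sigma)
        key = Sigma.tobytes()
        if key == self._cache_key:
            return self._cache
        ch = self.ch
        lamS, VS = linalg.eigh(_sym(Sigma))
        F0 = ch.B @ (VS * np.sqrt(np.clip(lamS, 0.0, None)))  # B Sigma^1/2
        Lw = solve_stein_factor(self.E, F0)  # W = Lw Lw'
        U2, s2v, _ = linalg.svd(self.Oh @ (self.E @ Lw))
        K = self.Oh @ F0
        d2 = ch.sigma2 + s2v**2
        UtK = U2.T @ K
        M2inv_K = U2 @ (UtK / d2[:, None])
        # Mm = I + K' M2^-1 K formed as an exact Gram product (PSD)
        Lm = UtK / np.sqrt(d2)[:, None]
        _, sL, VLt = linalg.svd(Lm, full_matrices=False)
        self._cache_key = key
        self._cache = (U2, s2v, d2, K, M2inv_K, sL, VLt)
        return self._cache

    def value(self, Sigma) -> float:
        *_, sL, _ = self._pieces(Sigma)
        val = float(np.sum(np.log1p(sL**2))) / (2.0 * LN2)
        if not np.isfinite(val):
            raise FloatingPointError("non-finite capacity objective (conditioning)")
        return val

    def gradient(self, Sigma) -> np.ndarray:
        """d value / d Sigma (symmetric m x m), in bits, via adjoint
        Stein solves (the objective is affine in Sigma through the
        Lyapunov operator)."""
        ch = self.ch
        U2, s2v, d2, K, M2inv_K, sL, VLt = self._pieces(Sigma)
        OU2 = self.Oh @ U2
        G2 = _sym((OU2 / d2) @ OU2.T)  # Oh M2^-1 Oh
        # Woodbury: M1^-1 = M2^-1 - M2^-1 K (I + K'M2^-1 K)^-1 K'M2^-1,
        # with the inner inverse applied spectrally (Gram subtraction)
        P = (self.Oh @ M2inv_K) @ (VLt.T / np.sqrt(1.0 + sL**2))
        G1 = _sym(G2 - P @ P.T)
        # adjoint of the Lyapunov operator L(Q) = sum_k E^k Q E'^k
        Z1 = solve_stein(self.E.T, G1)
        Z2 = solve_stein(self.E.T, _sym(self.E.T @ G2 @ self.E))
        G = ch.B.T @ (Z1 - Z2) @ ch.B
        return _sym(G) / (2.0 * LN2)


def capacity_given_input(ch: NetworkChannel, Sigma) -> float:
    """Evaluate the capacity objective (in bits) for a fixed input
    covariance ``Sigma`` (PSD ``m x m``; the trace-one constraint is the
    caller's concern here)."""
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    if Sigma.shape != (ch.m, ch.m):
        raise ValueError(f"Sigma must be {ch.m} x {ch.m}")
    lam_min = float(linalg.eigvalsh(_sym(Sigma))[0])
    if lam_min < -1e-10 * max(1.0, abs(float(np.trace(Sigma)))):
        raise ValueError(f"Sigma is not PSD (min eigenvalue {lam_min:.3e})")
    return _CapacityObjective(ch).value(Sigma)


def _is_symmetric(A, rtol=1e-10):
    nrm = np.linalg.norm(A, "fro")
    return nrm == 0.0 or np.linalg.norm(A - A.T, "fro") <= rtol * nrm


def _symmetric_full_io_capacity(ch: NetworkChannel):
    """Exact route for symmetric (hence normal) A with B = C = I.

    The channel splits into independent scalar channels along the
    eigenmodes; the capacity is a concave power allocation over the
    probability simplex, solved with SLSQP.
    """
    lam = linalg.eigvalsh(ch.A)
    a = -lam  # positive decay rates
    V = linalg.eigh(ch.A)[1]
    x = 2.0 * a * ch.sigma2
    e = np.exp(-2.0 * a * ch.T)

    def raw(p):
        p = np.clip(p, 0.0, None)
        return 0.5 * float(np.sum(np.log2((x + p) / (x + p * e))))

    n = ch.n
    p0 = np.full(n, 1.0 / n)
    scale = max(raw(p0), 1e-300)  # SLSQP tolerances are absolute

    def neg(p):
        return -raw(p) / scale

    def neg_grad(p):
        p = np.clip(p, 0.0, None)
        return -(1.0 / (2.0 * LN2 * scale)) * (1.0 / (x + p) - e / (x + p * e))

    res = sp_optimize.minimize(
        neg, p0, jac=neg_grad, method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda p: np.sum(p) - 1.0,
                      "jac": lambda p: np.ones_like(p)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    p = np.clip(res.x, 0.0, None)
    p /= p.sum()
    Sigma = (V * p) @ V.T
    return Sigma, float(raw(p)), bool(res.success)


def capacity(ch: NetworkChannel, opts: OptimizerOptions | None = None) -> CapacityResult:
    """Information capacity ``C_T`` in bits, maximized over trace-one
    PSD input covariances.

    Structure-aware short-circuits: a scalar input (m = 1) needs no
    search; a symmetric ``A`` with full input/output reduces to an exact
    concave power allocation across eigenmodes.  Otherwise a
    multi-restart factor-gradient search runs (single restart when the
    concavity certificate holds).
    """
    opts = opts or OptimizerOptions()
    cert = convexity_certificate(ch.A, ch.C, ch.T)
    if ch.m == 1:
        Sigma = np.array([[1.0]])
        value = capacity_given_input(ch, Sigma)
        used, converged = 0, True
    elif ch.full_io and _is_symmetric(ch.A):
        Sigma, value, converged = _symmetric_full_io_capacity(ch)
        used = 1
    else:
        obj = _CapacityObjective(ch)
        # energy-aligned start: the high-noise optimum concentrates all
        # power along the top eigenvector of B' O B
        BOB = _sym(ch.B.T @ obj.Oh @ obj.Oh @ ch.B)
        v = linalg.eigh(BOB)[1][:, -1]
        run_opts = replace(opts, extra_inits=list(opts.extra_inits) + [np.outer(v, v)])
        Sigma, value, diag = optimize_input_covariance(
            obj.value, ch.m, run_opts, gradient=obj.gradient, concave=cert
        )
        used, converged = diag["n_restarts_used"], diag["converged"]
        if not converged:
            warnings.warn("input-covariance search did not converge; best value returned")
    return CapacityResult(
        capacity_bits=float(value),
        rate_bits_per_time=float(value) / ch.T,
        sigma_opt=Sigma,
        n_restarts_used=used,
        converged=converged,
        convex_certificate=bool(cert),
        input_dimensionality=participation_ratio(Sigma),
    )


def rate(ch: NetworkChannel, opts: OptimizerOptions | None = None) -> CapacityResult:
    """Information rate ``R_T = C_T / T`` (bits per unit time); returns
    the full :class:`CapacityResult`."""
    return capacity(ch, opts)


def _golden_max(f, lo, hi, rel_tol=1e-4, max_iter=100):
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if (b - a) <= rel_tol * max(abs(a), abs(b)):
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (c, fc) if fc >= fd else (d, fd)


def max_rate_over_T(A, T_grid, B=None, C=None, sigma2: float = 1.0,
                    opts: OptimizerOptions | None = None, refine: bool = True,
                    rel_tol: float = 1e-4) -> RateMaximum:
    """Maximize ``R_T`` over the transmission window.

    Evaluates the rate on ``T_grid`` (sorted, all >= ``T_MIN``), then
    refines around the best interior grid point by golden-section
    search.  A maximum at the smallest grid point is reported as a
    boundary optimum (the signature of normal networks, which are best
    exploited as ``T -> 0``).
    """
    T_grid = np.asarray(T_grid, dtype=float)
    if T_grid.size == 0:
        raise ValueError("empty T grid")
    if np.any(np.diff(T_grid) <= 0) or T_grid[0] < T_MIN:
        raise ValueError(f"T_grid must be strictly increasing with min >= {T_MIN}")
    results = {}

    def rate_at(T):
        if T not in results:
            ch = NetworkChannel(A=A, B=B, C=C, T=float(T), sigma2=sigma2)
            results[T] = capacity(ch, opts)
        return results[T].rate_bits_per_time

    rates = np.array([rate_at(T) for T in T_grid])
    i = int(np.argmax(rates))
    boundary = i == 0
    T_opt, R_max = float(T_grid[i]), float(rates[i])
    if refine and 0 < i < T_grid.size - 1:
        T_ref, R_ref = _golden_max(rate_at, T_grid[i - 1], T_grid[i + 1], rel_tol)
        if R_ref > R_max:
            T_opt, R_max = float(T_ref), float(R_ref)
    return RateMaximum(
        R_max=R_max, T_opt=T_opt, boundary=boundary, T_grid=T_grid,
        rates=rates, result=results[T_opt],
    )


def normal_rate_bound(trace_A: float, sigma2: float) -> float:
    """Upper bound on the rate of any normal network:
    ``(1/ln 2) tr(A) / (2 sigma2 tr(A) - 1)``.

    Depends on the connectivity only through ``tr(A)``; at low SNR it
    degenerates to ``1/(2 ln 2 sigma2)`` regardless of wiring.
    """
    if trace_A >= 0:
        raise ValueError("trace_A must be negative (stable network)")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    return (1.0 / LN2) * trace_A / (2.0 * sigma2 * trace_A - 1.0)


def low_noise_rate(A) -> float:
    """Low-noise (sigma2 -> 0) rate, ``-tr(A)/ln 2`` bits per unit time:
    the spectrum alone sets the rate, non-normality is irrelevant.
    Also the limit attained by infinitely non-normal chains at any
    noise level."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if not is_stable(A):
        raise ValueError("A must be stable")
    return -float(np.trace(A)) / LN2


def high_noise_rate(ch: NetworkChannel) -> float:
    """High-noise (sigma2 -> inf) rate asymptote,
    ``lambda_max(B' O B) / (2 ln 2 T sigma2)``: the largest output
    energy the network can generate from a unit input within one
    window, traded against the noise floor.  Attained by rank-one input
    covariances along the most amplified input direction."""
    O = observability_gramian(ch.A, ch.C, ch.T)
    BOB = _sym(ch.B.T @ O @ ch.B)
    lam_max = float(linalg.eigvalsh(BOB)[-1])
    return lam_max / (2.0 * LN2 * ch.T * ch.sigma2)
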