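"""Effective dimensionality and non-normality diagnostics."""

from __future__ import annotations

import numpy as np
from scipy import linalg

__all__ = ["participation_ratio", "nonnormality_index"]


def participation_ratio(M: np.ndarray) -> float:
    """Participation ratio ``(sum_i lam_i)^2 / sum_i lam_i^2`` of a
    symmetric PSD matrix.

    Equals ``n`` for the identity (all directions used equally) and 1
    for a rank-one matrix; applied to a covariance it measures the
    effective dimensionality of the underlying random vector.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.shape[0] != M.shape[1]:
        raise ValueError("M must be square")
    M = 0.5 * (M + M.T)
    lam = linalg.eigvalsh(M)
    if lam[0] < -1e-10 * max(abs(lam[-1]), 1.0):
        raise ValueError(f"M is not PSD (min eigenvalue {lam[0]:.3e})")
    lam = np.clip(lam, 0.0, None)
    s2 = float(np.sum(lam**2))
    if s2 == 0.0:
        raise ValueError("participation ratio undefined for the zero matrix")
    return float(np.sum(lam) ** 2 / s2)


def nonnormality_index(A: np.ndarray, kind: str = "henrici",
                       normalized: bool = True) -> float:
    """Scalar degree of matrix non-normality.

    Henrici's departure from normality,
    ``sqrt(||A||_F^2 - sum_i |lam_i|^2)``: the Frobenius mass of the
    strictly-triangular (feedforward) part of the Schur form.  Zero iff
    ``A`` is normal.  With ``normalized=True`` (default) the value is
    divided by ``||A||_F``, giving a scale-free index in [0, 1) that
    approaches 1 for purely feedforward structure; the normalized
    variant saturates quickly in disordered ensembles, so comparisons
    of *how far* two networks of similar scale depart from normality
    are often better made unnormalized.
    """
    if kind != "henrici":
        raise ValueError(f"unknown non-normality index {kind!r}")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    fro2 = float(np.sum(A * A))
    if fro2 == 0.0:
        return 0.0
    lam = np.linalg.eigvals(A)
    dep2 = max(fro2 - float(np.sum(np.abs(lam) ** 2)), 0.0)
    return float(np.sqrt(dep2 / fro2)) if normalized else float(np.sqrt(dep2))
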