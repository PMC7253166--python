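"""Text I/O for dense matrices and weighted edge lists.

Conventions
-----------
Dense matrices are whitespace- or comma-delimited numeric grids, one row
per line.  Edge lists are three-column delimited files
``source  target  weight``; an optional header row is detected and
skipped.  The adjacency convention throughout the package is
``A[i, j]`` = weight of the edge ``j -> i`` (so that ``dx/dt = A x``
propagates activity along edges), and edge-list readers apply it.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_dense_matrix",
    "write_dense_matrix",
    "read_edge_list",
    "write_edge_list",
]


def read_dense_matrix(path) -> np.ndarray:
    """Read a dense numeric matrix from a delimited text file."""
    text = Path(path).read_text()
    rows = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        rows.append([float(tok) for tok in line.replace(",", " ").split()])
    if not rows:
        raise ValueError(f"no numeric data in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged rows in {path}: lengths {sorted(lengths)}")
    M = np.asarray(rows, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError(f"non-finite entries in {path}")
    return M


def write_dense_matrix(path, M: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(np.asarray(M, dtype=float)), fmt="%.17g")


def _read_table(path) -> pd.DataFrame:
    """Read a small delimited table, tolerating comma/tab/space delimiters
    and an optional header row."""
    raw = Path(path).read_text()
    lines = [ln for ln in raw.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError(f"empty table {path}")
    first = lines[0].replace(",", " ").split()
    # header if the last field of the first row is not numeric
    try:
        float(first[-1])
        header = None
    except ValueError:
        header = 0
    return pd.read_csv(
        _io.StringIO("\n".join(lines)),
        sep=r"[,\s]+",
        engine="python",
        header=header,
    )


def read_edge_list(path):
    """Read a weighted directed edge list.

    Returns ``(A, node_index)`` where ``A[i, j]`` holds the summed weight
    of edges ``j -> i`` and ``node_index`` maps node labels to row/column
    indices (labels sorted for determinism).
    """
    df = _read_table(path)
    if df.shape[1] < 3:
        raise ValueError(f"edge list {path} needs 3 columns (source, target, weight)")
    src = df.iloc[:, 0].astype(str).to_numpy()
    dst = df.iloc[:, 1].astype(str).to_numpy()
    w = df.iloc[:, 2].astype(float).to_numpy()
    labels = sorted(set(src) | set(dst))
    idx = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    A = np.zeros((n, n))
    for s, d, wt in zip(src, dst, w):
        A[idx[d], idx[s]] += wt  # edge s -> d stored column s, row d
    return A, idx


def write_edge_list(path, A: np.ndarray, labels=None) -> None:
    """Write the nonzero entries of ``A`` as ``source target weight`` rows."""
    A = np.asarray(A)
    n = A.shape[0]
    if labels is None:
        labels = [str(k) for k in range(n)]
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for i in range(n):
            for j in range(n):
                if A[i, j] != 0.0:
                    fh.write(f"{labels[j]}\t{labels[i]}\t{A[i, j]:.17g}\n")
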