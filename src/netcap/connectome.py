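"""Connectome communication analysis.

Implements the protocol used to ask whether a directed biological
wiring diagram (the C. elegans chemical-synapse network: 279 neurons,
88 sensory / 82 inter / 107 motor, 26 GABAergic, 2194 directed
synapses) is non-normal *in a way that benefits information
transmission*:

1. load a signed, weighted, directed adjacency with node classes
   (GABAergic presynaptic neurons contribute inhibitory, negative
   outgoing weights);
2. stabilize the linearized membrane dynamics
   ``tau x' = (A - gamma I) x`` by shifting the spectrum so the slowest
   mode decays at a prescribed rate (defaults ``tau = 0.5``, largest
   eigenvalue real part ``-0.1``);
3. compute the information-rate curve ``R_T`` versus the transmission
   window, for full communication (``B = C = I``) or with inputs on
   sensory and outputs on motor neurons;
4. compare against structure-destroying nulls — symmetrization
   ``(A + A')/2`` and random reversal of each edge pair with
   probability 1/2 — and against random input/output node selections,
   with confidence bands over realizations.

A seeded synthetic generator emulates the dataset schema (three node
classes, signed weighted directed graph, tunable sensory->inter->motor
feedforward bias) so the full pipeline runs without any download.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as ncio
from .capacity import NetworkChannel, capacity
from .networks import randomize_edge_directions, stabilize_shift, symmetrize
from .optimize import OptimizerOptions

__all__ = [
    "Connectome",
    "EnsembleCurve",
    "RateCurve",
    "load_connectome",
    "save_connectome",
    "synthetic_connectome_fixture",
    "stabilized_dynamics",
    "class_selectors",
    "random_selectors",
    "rate_sweep",
    "randomized_ensemble",
    "default_T_grid",
]

NODE_CLASSES = ("sensory", "inter", "motor")


def default_T_grid(n_points: int = 30, lo: float = 0.01, hi: float = 10.0) -> np.ndarray:
    """Log-spaced transmission-window grid covering the qualitative
    regimes of the stabilized dynamics (time constant ~ tau)."""
    return np.geomspace(lo, hi, n_points)


@dataclass
class Connectome:
    """Signed weighted directed adjacency with node classes.

    ``A_signed[i, j]`` is the synaptic weight of the edge ``j -> i``,
    negative iff node ``j`` is inhibitory (GABAergic).
    """

    A_signed: np.ndarray
    node_ids: list
    node_class: dict  # label -> {"sensory", "inter", "motor"}
    inhibitory: set

    def __post_init__(self):
        self.A_signed = np.atleast_2d(np.asarray(self.A_signed, dtype=float))
        n = self.A_signed.shape[0]
        if self.A_signed.shape != (n, n) or len(self.node_ids) != n:
            raise ValueError("A_signed must be square and match node_ids")
        missing = [v for v in self.node_ids if v not in self.node_class]
        if missing:
            raise ValueError(f"nodes without class assignment: {missing[:5]}")
        bad = {c for c in self.node_class.values()} - set(NODE_CLASSES)
        if bad:
            raise ValueError(f"unknown node classes: {bad}")
        # sign rule: outgoing (column) weights of inhibitory nodes <= 0,
        # all other columns >= 0
        for j, lab in enumerate(self.node_ids):
            col = self.A_signed[:, j]
            if lab in self.inhibitory:
                if np.any(col > 0):
                    raise ValueError(f"inhibitory node {lab} has positive outgoing weights")
            elif np.any(col < 0):
                raise ValueError(f"excitatory node {lab} has negative outgoing weights")

    @property
    def n(self) -> int:
        return self.A_signed.shape[0]

    def class_members(self, cls: str) -> list:
        if cls == "all":
            return list(self.node_ids)
        if cls not in NODE_CLASSES:
            raise ValueError(f"unknown class {cls!r}")
        return [v for v in self.node_ids if self.node_class[v] == cls]


def load_connectome(edges_path, classes_path) -> Connectome:
    """Build a :class:`Connectome` from an edge list
    ``(pre_id, post_id, weight >= 0)`` and a class table
    ``(id, class, gabaergic 0/1)``.

    Duplicate edges are summed (with a warning); inhibitory signs are
    applied to the outgoing weights of GABAergic nodes after summation.
    """
    cls_df = ncio._read_table(classes_path)
    if cls_df.shape[1] < 3:
        raise ValueError("class table needs 3 columns (id, class, gabaergic)")
    labels = [str(x) for x in cls_df.iloc[:, 0]]
    classes = [str(x).lower() for x in cls_df.iloc[:, 1]]
    gaba = [bool(int(x)) for x in cls_df.iloc[:, 2]]
    node_class = dict(zip(labels, classes))
    inhib = {lab for lab, g in zip(labels, gaba) if g}

    edf = ncio._read_table(edges_path)
    if edf.shape[1] < 3:
        raise ValueError("edge list needs 3 columns (pre, post, weight)")
    pre = [str(x) for x in edf.iloc[:, 0]]
    post = [str(x) for x in edf.iloc[:, 1]]
    w = edf.iloc[:, 2].astype(float).to_numpy()
    if np.any(w < 0):
        raise ValueError("edge weights must be nonnegative (signs come from classes)")
    unknown = (set(pre) | set(post)) - set(labels)
    if unknown:
        raise ValueError(f"edge nodes missing from the class table: {sorted(unknown)[:5]}")

    idx = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    A = np.zeros((n, n))
    seen = set()
    dups = 0
    for s, d, wt in zip(pre, post, w):
        if (s, d) in seen:
            dups += 1
        seen.add((s, d))
        A[idx[d], idx[s]] += wt
    if dups:
        warnings.warn(f"{dups} duplicate edges were summed")
    for lab in inhib:
        A[:, idx[lab]] *= -1.0
    return Connectome(A_signed=A, node_ids=labels, node_class=node_class, inhibitory=inhib)


def save_connectome(cn: Connectome, edges_path, classes_path) -> None:
    """Write the connectome back to the two-file text schema (weights
    unsigned in the edge list; signs re-derivable from the class table)."""
    with open(classes_path, "w") as fh:
        fh.write("id\tclass\tgabaergic\n")
        for lab in cn.node_ids:
            fh.write(f"{lab}\t{cn.node_class[lab]}\t{int(lab in cn.inhibitory)}\n")
    with open(edges_path, "w") as fh:
        fh.write("pre\tpost\tweight\n")
        for j, src in enumerate(cn.node_ids):
            for i, dst in enumerate(cn.node_ids):
                wt = cn.A_signed[i, j]
                if wt != 0.0:
                    fh.write(f"{src}\t{dst}\t{abs(wt):.17g}\n")


def synthetic_connectome_fixture(
    n: int = 60,
    class_fractions=(88 / 277, 82 / 277, 107 / 277),
    inhib_fraction: float = 26 / 279,
    directionality: float = 3.0,
    density: float = 2194 / (279 * 278),
    seed: int = 0,
) -> Connectome:
    """Seeded synthetic stand-in emulating the chemical-synapse dataset
    schema.

    Classes (sensory, inter, motor) are assigned in ``class_fractions``
    proportions (defaults mirror 88:82:107) and a random subset
    (default 26/279) is marked inhibitory.  Directed edges are drawn
    with overall density ``density``; pairs aligned with the
    sensory -> inter -> motor hierarchy are ``(1 + directionality)``
    times more likely than anti-aligned ones, so ``directionality = 0``
    yields no directed structure and large values a strongly
    feedforward (non-normal) graph.  Weights are integer synapse
    counts (geometric).
    """
    if abs(sum(class_fractions) - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    if directionality < 0:
        raise ValueError("directionality must be nonnegative")
    rng = np.random.default_rng(seed)
    counts = [int(round(f * n)) for f in class_fractions[:2]]
    counts.append(n - sum(counts))
    classes = sum(([c] * k for c, k in zip(NODE_CLASSES, counts)), [])
    labels = [f"n{k:03d}" for k in range(n)]
    node_class = dict(zip(labels, classes))
    n_inhib = max(1, int(round(inhib_fraction * n)))
    inhib = set(rng.choice(labels, size=n_inhib, replace=False).tolist())

    rank = {"sensory": 0, "inter": 1, "motor": 2}
    r = np.array([rank[c] for c in classes])
    forward = r[None, :] < r[:, None]  # row=post, col=pre: pre lower in hierarchy
    backward = r[None, :] > r[:, None]
    bias = np.ones((n, n))
    bias[forward] *= 1.0 + directionality
    bias[backward] /= 1.0 + directionality
    np.fill_diagonal(bias, 0.0)
    off = ~np.eye(n, dtype=bool)
    p_edge = density * bias * off.sum() / bias[off].sum()
    edges = rng.random((n, n)) < np.clip(p_edge, 0.0, 1.0)
    np.fill_diagonal(edges, False)
    A = np.where(edges, rng.geometric(0.35, size=(n, n)).astype(float), 0.0)
    for j, lab in enumerate(labels):
        if lab in inhib:
            A[:, j] *= -1.0
    return Connectome(A_signed=A, node_ids=labels, node_class=node_class, inhibitory=inhib)


def stabilized_dynamics(cn_or_A, tau: float = 0.5, target: float = -0.1):
    """Leaky linearized dynamics ``(A - gamma I)/tau`` with ``gamma``
    tuned so the slowest mode decays at rate ``-target``."""
    A = cn_or_A.A_signed if isinstance(cn_or_A, Connectome) else np.asarray(cn_or_A, float)
    return stabilize_shift(A, tau=tau, target_realpart=target)


def class_selectors(cn: Connectome, input_class: str = "all", output_class: str = "all"):
    """0/1 selector matrices ``(B, C)``: one unit column of ``B`` per
    input node, one unit row of ``C`` per output node."""
    idx = {lab: k for k, lab in enumerate(cn.node_ids)}
    inp = [idx[v] for v in cn.class_members(input_class)]
    out = [idx[v] for v in cn.class_members(output_class)]
    if not inp or not out:
        raise ValueError("empty input or output class")
    B = np.zeros((cn.n, len(inp)))
    B[inp, np.arange(len(inp))] = 1.0
    C = np.zeros((len(out), cn.n))
    C[np.arange(len(out)), out] = 1.0
    return B, C


def random_selectors(cn: Connectome, m: int, p: int, seed: int = 0):
    """Random nonoverlapping input/output node selections of sizes
    ``(m, p)`` (the null for the sensory-in / motor-out hypothesis)."""
    if m + p > cn.n:
        raise ValueError("m + p exceeds the number of nodes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(cn.n)
    inp, out = np.sort(perm[:m]), np.sort(perm[m:m + p])
    B = np.zeros((cn.n, m))
    B[inp, np.arange(m)] = 1.0
    C = np.zeros((p, cn.n))
    C[np.arange(p), out] = 1.0
    return B, C


@dataclass
class RateCurve:
    """Information-rate curve over a transmission-window grid."""

    T_grid: np.ndarray
    rates: np.ndarray
    converged: np.ndarray  # per-point optimizer flag; NaN rate where failed
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "T": self.T_grid, "rate": self.rates,
            "converged": self.converged, "label": self.label,
        })


@dataclass
class EnsembleCurve:
    """Mean rate curve with a 95% confidence band over realizations."""

    T_grid: np.ndarray
    mean_rate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_realizations: int
    gammas: list
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "T": self.T_grid, "mean": self.mean_rate,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "label": self.label,
        })


def rate_sweep(A_dyn, B, C, T_grid, sigma2: float = 1.0,
               opts: OptimizerOptions | None = None, label: str = "") -> RateCurve:
    """``R_T`` per grid point; per-point failures are recorded as NaN
    and flagged rather than aborting the sweep."""
    T_grid = np.asarray(T_grid, dtype=float)
    rates = np.full(T_grid.shape, np.nan)
    flags = np.zeros(T_grid.shape, dtype=bool)
    for k, T in enumerate(T_grid):
        try:
            res = capacity(NetworkChannel(A=A_dyn, B=B, C=C, T=float(T), sigma2=sigma2), opts)
            rates[k] = res.rate_bits_per_time
            flags[k] = res.converged
        except (ValueError, FloatingPointError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"rate evaluation failed at T={T:g}: {exc}")
    return RateCurve(T_grid=T_grid, rates=rates, converged=flags, label=label)


def randomized_ensemble(
    cn: Connectome,
    manipulation: str,
    n_real: int = 10,
    seed: int = 0,
    T_grid=None,
    tau: float = 0.5,
    target: float = -0.1,
    sigma2: float = 1.0,
    swap_p: float = 0.5,
    opts: OptimizerOptions | None = None,
    ci_method: str = "normal",
) -> EnsembleCurve:
    """Null ensemble of rate curves under a structure-destroying
    manipulation.

    ``manipulation``:
      - ``"direction-swap"``: each signed entry pair ``(A_ij, A_ji)``
        is exchanged with probability ``swap_p`` (an inhibitory edge
        stays inhibitory after reversal); full I/O; the manipulated
        matrix is re-stabilized per realization.
      - ``"random-BC"``: the stabilized real network with fresh random
        nonoverlapping input/output selections of the sensory/motor
        class sizes.

    The band is the normal-approximation 95% CI, ``mean +/- 1.96
    SE``; ``ci_method="bootstrap"`` switches to a percentile bootstrap.
    """
    if n_real < 2:
        raise ValueError("need at least 2 realizations")
    if manipulation not in ("direction-swap", "random-BC"):
        raise ValueError(f"unknown manipulation {manipulation!r}")
    if ci_method not in ("normal", "bootstrap"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    T_grid = default_T_grid() if T_grid is None else np.asarray(T_grid, dtype=float)
    m = len(cn.class_members("sensory"))
    p = len(cn.class_members("motor"))
    A_real, _ = stabilized_dynamics(cn, tau, target)

    curves = np.empty((n_real, T_grid.size))
    gammas = []
    for r in range(n_real):
        sub = seed + 1 + r  # fixed per-realization seed increment
        if manipulation == "direction-swap":
            A_swap = randomize_edge_directions(cn.A_signed, p=swap_p, seed=sub)
            A_dyn, gamma = stabilize_shift(A_swap, tau=tau, target_realpart=target)
            B, C = np.eye(cn.n), np.eye(cn.n)
        else:
            A_dyn, gamma = A_real, None
            B, C = random_selectors(cn, m, p, seed=sub)
        gammas.append(gamma)
        curves[r] = rate_sweep(A_dyn, B, C, T_grid, sigma2, opts).rates

    mean = np.nanmean(curves, axis=0)
    if ci_method == "normal":
        se = np.nanstd(curves, axis=0, ddof=1) / np.sqrt(n_real)
        lo, hi = mean - 1.96 * se, mean + 1.96 * se
    else:
        rng = np.random.default_rng(seed)
        boots = np.empty((500, T_grid.size))
        for b in range(500):
            pick = rng.integers(0, n_real, size=n_real)
            boots[b] = np.nanmean(curves[pick], axis=0)
        lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return EnsembleCurve(
        T_grid=T_grid, mean_rate=mean, ci_low=lo, ci_high=hi,
        n_realizations=n_real, gammas=gammas, label=manipulation,
    )
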