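"""Random walk with restart: the influence matrix and its solvers.

A walk starting at any node terminates with probability ``alpha`` at each
step and otherwise moves to a neighbor with probability proportional to edge
weight.  The matrix of termination probabilities solves

    F = alpha * (I - (1 - alpha) * W)^{-1},   W = D^{-1} A,

where A is the combined adjacency and D its diagonal degree matrix.  F is
row-stochastic; the cell-row, tree-node-column block drives all region
scoring downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .hierarchy import CellTypeTree
from .network import CombinedGraph

# above this size the closed-form dense solve is replaced by fixed-point iteration
_DIRECT_SOLVE_MAX = 5000
_NEG_FLOOR = -1e-12


class DegreeError(ValueError):
    """A node with zero total edge weight makes W undefined."""


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class WalkParams:
    """Restart probability and iteration controls.

    ``alpha`` is the per-step termination (restart) probability; smaller
    values let walks range further over the graph.
    """

    alpha: float = 0.5
    max_iter: int = 10_000
    tol: float = 1e-10

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")


@dataclass
class InfluenceMatrix:
    """Walk-termination probabilities; node order matches the combined graph."""

    values: np.ndarray
    node_names: list[str]

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.min(initial=0.0) < _NEG_FLOOR:
            raise ValueError(f"influence entries below numerical floor: min={vals.min()}")
        vals = np.clip(vals, 0.0, None)
        rowsums = vals.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-8):
            worst = np.abs(rowsums - 1.0).max()
            raise ValueError(f"influence rows must sum to 1 (worst deviation {worst:.2e})")
        self.values = vals


def _as_adjacency(graph) -> tuple[sp.csr_matrix, list[str]]:
    """Accept a CombinedGraph or a bare symmetric adjacency matrix."""
    if hasattr(graph, "adjacency"):
        return sp.csr_matrix(graph.adjacency), list(graph.node_names)
    A = sp.csr_matrix(np.asarray(graph, dtype=float) if not sp.issparse(graph) else graph)
    return A, [str(i) for i in range(A.shape[0])]


def _transition_matrix(graph) -> tuple[sp.csr_matrix, list[str]]:
    A, names = _as_adjacency(graph)
    deg = np.asarray(A.sum(axis=1)).ravel()
    if (deg <= 0).any():
        bad = [names[i] for i in np.where(deg <= 0)[0]]
        raise DegreeError(f"nodes with zero degree (disconnected): {bad[:10]}")
    return sp.diags(1.0 / deg) @ A, names


def solve_influence_closed(graph, params: WalkParams) -> InfluenceMatrix:
    """Direct solve of F = alpha (I - (1-alpha) W)^{-1}."""
    W, names = _transition_matrix(graph)
    m = W.shape[0]
    if params.alpha == 1.0:
        return InfluenceMatrix(np.eye(m), names)
    M = sp.eye(m, format="csc") - (1.0 - params.alpha) * W.tocsc()
    try:
        lu = spla.splu(M)
    except RuntimeError as exc:
        raise np.linalg.LinAlgError(f"singular diffusion system: {exc}") from exc
    F = params.alpha * lu.solve(np.eye(m))
    return InfluenceMatrix(F, names)


def solve_influence_iterative(graph, params: WalkParams) -> InfluenceMatrix:
    """Fixed-point iteration F_{t+1} = alpha I + (1-alpha) W F_t from F_0 = I."""
    W, names = _transition_matrix(graph)
    m = W.shape[0]
    I = np.eye(m)
    F = I.copy()
    alpha = params.alpha
    for _ in range(params.max_iter):
        F_next = alpha * I + (1.0 - alpha) * (W @ F)
        delta = np.abs(F_next - F).max()
        F = F_next
        if delta < params.tol:
            return InfluenceMatrix(F, names)
    raise ConvergenceError(
        f"no convergence after {params.max_iter} iterations (residual {delta:.2e})"
    )


def solve_influence(graph, params: WalkParams | None = None) -> InfluenceMatrix:
    """Solve for the influence matrix, choosing the solver by problem size."""
    params = params or WalkParams()
    size = graph.size if hasattr(graph, "size") and hasattr(graph, "adjacency") else _as_adjacency(graph)[0].shape[0]
    return solve_influence_closed(graph, params) if size <= _DIRECT_SOLVE_MAX else solve_influence_iterative(graph, params)


def drop_isolated_cells(graph: CombinedGraph) -> CombinedGraph:
    """Remove cells with no edges at all (cannot participate in any walk)."""
    from .network import CombinedGraph as CG

    deg = np.asarray(graph.adjacency.sum(axis=1)).ravel()
    n_nodes = graph.tree.node_count
    cell_deg = deg[n_nodes:]
    keep = cell_deg > 0
    if keep.all():
        return graph
    dropped = [graph.cells[i] for i in np.where(~keep)[0]]
    warnings.warn(f"dropping {len(dropped)} isolated cells: {dropped[:10]}")
    keep_idx = np.concatenate([np.arange(n_nodes), n_nodes + np.where(keep)[0]])
    sub = graph.adjacency[keep_idx][:, keep_idx]
    return CG(tree=graph.tree, cells=[c for c, k in zip(graph.cells, keep) if k],
              adjacency=sp.csr_matrix(sub), label_edge_weight=graph.label_edge_weight)


def monte_carlo_influence(
    graph, params: WalkParams, start: str, n_walks: int, seed: int
) -> np.ndarray:
    """Empirical termination distribution of seeded simulated walks.

    Test oracle for the analytic solvers: each walk terminates with
    probability ``alpha`` at every step (including step zero, before any
    move) and otherwise steps to a neighbor chosen proportionally to edge
    weight.  Returns a probability vector over all graph nodes summing to 1.
    """
    if n_walks < 1:
        raise ValueError("n_walks must be >= 1")
    rng = np.random.default_rng(seed)
    W, names = _transition_matrix(graph)
    W = W.toarray()
    cum = np.cumsum(W, axis=1)
    m = W.shape[0]
    start_idx = names.index(str(start))

    counts = np.zeros(m, dtype=np.int64)
    position = np.full(n_walks, start_idx, dtype=np.int64)
    active = np.ones(n_walks, dtype=bool)
    while active.any():
        stop = rng.random(active.sum()) < params.alpha
        idx = np.where(active)[0]
        stopping = idx[stop]
        np.add.at(counts, position[stopping], 1)
        active[stopping] = False
        moving = idx[~stop]
        if moving.size:
            u = rng.random(moving.size)
            position[moving] = np.array(
                [np.searchsorted(cum[p], x) for p, x in zip(position[moving], u)]
            )
    return counts / n_walks


def extract_cell_to_label_block(F: InfluenceMatrix, tree: CellTypeTree) -> np.ndarray:
    """Sub-block of F: rows = cells, columns = all tree nodes (leaves + internal)."""
    n_nodes = tree.node_count
    return F.values[n_nodes:, :n_nodes]
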