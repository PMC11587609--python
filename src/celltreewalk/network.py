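"""Graph construction: cell-cell similarity, label-cell edges, assembly, tuning.

The combined graph has one node per tree node (leaves and internal groupings)
followed by one node per cell.  Cell-cell edges encode genome-wide
accessibility similarity; label-cell edges encode marker-gene activity and are
scaled by a tunable multiplier; internal tree nodes connect to cells only
through the tree, never directly (their cell block is zero-padded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .hierarchy import CellTypeTree, encode_tree_adjacency

logger = logging.getLogger(__name__)


class PreprocessingError(ValueError):
    pass


class AssemblyError(ValueError):
    pass


@dataclass
class AccessibilityMatrix:
    """Binary peak-by-cell accessibility with peak coordinates.

    ``peaks`` is a DataFrame with columns chrom/start/end (0-based half-open);
    ``matrix`` is sparse CSR of shape (n_peaks, n_cells), binarized on load.
    """

    peaks: pd.DataFrame
    cells: list[str]
    matrix: sp.csr_matrix

    def __post_init__(self):
        required = {"chrom", "start", "end"}
        if not required.issubset(self.peaks.columns):
            raise PreprocessingError(f"peaks table must have columns {sorted(required)}")
        if (self.peaks["start"] >= self.peaks["end"]).any():
            bad = self.peaks[self.peaks["start"] >= self.peaks["end"]]
            raise PreprocessingError(f"peaks with start >= end: {bad.index.tolist()[:5]}")
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.peaks), len(self.cells)):
            raise PreprocessingError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.peaks)} peaks x {len(self.cells)} cells"
            )
        self.matrix.data = (self.matrix.data != 0).astype(np.int8)
        self.matrix.eliminate_zeros()

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


@dataclass
class GeneActivityMatrix:
    """Nonnegative gene-by-cell activity scores (accessibility proxy for expression)."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(
            self.values.toarray() if sp.issparse(self.values) else self.values, dtype=float
        )
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise PreprocessingError("gene activity shape mismatch")
        if (self.values < 0).any():
            raise PreprocessingError("gene activity values must be nonnegative")


@dataclass
class MarkerTable:
    """Rows of (leaf cell type, gene, log fold-change weight)."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"cell_type", "gene", "log_fc"}
        if not required.issubset(self.table.columns):
            raise PreprocessingError(f"marker table must have columns {sorted(required)}")
        if not np.isfinite(self.table["log_fc"]).all():
            raise PreprocessingError("marker log_fc values must be finite")
        self.table = self.table.drop_duplicates(subset=["cell_type", "gene"]).reset_index(drop=True)

    def cell_types(self) -> list[str]:
        return list(pd.unique(self.table["cell_type"]))


@dataclass
class CombinedGraph:
    """Symmetric weighted adjacency over [tree nodes | cells]."""

    tree: CellTypeTree
    cells: list[str]
    adjacency: sp.csr_matrix
    label_edge_weight: float
    node_names: list[str] = field(init=False)

    def __post_init__(self):
        m = self.tree.node_count + len(self.cells)
        if self.adjacency.shape != (m, m):
            raise AssemblyError(f"adjacency shape {self.adjacency.shape}, expected {(m, m)}")
        self.node_names = list(self.tree.nodes) + list(self.cells)

    @property
    def size(self) -> int:
        return self.adjacency.shape[0]


def compute_cell_similarity(acc: AccessibilityMatrix, metric: str = "jaccard") -> np.ndarray:
    """Pairwise cell similarity from binarized genome-wide accessibility.

    Jaccard (default) or cosine over peak indicator vectors; values in [0, 1]
    with the diagonal zeroed (no self-edges).
    """
    X = acc.matrix.astype(np.float64)
    counts = np.asarray(X.sum(axis=0)).ravel()
    if (counts == 0).any():
        bad = [acc.cells[i] for i in np.where(counts == 0)[0]]
        raise PreprocessingError(f"cells with no accessible peaks: {bad}")
    inter = np.asarray((X.T @ X).todense())
    if metric == "jaccard":
        union = counts[:, None] + counts[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(union > 0, inter / union, 0.0)
    elif metric == "cosine":
        norms = np.sqrt(counts)
        sim = inter / np.outer(norms, norms)
    else:
        raise ValueError(f"unknown similarity metric {metric!r}")
    np.fill_diagonal(sim, 0.0)
    return np.clip(sim, 0.0, 1.0)


def compute_label_edges(gact: GeneActivityMatrix, markers: MarkerTable) -> tuple[np.ndarray, list[str]]:
    """Label-to-cell edge weights from marker-gene activity.

    For each leaf label the edge to a cell is the logFC-weighted sum of that
    cell's marker-gene activities, after normalizing each cell's activity
    vector to unit total, floored at zero.  Returns (n_labels x n_cells
    matrix, label order).  Marker genes missing from the activity matrix are
    dropped with a warning; a label with no usable marker is an error.
    """
    gene_idx = {g: i for i, g in enumerate(gact.genes)}
    totals = gact.values.sum(axis=0)
    if (totals == 0).any():
        bad = [gact.cells[i] for i in np.where(totals == 0)[0]]
        raise PreprocessingError(f"cells with zero total gene activity: {bad}")
    norm = gact.values / totals[None, :]

    labels = markers.cell_types()
    edges = np.zeros((len(labels), len(gact.cells)))
    for li, label in enumerate(labels):
        sub = markers.table[markers.table["cell_type"] == label]
        present = sub[sub["gene"].isin(gene_idx)]
        missing = sub[~sub["gene"].isin(gene_idx)]
        if not missing.empty:
            logger.warning(
                "label %s: dropping %d marker genes absent from gene activity: %s",
                label, len(missing), missing["gene"].tolist()[:10],
            )
        if present.empty:
            raise PreprocessingError(f"label {label!r}: all marker genes missing from gene activity matrix")
        rows = [gene_idx[g] for g in present["gene"]]
        w = present["log_fc"].to_numpy()
        edges[li] = w @ norm[rows]
    return np.maximum(edges, 0.0), labels


def gene_activity_from_peaks(
    acc: AccessibilityMatrix, gene_annotations: pd.DataFrame, upstream: int = 2000
) -> GeneActivityMatrix:
    """Fallback gene activity: accessible-peak counts over gene body + upstream.

    ``gene_annotations`` needs columns gene/chrom/start/end/strand.  Each
    gene's window is extended ``upstream`` bp in the 5' direction; the
    activity of a gene in a cell is the number of the cell's accessible peaks
    overlapping the window.
    """
    import pyranges as pr

    required = {"gene", "chrom", "start", "end", "strand"}
    if not required.issubset(gene_annotations.columns):
        raise PreprocessingError(f"gene annotations must have columns {sorted(required)}")
    ga = gene_annotations.copy()
    minus = ga["strand"] == "-"
    ga["start"] = np.where(minus, ga["start"], np.maximum(ga["start"] - upstream, 0))
    ga["end"] = np.where(minus, ga["end"] + upstream, ga["end"])

    genes_pr = pr.PyRanges(
        ga.rename(columns={"chrom": "Chromosome", "start": "Start", "end": "End"})[
            ["Chromosome", "Start", "End", "gene"]
        ]
    )
    peaks_df = acc.peaks.rename(columns={"chrom": "Chromosome", "start": "Start", "end": "End"}).copy()
    peaks_df["peak_idx"] = np.arange(len(peaks_df))
    hits = genes_pr.join(pr.PyRanges(peaks_df[["Chromosome", "Start", "End", "peak_idx"]])).df

    genes = list(ga["gene"])
    values = np.zeros((len(genes), acc.n_cells))
    if not hits.empty:
        gidx = {g: i for i, g in enumerate(genes)}
        dense = acc.matrix.toarray()
        for g, grp in hits.groupby("gene"):
            values[gidx[g]] = dense[grp["peak_idx"].to_numpy()].sum(axis=0)
    return GeneActivityMatrix(genes=genes, cells=list(acc.cells), values=values)


def assemble_graph(
    tree: CellTypeTree,
    cell_similarity: np.ndarray,
    label_edges: np.ndarray,
    label_order: list[str],
    cells: list[str],
    label_edge_weight: float = 100.0,
) -> CombinedGraph:
    """Assemble the combined [tree | cells] adjacency.

    Block layout::

        [ tree adjacency          | padded label edges * w ]
        [ (padded label edges)^T  | cell-cell similarity   ]

    where the label-cell block has one row per tree node: leaf rows carry the
    marker-derived edges scaled by ``label_edge_weight`` and internal-node
    rows are all zero.
    """
    n_nodes, c = tree.node_count, len(cells)
    if cell_similarity.shape != (c, c):
        raise AssemblyError(f"cell similarity shape {cell_similarity.shape}, expected {(c, c)}")
    if label_edges.shape != (len(label_order), c):
        raise AssemblyError("label edge matrix does not match label order / cell count")
    if set(label_order) != set(tree.leaf_names):
        raise AssemblyError("label order must cover exactly the tree leaves")
    if label_edge_weight < 0:
        raise AssemblyError("label_edge_weight must be nonnegative")

    padded = np.zeros((n_nodes, c))
    for li, label in enumerate(label_order):
        padded[tree.index(label)] = label_edges[li] * label_edge_weight

    tree_block = encode_tree_adjacency(tree)
    top = np.hstack([tree_block, padded])
    bottom = np.hstack([padded.T, cell_similarity])
    adjacency = sp.csr_matrix(np.vstack([top, bottom]))
    return CombinedGraph(tree=tree, cells=list(cells), adjacency=adjacency,
                         label_edge_weight=label_edge_weight)


def cell_homogeneity(influence: np.ndarray, tree: CellTypeTree, n_cells: int) -> float:
    """Tuning objective: how sharply cells separate by their top leaf label.

    Each cell is assigned the leaf with the highest cell-to-label influence;
    the objective is the log2 ratio of mean cell-to-cell influence within an
    assigned type to the mean between types.  Undefined (error) when all
    cells receive the same label.
    """
    n_nodes = tree.node_count
    cell_rows = influence[n_nodes:, :]
    leaf_block = cell_rows[:, : tree.n_leaves]
    assigned = leaf_block.argmax(axis=1)
    if len(np.unique(assigned)) < 2:
        raise ValueError("cell homogeneity undefined: all cells assigned one label")
    cc = influence[n_nodes:, n_nodes:]
    same = assigned[:, None] == assigned[None, :]
    off = ~np.eye(n_cells, dtype=bool)
    within = cc[same & off].mean()
    between = cc[~same].mean()
    eps = np.finfo(float).tiny
    return float(np.log2((within + eps) / (between + eps)))


def tune_edge_weight(
    tree: CellTypeTree,
    cell_similarity: np.ndarray,
    label_edges: np.ndarray,
    label_order: list[str],
    cells: list[str],
    grid: list[float] | None = None,
    walk_params=None,
) -> tuple[float, pd.DataFrame]:
    """Grid-search the label-edge multiplier by the cell-homogeneity objective.

    Default grid is powers of ten from 1 to 1e4.  Ties break toward the
    smaller weight.  Returns (best weight, per-weight diagnostics).
    """
    from .diffusion import WalkParams, solve_influence

    if grid is None:
        grid = [10.0 ** k for k in range(5)]
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("edge-weight grid is empty")
    params = walk_params or WalkParams()

    rows = []
    for w in grid:
        graph = assemble_graph(tree, cell_similarity, label_edges, label_order, cells, w)
        F = solve_influence(graph, params)
        rows.append({"weight": w, "homogeneity": cell_homogeneity(F.values, tree, len(cells))})
    diag = pd.DataFrame(rows)
    best = diag.loc[diag["homogeneity"].idxmax(), "weight"]  # idxmax → first max → smaller weight
    return float(best), diag


def edge_weight_grid(steps: int, low: float = 1.0, high: float = 1e4) -> list[float]:
    """Log-spaced grid of candidate label-edge weights; ``steps`` points."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if steps == 1:
        return [float(np.sqrt(low * high))]
    return list(np.logspace(np.log10(low), np.log10(high), steps))
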