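"""Cell similarity, label edges, graph assembly, and weight tuning."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from celltreewalk.hierarchy import parse_tree
from celltreewalk.network import (
    AccessibilityMatrix,
    GeneActivityMatrix,
    MarkerTable,
    PreprocessingError,
    AssemblyError,
    assemble_graph,
    compute_cell_similarity,
    compute_label_edges,
    edge_weight_grid,
    gene_activity_from_peaks,
    tune_edge_weight,
)


def acc_from_dense(values, starts=None):
    values = np.asarray(values)
    n_peaks = values.shape[0]
    starts = starts if starts is not None else np.arange(n_peaks) * 100
    peaks = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 50})
    cells = [f"c{i}" for i in range(values.shape[1])]
    return AccessibilityMatrix(peaks=peaks, cells=cells, matrix=sp.csr_matrix(values))


class TestCellSimilarity:
    def test_jaccard_hand_counts(self):
        # cells with peak sets {0,1,2}, {1,2,3}, {0,1,2} and a disjoint cell {4}
        acc = acc_from_dense(
            [
                [1, 0, 1, 0],
                [1, 1, 1, 0],
                [1, 1, 1, 0],
                [0, 1, 0, 0],
                [0, 0, 0, 1],
            ]
        )
        sim = compute_cell_similarity(acc)
        assert sim[0, 1] == pytest.approx(2 / 4)  # {1,2} over {0,1,2,3}
        assert sim[0, 2] == pytest.approx(1.0)  # identical sets
        assert sim[0, 3] == 0.0  # disjoint
        assert np.all(np.diag(sim) == 0)
        assert np.array_equal(sim, sim.T)
        assert sim.min() >= 0 and sim.max() <= 1

    def test_all_zero_cell_is_reported_by_barcode(self):
        acc = acc_from_dense([[1, 0], [1, 0]])
        with pytest.raises(PreprocessingError, match="c1"):
            compute_cell_similarity(acc)

    def test_invariant_to_peak_permutation(self):
        rng = np.random.default_rng(0)
        values = (rng.random((12, 6)) < 0.4).astype(int)
        values[:, values.sum(axis=0) == 0] = 1
        sim1 = compute_cell_similarity(acc_from_dense(values))
        perm = rng.permutation(12)
        sim2 = compute_cell_similarity(acc_from_dense(values[perm]))
        assert np.allclose(sim1, sim2)

    def test_cosine_option(self):
        acc = acc_from_dense([[1, 1], [1, 0], [0, 0], [0, 1]])
        sim = compute_cell_similarity(acc, metric="cosine")
        assert sim[0, 1] == pytest.approx(1 / 2)  # 1 / sqrt(2)*sqrt(2)


class TestLabelEdges:
    def test_weighted_normalized_sum(self, tiny_gene_activity, tiny_markers):
        edges, labels = compute_label_edges(tiny_gene_activity, tiny_markers)
        assert labels == ["A", "B"]
        # cell c1 activity totals 4, so each gene has normalized activity 1/4;
        # label A = 2*(1/4) + 1*(1/4) = 0.75, label B = 1.5*(1/4)
        assert edges[0, 0] == pytest.approx(0.75)
        assert edges[1, 0] == pytest.approx(0.375)
        # cell c2: g1 absent -> A = 1 * 2/4 = 0.5
        assert edges[0, 1] == pytest.approx(0.5)
        assert (edges >= 0).all()

    def test_negative_logfc_floors_at_zero(self):
        gact = GeneActivityMatrix(genes=["g1", "g2"], cells=["c"], values=np.array([[3.0], [1.0]]))
        markers = MarkerTable(
            pd.DataFrame({"cell_type": ["A", "A"], "gene": ["g1", "g2"], "log_fc": [-2.0, 1.0]})
        )
        edges, _ = compute_label_edges(gact, markers)
        # -2*(3/4) + 1*(1/4) = -1.25 -> clipped
        assert edges[0, 0] == 0.0

    def test_missing_gene_dropped_all_missing_raises(self, tiny_gene_activity):
        markers = MarkerTable(
            pd.DataFrame({"cell_type": ["A", "A"], "gene": ["g1", "absent"], "log_fc": [2.0, 1.0]})
        )
        edges, _ = compute_label_edges(tiny_gene_activity, markers)
        assert edges.shape == (1, 3)
        bad = MarkerTable(pd.DataFrame({"cell_type": ["A"], "gene": ["absent"], "log_fc": [1.0]}))
        with pytest.raises(PreprocessingError, match="all marker genes missing"):
            compute_label_edges(tiny_gene_activity, bad)

    def test_duplicate_marker_rows_are_deduped(self, tiny_gene_activity, tiny_markers):
        dup = MarkerTable(pd.concat([tiny_markers.table, tiny_markers.table]))
        e1, _ = compute_label_edges(tiny_gene_activity, tiny_markers)
        e2, _ = compute_label_edges(tiny_gene_activity, dup)
        assert np.allclose(e1, e2)


class TestAssembly:
    @pytest.fixture
    def pieces(self):
        tree = parse_tree("(A,B);")
        cellsim = np.array([[0, 0.5, 0.2], [0.5, 0, 0.1], [0.2, 0.1, 0]])
        label_edges = np.array([[1.0, 0.0, 0.3], [0.0, 2.0, 0.1]])
        return tree, cellsim, label_edges, ["A", "B"], ["c1", "c2", "c3"]

    def test_block_layout_and_padding(self, pieces):
        tree, cellsim, le, order, cells = pieces
        graph = assemble_graph(tree, cellsim, le, order, cells, label_edge_weight=10.0)
        A = graph.adjacency.toarray()
        assert A.shape == (6, 6)
        assert np.array_equal(A, A.T)
        assert np.all(np.diag(A) == 0)
        root_row = tree.index(tree.root)
        assert np.all(A[root_row, 3:] == 0)  # internal node touches no cell
        assert A[tree.index("A"), 3] == pytest.approx(10.0)
        assert np.array_equal(A[:3, :3], np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]]))
        assert np.array_equal(A[3:, 3:], cellsim)

    def test_zero_weight_disconnects_blocks(self, pieces):
        tree, cellsim, le, order, cells = pieces
        graph = assemble_graph(tree, cellsim, le, order, cells, label_edge_weight=0.0)
        A = graph.adjacency.toarray()
        assert np.all(A[:3, 3:] == 0) and np.all(A[3:, :3] == 0)

    def test_doubling_weight_doubles_only_label_block(self, pieces):
        tree, cellsim, le, order, cells = pieces
        A1 = assemble_graph(tree, cellsim, le, order, cells, 5.0).adjacency.toarray()
        A2 = assemble_graph(tree, cellsim, le, order, cells, 10.0).adjacency.toarray()
        assert np.allclose(A2[:3, 3:], 2 * A1[:3, 3:])
        assert np.allclose(A2[:3, :3], A1[:3, :3])
        assert np.allclose(A2[3:, 3:], A1[3:, 3:])

    def test_dimension_mismatch(self, pieces):
        tree, cellsim, le, order, cells = pieces
        with pytest.raises(AssemblyError):
            assemble_graph(tree, cellsim[:2, :2], le, order, cells, 1.0)


class TestTuning:
    def test_single_point_grid_returns_it(self):
        tree = parse_tree("(A,B);")
        cellsim = np.array([[0, 0.5, 0.2], [0.5, 0, 0.1], [0.2, 0.1, 0]])
        edges = np.array([[2.0, 0.1, 0.1], [0.1, 2.0, 2.0]])  # cells split across labels
        best, diag = tune_edge_weight(tree, cellsim, edges, ["A", "B"], ["c1", "c2", "c3"],
                                      grid=[7.0])
        assert best == 7.0
        assert len(diag) == 1

    def test_objective_varies_on_structured_data(self):
        from celltreewalk.simulate import SimConfig, simulate_dataset

        data = simulate_dataset(SimConfig(seed=5, n_leaves=4, cells_per_leaf=10,
                                          n_egenes=2, n_nonspecific_egenes=1))
        edges, order = compute_label_edges(data.gene_activity, data.markers)
        sim = compute_cell_similarity(data.accessibility)
        best, diag = tune_edge_weight(
            data.tree, sim, edges, order, data.accessibility.cells, grid=[1.0, 10.0, 100.0]
        )
        assert best in {1.0, 10.0, 100.0}
        assert diag["homogeneity"].nunique() > 1

    def test_grid_helper(self):
        assert edge_weight_grid(3) == pytest.approx([1.0, 100.0, 10000.0])
        with pytest.raises(ValueError):
            edge_weight_grid(0)


def test_gene_activity_fallback_counts_overlaps():
    acc = acc_from_dense([[1, 0], [1, 1], [0, 1]], starts=np.array([0, 3000, 6000]))
    genes = pd.DataFrame(
        {
            "gene": ["gA", "gB"],
            "chrom": ["chr1", "chr1"],
            "start": [2500, 8000],
            "end": [3500, 9000],
            "strand": ["+", "-"],
        }
    )
    gact = gene_activity_from_peaks(acc, genes, upstream=2000)
    # gA window [500, 3500) catches peak at 3000; gB window [8000, 11000) catches nothing
    assert gact.values[0].tolist() == [1.0, 1.0]
    assert gact.values[1].tolist() == [0.0, 0.0]
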