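import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from celltreewalk.hierarchy import parse_tree, random_binary_tree
from celltreewalk.network import AccessibilityMatrix, GeneActivityMatrix, MarkerTable


@pytest.fixture
def toy_tree():
    """Three leaves: ((A,B),C) with generated internal names A+B and A+B+C."""
    return parse_tree("((A,B),C);")


@pytest.fixture
def two_node_adjacency():
    return np.array([[0.0, 1.0], [1.0, 0.0]])


def random_tree(n_leaves: int, seed: int):
    return random_binary_tree([f"L{i}" for i in range(n_leaves)], seed=seed)


@pytest.fixture
def tiny_accessibility():
    """4 peaks x 3 cells with hand-placed entries for overlap arithmetic."""
    peaks = pd.DataFrame(
        {"chrom": ["chr1"] * 4, "start": [50, 100, 300, 500], "end": [100, 200, 400, 600]}
    )
    mat = sp.csr_matrix(
        np.array(
            [
                [1, 0, 0],
                [1, 1, 0],
                [0, 1, 1],
                [1, 0, 1],
            ]
        )
    )
    return AccessibilityMatrix(peaks=peaks, cells=["c1", "c2", "c3"], matrix=mat)


@pytest.fixture
def tiny_gene_activity():
    genes = ["g1", "g2", "g3", "g4"]
    values = np.array(
        [
            [1.0, 0.0, 2.0],
            [1.0, 2.0, 0.0],
            [1.0, 1.0, 1.0],
            [1.0, 1.0, 1.0],
        ]
    )
    return GeneActivityMatrix(genes=genes, cells=["c1", "c2", "c3"], values=values)


@pytest.fixture
def tiny_markers():
    return MarkerTable(
        pd.DataFrame(
            {
                "cell_type": ["A", "A", "B"],
                "gene": ["g1", "g2", "g3"],
                "log_fc": [2.0, 1.0, 1.5],
            }
        )
    )
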