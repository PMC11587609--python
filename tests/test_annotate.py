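"""Threshold / collapse / dedupe rules and divergence calling."""

import numpy as np
import pytest

from celltreewalk.annotate import (
    AnnotationParams,
    DivergenceParams,
    RegionAnnotation,
    _max_compatible_set,
    collapse_parent_children,
    dedupe_ancestors,
    embed_scores,
    find_divergent_genes,
    threshold_labels,
)
from celltreewalk.hierarchy import balanced_binary_tree, parse_tree
from celltreewalk.regions import RegionLabelScores
from conftest import random_tree


def scores_with_z(tree, z, region_id="r", egene=None):
    z = np.asarray(z, dtype=float)
    return RegionLabelScores(
        region_id=region_id, n_cells=1, raw=np.abs(z), normalized=np.abs(z), z=z, egene=egene
    )


class TestThreshold:
    def test_strictly_greater(self, toy_tree):
        s = scores_with_z(toy_tree, [2.1, 2.0, 1.9, 0.0, -1.0])
        assert threshold_labels(s, toy_tree, AnnotationParams()) == {"A"}

    def test_all_below_gives_empty(self, toy_tree):
        s = scores_with_z(toy_tree, [2.0, 1.0, 0.0, 0.0, 0.0])
        assert threshold_labels(s, toy_tree, AnnotationParams()) == set()

    def test_lower_threshold_gives_superset(self, toy_tree):
        s = scores_with_z(toy_tree, [2.5, 1.5, 0.5, -0.5, 3.0])
        strict = threshold_labels(s, toy_tree, AnnotationParams(z_threshold=2))
        lenient = threshold_labels(s, toy_tree, AnnotationParams(z_threshold=1))
        assert strict <= lenient


class TestCollapse:
    def test_parent_with_both_children(self, toy_tree):
        assert collapse_parent_children({"A+B", "A", "B"}, toy_tree) == {"A+B"}

    def test_parent_with_one_child_unchanged(self, toy_tree):
        sig = {"A+B", "A"}
        assert collapse_parent_children(sig, toy_tree) == sig

    def test_multilevel_cascade(self):
        tree = parse_tree("((a,b),(c,d));")
        sig = {"a", "b", "c", "d", "a+b", "c+d", tree.root}
        assert collapse_parent_children(sig, tree) == {tree.root}

    def test_cascade_requires_parent_in_set(self):
        tree = parse_tree("((a,b),(c,d));")
        # root missing: each pair collapses to its parent, then stops
        assert collapse_parent_children({"a", "b", "c", "d", "a+b", "c+d"}, tree) == {"a+b", "c+d"}

    @pytest.mark.parametrize("seed", range(10))
    def test_idempotent_and_no_full_families_remain(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(n_leaves=int(rng.integers(2, 10)), seed=seed)
        nodes = list(tree.nodes)
        sig = {n for n in nodes if rng.random() < 0.5}
        out = collapse_parent_children(sig, tree)
        assert collapse_parent_children(out, tree) == out
        for node in tree.internal_nodes():
            kids = tree.children_of(node)
            assert not (node in out and kids and all(k in out for k in kids))


class TestDedupe:
    def test_examples(self, toy_tree):
        assert dedupe_ancestors({"A", toy_tree.root}, toy_tree) == {toy_tree.root}
        assert dedupe_ancestors({"A", "B"}, toy_tree) == {"A", "B"}
        assert dedupe_ancestors({"A", "A+B"}, toy_tree) == {"A+B"}

    @pytest.mark.parametrize("seed", range(10))
    def test_output_is_antichain(self, seed):
        rng = np.random.default_rng(100 + seed)
        tree = random_tree(n_leaves=int(rng.integers(2, 10)), seed=seed)
        labels = {n for n in tree.nodes if rng.random() < 0.6}
        out = dedupe_ancestors(labels, tree)
        assert out <= labels
        for a in out:
            for b in out:
                if a != b:
                    assert not tree.is_ancestor(a, b)
        # every removed label has a kept ancestor
        for dropped in labels - out:
            assert any(tree.is_ancestor(kept, dropped) for kept in out)


class TestEmbedding:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(0)
        mat = np.vstack([rng.normal(0, 1, (10, 5)), rng.normal(8, 1, (10, 5))])
        e1 = embed_scores(mat, seed=42)
        e2 = embed_scores(mat, seed=42)
        assert e1.shape == (20, 2)
        assert np.array_equal(e1, e2)

    def test_identical_vectors_land_together_and_clusters_separate(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.01, (8, 4))
        b = rng.normal(10, 0.01, (8, 4)) + 10
        emb = embed_scores(np.vstack([a, a[:1], b]), seed=0, n_neighbors=5)
        d_same = np.linalg.norm(emb[0] - emb[8])
        centroid_a, centroid_b = emb[:9].mean(axis=0), emb[9:].mean(axis=0)
        assert d_same < np.linalg.norm(centroid_a - centroid_b)

    def test_neighbor_autoshrink_warns(self):
        mat = np.random.default_rng(2).normal(size=(5, 3))
        with pytest.warns(UserWarning, match="n_neighbors"):
            emb = embed_scores(mat, seed=0)
        assert emb.shape == (5, 2)

    def test_too_few_regions(self):
        with pytest.raises(ValueError):
            embed_scores(np.zeros((2, 3)), seed=0)


class TestDivergence:
    @pytest.fixture
    def tree(self):
        return parse_tree("((a,b),(c,d));")

    def make_inputs(self, tree, labels1, labels2, score_dist, embed_dist):
        """Two regions of one gene with controlled distances."""
        z1 = np.zeros(tree.node_count)
        z2 = np.zeros(tree.node_count)
        z2[0] = score_dist  # exact Euclidean distance between z vectors
        scores = [
            RegionLabelScores("r1", 1, z1, z1, z=z1, egene="G"),
            RegionLabelScores("r2", 1, z2, z2, z=z2, egene="G"),
        ]
        annotations = [
            RegionAnnotation("r1", set(labels1), set(labels1), egene="G"),
            RegionAnnotation("r2", set(labels2), set(labels2), egene="G"),
        ]
        embedding = np.array([[0.0, 0.0], [embed_dist, 0.0]])
        return annotations, scores, embedding

    def test_all_three_rules_satisfied(self, tree):
        ann, sc, emb = self.make_inputs(tree, {"a"}, {"b"}, 50, 10)
        calls = find_divergent_genes(ann, sc, emb, tree, DivergenceParams())
        assert len(calls) == 1
        assert calls[0].egene == "G"
        assert calls[0].n_distinct_celltypes == 2
        (pair,) = calls[0].supporting_pairs
        assert pair[4] == pytest.approx(50) and pair[5] == pytest.approx(10)

    def test_ancestor_labels_never_divergent(self, tree):
        ann, sc, emb = self.make_inputs(tree, {"a"}, {"a+b"}, 500, 100)
        assert find_divergent_genes(ann, sc, emb, tree, DivergenceParams()) == []
        ann, sc, emb = self.make_inputs(tree, {"a"}, {"a"}, 500, 100)
        assert find_divergent_genes(ann, sc, emb, tree, DivergenceParams()) == []

    def test_score_distance_rule(self, tree):
        ann, sc, emb = self.make_inputs(tree, {"a"}, {"b"}, 30, 10)
        assert find_divergent_genes(ann, sc, emb, tree, DivergenceParams()) == []

    def test_embed_distance_rule(self, tree):
        ann, sc, emb = self.make_inputs(tree, {"a"}, {"b"}, 50, 7.9)
        assert find_divergent_genes(ann, sc, emb, tree, DivergenceParams()) == []

    def test_symmetric_in_region_order(self, tree):
        ann, sc, emb = self.make_inputs(tree, {"a"}, {"c"}, 50, 10)
        fwd = find_divergent_genes(ann, sc, emb, tree, DivergenceParams())
        rev = find_divergent_genes(ann[::-1], sc, emb, tree, DivergenceParams())
        assert fwd[0].egene == rev[0].egene
        assert fwd[0].n_distinct_celltypes == rev[0].n_distinct_celltypes

    def test_unannotated_regions_do_not_participate(self, tree):
        ann, sc, emb = self.make_inputs(tree, set(), {"b"}, 50, 10)
        assert find_divergent_genes(ann, sc, emb, tree, DivergenceParams()) == []


def test_max_compatible_set_counts_antichain():
    tree = balanced_binary_tree([f"L{i}" for i in range(8)])
    assert _max_compatible_set({"L0", "L1", "L2"}, tree) == 3
    assert _max_compatible_set({"L0", tree.parent_of["L0"]}, tree) == 1
    assert _max_compatible_set(set(), tree) == 0
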