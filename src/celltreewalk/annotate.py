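"""Discrete hierarchical annotation and detection of cell type-divergent genes.

Z-score vectors are turned into label sets by thresholding (z > 2 by
default), then pruned twice: a parent whose children are all themselves
significant absorbs them (bottom-up), and among remaining labels related by
ancestry only the least specific is kept.  A gene has cell type-divergent
regions when two of its regions carry labels that are distinct,
non-ancestral, and far apart both in label-score space and in a 2-D
embedding of the score vectors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .hierarchy import CellTypeTree
from .regions import RegionLabelScores


@dataclass(frozen=True)
class AnnotationParams:
    """z_threshold: specificity cutoff; 2 = high specificity, 1 = lenient."""

    z_threshold: float = 2.0

    def __post_init__(self):
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")


@dataclass(frozen=True)
class DivergenceParams:
    """Minimum distances for a region pair to count as cell type-divergent.

    ``score_distance_min`` applies to the full label-score vectors,
    ``embed_distance_min`` to the 2-D embedding; both must be exceeded (or
    met) by the same pair that passes the non-ancestry label rule.
    """

    score_distance_min: float = 40.0
    embed_distance_min: float = 8.0
    embed_seed: int = 0

    def __post_init__(self):
        if self.score_distance_min <= 0 or self.embed_distance_min <= 0:
            raise ValueError("distance minima must be positive")


@dataclass
class RegionAnnotation:
    region_id: str
    retained_labels: set[str]
    all_significant: set[str]
    egene: str | None = None


@dataclass
class DivergenceCall:
    egene: str
    supporting_pairs: list[tuple[str, str, str, str, float, float]]
    n_distinct_celltypes: int


def threshold_labels(
    scores: RegionLabelScores, tree: CellTypeTree, params: AnnotationParams
) -> set[str]:
    """Tree nodes whose z-score strictly exceeds the threshold."""
    if scores.z is None:
        raise ValueError("region has no z-scores")
    return {tree.nodes[j] for j in np.where(scores.z > params.z_threshold)[0]}


def collapse_parent_children(significant: set[str], tree: CellTypeTree) -> set[str]:
    """Bottom-up pruning: a significant parent absorbs its significant children.

    Whenever a parent and ALL of its children are significant, the children
    are removed; applied from the leaves up to the root until a fixed point.
    """
    kept = set(significant)
    changed = True
    while changed:
        changed = False
        # sweep internal nodes bottom-up (postorder: children precede parents)
        for node in tree.internal_nodes():
            if node not in kept:
                continue
            kids = tree.children_of(node)
            if kids and all(k in kept for k in kids):
                kept.difference_update(kids)
                changed = True
    return kept


def dedupe_ancestors(labels: set[str], tree: CellTypeTree) -> set[str]:
    """Keep only the least specific label of every ancestor-descendant pair.

    The result is an antichain of the tree's ancestry order.
    """
    return {
        a for a in labels
        if not any(tree.is_ancestor(b, a) for b in labels if b != a)
    }


def annotate_region(
    scores: RegionLabelScores, tree: CellTypeTree, params: AnnotationParams
) -> RegionAnnotation:
    """threshold -> parent-collapse -> ancestor-dedupe for one region."""
    significant = threshold_labels(scores, tree, params)
    retained = dedupe_ancestors(collapse_parent_children(significant, tree), tree)
    return RegionAnnotation(
        region_id=scores.region_id,
        retained_labels=retained,
        all_significant=significant,
        egene=scores.egene,
    )


def annotate_regions(
    scores: list[RegionLabelScores], tree: CellTypeTree, params: AnnotationParams | None = None
) -> list[RegionAnnotation]:
    params = params or AnnotationParams()
    return [annotate_region(s, tree, params) for s in scores]


def embed_scores(score_matrix: np.ndarray, seed: int = 0, n_neighbors: int = 15) -> np.ndarray:
    """2-D UMAP embedding of per-region label-score vectors.

    Deterministic for a fixed seed (single-threaded when seeded).  With fewer
    regions than ``n_neighbors`` the neighborhood size shrinks automatically
    with a warning.
    """
    import warnings

    n = score_matrix.shape[0]
    if n < 3:
        raise ValueError("embedding needs at least 3 regions")
    if n_neighbors >= n:
        warnings.warn(f"n_neighbors reduced from {n_neighbors} to {n - 1} for {n} regions")
        n_neighbors = n - 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that seeding disables parallelism
        import umap

        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors, random_state=seed)
        coords = reducer.fit_transform(score_matrix)
    return np.asarray(coords, dtype=float)


def _compatible(a: str, b: str, tree: CellTypeTree) -> bool:
    return a != b and not tree.is_ancestor(a, b) and not tree.is_ancestor(b, a)


def _max_compatible_set(labels: set[str], tree: CellTypeTree) -> int:
    """Size of the largest set of pairwise non-ancestral, distinct labels.

    Label sets in practice are tiny, so exhaustive subset search suffices.
    """
    labels = sorted(labels)
    best = 1 if labels else 0
    for r in range(2, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            if all(_compatible(a, b, tree) for a, b in itertools.combinations(combo, 2)):
                best = max(best, r)
    return best


def _score_vector(s: RegionLabelScores, vector: str) -> np.ndarray:
    if vector == "z":
        if s.z is None:
            raise ValueError(f"region {s.region_id} has no z-scores")
        return s.z
    if vector == "normalized":
        return s.normalized
    if vector == "compositional":
        total = s.raw.sum()
        return s.raw / total if total > 0 else s.raw
    raise ValueError(f"unknown score vector {vector!r}")


def find_divergent_genes(
    annotations: list[RegionAnnotation],
    scores: list[RegionLabelScores],
    embedding: np.ndarray,
    tree: CellTypeTree,
    params: DivergenceParams,
    vector: str = "z",
) -> list[DivergenceCall]:
    """Call genes whose regions map to divergent cell types.

    For each gene, every pair of annotated regions is tested against three
    rules that must all hold for the same pair: (i) the two regions carry
    labels that differ and are not ancestors of each other; (ii) the
    Euclidean distance between their full label-score vectors is at least
    ``score_distance_min``; (iii) the distance between their embedding
    coordinates is at least ``embed_distance_min``.  A gene with at least one
    supporting pair is called divergent.
    """
    score_by_id = {s.region_id: s for s in scores}
    row_by_id = {s.region_id: i for i, s in enumerate(scores)}
    by_gene: dict[str, list[RegionAnnotation]] = {}
    for ann in annotations:
        if ann.egene is not None and ann.retained_labels:
            by_gene.setdefault(ann.egene, []).append(ann)

    calls: list[DivergenceCall] = []
    for gene in sorted(by_gene):
        anns = sorted(by_gene[gene], key=lambda a: a.region_id)
        pairs: list[tuple[str, str, str, str, float, float]] = []
        divergent_labels: set[str] = set()
        for a1, a2 in itertools.combinations(anns, 2):
            s1, s2 = score_by_id[a1.region_id], score_by_id[a2.region_id]
            score_dist = float(np.linalg.norm(_score_vector(s1, vector) - _score_vector(s2, vector)))
            embed_dist = float(
                np.linalg.norm(embedding[row_by_id[a1.region_id]] - embedding[row_by_id[a2.region_id]])
            )
            if score_dist < params.score_distance_min or embed_dist < params.embed_distance_min:
                continue
            label_pair = None
            for l1 in sorted(a1.retained_labels):
                for l2 in sorted(a2.retained_labels):
                    if _compatible(l1, l2, tree):
                        label_pair = (l1, l2)
                        break
                if label_pair:
                    break
            if label_pair is None:
                continue
            pairs.append((a1.region_id, label_pair[0], a2.region_id, label_pair[1], score_dist, embed_dist))
            divergent_labels.update(label_pair)
        if pairs:
            calls.append(
                DivergenceCall(
                    egene=gene,
                    supporting_pairs=pairs,
                    n_distinct_celltypes=_max_compatible_set(divergent_labels, tree),
                )
            )
    return calls


def _bimodal_split(distances: np.ndarray) -> float:
    """Geometric midpoint between the two modes of a distance distribution.

    One-dimensional two-means on log distances, initialized at the extremes
    (deterministic); the threshold is the geometric mean of the two cluster
    centers.  Distances of (near-)zero are floored to the smallest positive
    value observed.
    """
    d = np.asarray(distances, dtype=float)
    positive = d[d > 0]
    if positive.size == 0:
        raise ValueError("all pairwise distances are zero; cannot calibrate")
    x = np.log(np.where(d > 0, d, positive.min()))
    lo, hi = x.min(), x.max()
    if np.isclose(lo, hi):
        return float(np.exp(lo))
    c = np.array([lo, hi])
    for _ in range(100):
        assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
        new = np.array([x[assign == k].mean() if (assign == k).any() else c[k] for k in (0, 1)])
        if np.allclose(new, c):
            break
        c = new
    return float(np.exp(c.mean()))


def suggest_divergence_params(
    annotations: list[RegionAnnotation],
    scores: list[RegionLabelScores],
    embedding: np.ndarray,
    embed_seed: int = 0,
    vector: str = "compositional",
) -> DivergenceParams:
    """Calibrate the divergence distance cutoffs to the data at hand.

    The fixed defaults encode "these two regions do not correspond to similar
    cell types" on a particular data scale; score-vector magnitudes and
    embedding layouts vary with dataset size, so the cutoffs must move with
    them.  Pairwise distances among annotated regions are strongly bimodal:
    a tight mode of same-cell-type pairs and a broad mode of everything else.
    Each cutoff is set at the geometric midpoint between the two modes, for
    both the score-vector distances and the embedding distances.
    """
    row_by_id = {s.region_id: i for i, s in enumerate(scores)}
    vec_by_id = {s.region_id: _score_vector(s, vector) for s in scores}
    ids = sorted(a.region_id for a in annotations if a.retained_labels)
    if len(ids) < 2:
        raise ValueError("need at least two annotated regions to calibrate")
    score_d, embed_d = [], []
    for r1, r2 in itertools.combinations(ids, 2):
        score_d.append(float(np.linalg.norm(vec_by_id[r1] - vec_by_id[r2])))
        embed_d.append(float(np.linalg.norm(embedding[row_by_id[r1]] - embedding[row_by_id[r2]])))
    return DivergenceParams(
        score_distance_min=_bimodal_split(np.array(score_d)),
        embed_distance_min=_bimodal_split(np.array(embed_d)),
        embed_seed=embed_seed,
    )
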