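"""End-to-end composition: graph -> diffusion -> region scoring -> annotation.

``run_analysis`` is the in-memory pipeline used programmatically and by the
tests; ``run_pipeline`` wraps it with file reading/writing and provenance
headers for the command line.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import (
    AnnotationParams,
    DivergenceCall,
    DivergenceParams,
    RegionAnnotation,
    annotate_regions,
    embed_scores,
    find_divergent_genes,
    suggest_divergence_params,
)
from .diffusion import WalkParams, extract_cell_to_label_block, solve_influence
from .hierarchy import CellTypeTree
from .io import InputValidationError, RunConfig
from .network import (
    AccessibilityMatrix,
    GeneActivityMatrix,
    MarkerTable,
    assemble_graph,
    compute_cell_similarity,
    compute_label_edges,
    edge_weight_grid,
    tune_edge_weight,
)
from .regions import (
    BulkRegion,
    RegionLabelScores,
    overlap_regions_with_cells,
    score_regions,
    scores_to_frame,
    z_matrix,
    zscore_regions,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    tree: CellTypeTree
    label_edge_weight: float
    tune_table: pd.DataFrame | None
    scores: list[RegionLabelScores]
    unscoreable: list[str]
    annotations: list[RegionAnnotation]
    embedding: np.ndarray | None
    divergence_params: DivergenceParams | None
    divergence_calls: list[DivergenceCall]

    def annotated(self) -> list[RegionAnnotation]:
        return [a for a in self.annotations if a.retained_labels]


@dataclass
class InMemoryInputs:
    tree: CellTypeTree
    accessibility: AccessibilityMatrix
    gene_activity: GeneActivityMatrix
    markers: MarkerTable
    regions: list[BulkRegion]


def validate_inputs(inputs: InMemoryInputs) -> None:
    """Cross-file consistency; reports every problem at once."""
    problems: list[str] = []
    if inputs.gene_activity.cells != inputs.accessibility.cells:
        problems.append("cell barcodes differ between accessibility and gene activity matrices")
    marker_types = set(inputs.markers.cell_types())
    leaves = set(inputs.tree.leaf_names)
    if marker_types - leaves:
        problems.append(f"marker cell types not in tree leaves: {sorted(marker_types - leaves)[:5]}")
    if leaves - marker_types:
        problems.append(f"tree leaves without markers: {sorted(leaves - marker_types)[:5]}")
    region_chroms = {r.chrom for r in inputs.regions}
    peak_chroms = set(inputs.accessibility.peaks["chrom"].unique())
    if inputs.regions and not region_chroms & peak_chroms:
        problems.append(
            f"no shared chromosomes between eQTL regions {sorted(region_chroms)[:3]} "
            f"and peaks {sorted(peak_chroms)[:3]}"
        )
    if problems:
        raise InputValidationError(problems)


def run_analysis(
    inputs: InMemoryInputs,
    alpha: float = 0.5,
    label_edge_weight: float = 100.0,
    tune_steps: int = 0,
    z_threshold: float = 2.0,
    z_mode: str = "across_regions",
    z_normalization: str = "compositional",
    divergence_params: DivergenceParams | None = None,
    divergence_calibration: str = "fixed",
    divergence_vector: str = "compositional",
    seed: int = 0,
    similarity_metric: str = "jaccard",
) -> AnalysisResult:
    """Run the full analysis on in-memory inputs.

    ``tune_steps`` > 0 grid-searches the label-edge weight first;
    ``divergence_calibration='calibrated'`` replaces the fixed distance
    cutoffs with quantiles of the same-label pair distances (appropriate when
    the score scale differs from the defaults' provenance).
    """
    validate_inputs(inputs)
    walk = WalkParams(alpha=alpha)
    t0 = time.time()
    cellsim = compute_cell_similarity(inputs.accessibility, metric=similarity_metric)
    label_edges, label_order = compute_label_edges(inputs.gene_activity, inputs.markers)
    logger.info("edges built in %.1fs (%d cells)", time.time() - t0, len(inputs.accessibility.cells))

    tune_table = None
    if tune_steps > 0:
        label_edge_weight, tune_table = tune_edge_weight(
            inputs.tree, cellsim, label_edges, label_order, inputs.accessibility.cells,
            grid=edge_weight_grid(tune_steps), walk_params=walk,
        )
        logger.info("tuned label edge weight: %g", label_edge_weight)

    graph = assemble_graph(
        inputs.tree, cellsim, label_edges, label_order, inputs.accessibility.cells,
        label_edge_weight,
    )
    influence = solve_influence(graph, walk)
    block = extract_cell_to_label_block(influence, inputs.tree)

    cell_map = overlap_regions_with_cells(inputs.regions, inputs.accessibility)
    scores, unscoreable = score_regions(inputs.regions, cell_map, block, inputs.tree)
    logger.info("scored %d regions (%d unscoreable)", len(scores), len(unscoreable))
    zscore_regions(scores, mode=z_mode, cell_to_label=block, seed=seed,
                   normalization=z_normalization)

    annotations = annotate_regions(scores, inputs.tree, AnnotationParams(z_threshold=z_threshold))

    embedding = None
    div_params = divergence_params
    calls: list[DivergenceCall] = []
    if len(scores) >= 3:
        zmat, _ = z_matrix(scores)
        embedding = embed_scores(zmat, seed=seed)
        if div_params is None:
            if divergence_calibration == "calibrated":
                div_params = suggest_divergence_params(
                    annotations, scores, embedding, embed_seed=seed, vector=divergence_vector,
                )
                logger.info(
                    "calibrated divergence cutoffs: score >= %.3g, embedding >= %.3g",
                    div_params.score_distance_min, div_params.embed_distance_min,
                )
            else:
                div_params = DivergenceParams(embed_seed=seed)
        calls = find_divergent_genes(annotations, scores, embedding, inputs.tree, div_params,
                                     vector=divergence_vector)
    logger.info("%d annotated regions, %d divergent genes",
                sum(bool(a.retained_labels) for a in annotations), len(calls))

    return AnalysisResult(
        tree=inputs.tree,
        label_edge_weight=label_edge_weight,
        tune_table=tune_table,
        scores=scores,
        unscoreable=unscoreable,
        annotations=annotations,
        embedding=embedding,
        divergence_params=div_params,
        divergence_calls=calls,
    )


def read_inputs(config: RunConfig) -> InMemoryInputs:
    """Load and cross-validate all pipeline inputs from disk."""
    from . import io

    problems: list[str] = []
    for label, path in [
        ("gene_activity", config.gene_activity),
        ("markers", config.markers),
        ("tree", config.tree),
        ("eqtls", config.eqtls),
    ]:
        if not path or not Path(path).exists():
            problems.append(f"missing input file for {label}: {path!r}")
    if not config.atac_dir or not Path(config.atac_dir).exists():
        problems.append(f"missing accessibility directory: {config.atac_dir!r}")
    if problems:
        raise InputValidationError(problems)

    inputs = InMemoryInputs(
        tree=io.read_tree(config.tree),
        accessibility=io.read_accessibility(config.atac_dir, config.atac_prefix),
        gene_activity=io.read_gene_activity(config.gene_activity),
        markers=io.read_markers(config.markers),
        regions=io.read_regions(config.eqtls, one_based_pos=config.one_based_pos),
    )
    validate_inputs(inputs)
    return inputs


def run_pipeline(config: RunConfig) -> Path:
    """File-based pipeline: read inputs, analyse, write result tables.

    Writes scores.tsv (long format), annotations.tsv, unscoreable.tsv,
    divergence.tsv, embedding.tsv and, when tuning ran, tuning.tsv, each with
    a provenance header.  Returns the output directory.
    """
    from . import io

    inputs = read_inputs(config)
    result = run_analysis(
        inputs,
        alpha=config.alpha,
        label_edge_weight=config.label_edge_weight,
        tune_steps=config.tune_steps,
        z_threshold=config.z_threshold,
        z_mode=config.z_mode,
        z_normalization=config.z_normalization,
        divergence_params=None if config.divergence_calibration == "calibrated" else DivergenceParams(
            score_distance_min=config.score_distance_min,
            embed_distance_min=config.embed_distance_min,
            embed_seed=config.seed,
        ),
        divergence_calibration=config.divergence_calibration,
        seed=config.seed,
        similarity_metric=config.similarity_metric,
    )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    seeds = {"run": config.seed}

    io.write_table(scores_to_frame(result.scores, result.tree), outdir / "scores.tsv", chash, seeds)
    io.write_table(
        pd.DataFrame({"region_id": result.unscoreable}), outdir / "unscoreable.tsv", chash, seeds
    )
    ann = pd.DataFrame(
        {
            "region_id": [a.region_id for a in result.annotations],
            "egene": [a.egene for a in result.annotations],
            "retained_labels": [";".join(sorted(a.retained_labels)) for a in result.annotations],
            "all_significant": [";".join(sorted(a.all_significant)) for a in result.annotations],
        }
    )
    io.write_table(ann, outdir / "annotations.tsv", chash, seeds)
    import json as _json

    div = pd.DataFrame(
        {
            "egene": [c.egene for c in result.divergence_calls],
            "n_distinct_celltypes": [c.n_distinct_celltypes for c in result.divergence_calls],
            "supporting_pairs": [_json.dumps(c.supporting_pairs) for c in result.divergence_calls],
        }
    )
    io.write_table(div, outdir / "divergence.tsv", chash, seeds)
    if result.embedding is not None:
        emb = pd.DataFrame(result.embedding, columns=["umap1", "umap2"])
        emb.insert(0, "region_id", [s.region_id for s in result.scores])
        io.write_table(emb, outdir / "embedding.tsv", chash, seeds)
    if result.tune_table is not None:
        io.write_table(result.tune_table, outdir / "tuning.tsv", chash, seeds)
    return outdir
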