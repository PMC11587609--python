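"""Multiome validation: does eQTL-SNP accessibility track target-gene expression?

Cells measured with joint RNA + ATAC are assigned to an eQTL when its SNP is
accessible in the cell and no other SNP of the same gene is; the gene's
expression in assigned cells is then compared to cells assigned to none of
the gene's eQTLs with a two-tailed Wilcoxon rank-sum test, Benjamini-Hochberg
corrected across the batch.  Cell-type enrichment ratios use externally
provided per-cell annotations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import AccessibilityMatrix
from .regions import BulkRegion, overlap_regions_with_cells

logger = logging.getLogger(__name__)

# exact rank-sum enumeration up to this per-group size; normal approximation above
_EXACT_MAX_N = 8


@dataclass
class MultiomeData:
    """Joint expression + accessibility over the same cells, with external labels."""

    expression: pd.DataFrame  # genes x cells, raw counts
    accessibility: AccessibilityMatrix
    cell_annotations: dict[str, str]

    def __post_init__(self):
        if list(self.expression.columns) != list(self.accessibility.cells):
            raise ValueError("expression and accessibility must share cell barcodes in order")
        missing = [c for c in self.accessibility.cells if c not in self.cell_annotations]
        if missing:
            raise ValueError(f"cells without annotation: {missing[:5]}")


@dataclass
class EqtlExpressionTest:
    region_id: str
    egene: str
    n_assigned: int
    n_background: int
    log_fold_change: float
    p_value: float
    fdr: float = float("nan")


def assign_cells_by_unique_accessibility(
    regions: list[BulkRegion], acc: AccessibilityMatrix
) -> dict[str, set[int]]:
    """Assign cells to each eQTL by exclusive SNP accessibility.

    A cell belongs to region r iff r's SNP is accessible in it and no other
    SNP of the same gene is; assignments for SNPs of one gene are therefore
    disjoint.  Genes with a single SNP reduce to plain accessibility.
    """
    overlap = overlap_regions_with_cells(regions, acc)
    by_gene: dict[str | None, list[BulkRegion]] = {}
    for r in regions:
        by_gene.setdefault(r.egene, []).append(r)

    out: dict[str, set[int]] = {}
    for gene_regions in by_gene.values():
        for r in gene_regions:
            others: set[int] = set()
            for o in gene_regions:
                if o.region_id != r.region_id:
                    others |= overlap[o.region_id]
            out[r.region_id] = overlap[r.region_id] - others
    return out


def rank_sum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-tailed Wilcoxon rank-sum p-value.

    Exact by enumeration of all rank assignments (mid-ranks for ties) when
    both groups have at most 8 observations; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if n1 <= _EXACT_MAX_N and n2 <= _EXACT_MAX_N:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)  # mid-ranks for ties
        observed = ranks[:n1].sum()
        null_mean = n1 * (n1 + n2 + 1) / 2.0
        obs_dev = abs(observed - null_mean)
        count = total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            w = ranks[list(combo)].sum()
            total += 1
            if abs(w - null_mean) >= obs_dev - 1e-9:
                count += 1
        return count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def test_differential_expression(
    assignments: dict[str, set[int]],
    region_gene: dict[str, str],
    multiome: MultiomeData,
    fdr_method: str = "fdr_bh",
    pseudocount: float = 1.0,
) -> list[EqtlExpressionTest]:
    """Per-eQTL expression test of the target gene.

    Assigned cells are compared against the gene's background: cells assigned
    to none of that gene's eQTLs.  Log2 fold change of mean expression uses a
    pseudocount; p-values are rank-sum, corrected across the whole batch.
    """
    expr = multiome.expression
    n_cells = expr.shape[1]
    by_gene: dict[str, list[str]] = {}
    for rid, gene in region_gene.items():
        by_gene.setdefault(gene, []).append(rid)

    tests: list[EqtlExpressionTest] = []
    for gene in sorted(by_gene):
        if gene not in expr.index:
            logger.warning("eGene %s absent from expression matrix; skipped", gene)
            continue
        values = expr.loc[gene].to_numpy(dtype=float)
        assigned_any: set[int] = set()
        for rid in by_gene[gene]:
            assigned_any |= assignments.get(rid, set())
        background = sorted(set(range(n_cells)) - assigned_any)
        for rid in sorted(by_gene[gene]):
            cells = sorted(assignments.get(rid, set()))
            if not cells:
                continue
            if not background:
                logger.warning("region %s: empty background, test skipped", rid)
                continue
            a, b = values[cells], values[background]
            lfc = math.log2((a.mean() + pseudocount) / (b.mean() + pseudocount))
            p = rank_sum_pvalue(a, b)
            tests.append(
                EqtlExpressionTest(
                    region_id=rid, egene=gene, n_assigned=len(cells),
                    n_background=len(background), log_fold_change=lfc, p_value=p,
                )
            )
    if tests:
        fdrs = multipletests([t.p_value for t in tests], method=fdr_method)[1]
        for t, q in zip(tests, fdrs):
            t.fdr = float(q)
    return tests


def celltype_enrichment(
    assignment: set[int],
    background: set[int],
    cell_annotations: list[str],
    celltype: str,
) -> float:
    """Ratio of the cell type's share among assigned vs background cells.

    Values above 1 mean the assigned cells are enriched for the type.  An
    all-of-type background with no assigned counterpart yields ``inf``.
    """
    if not assignment or not background:
        raise ValueError("both assignment and background must be non-empty")
    frac_assigned = sum(cell_annotations[i] == celltype for i in assignment) / len(assignment)
    frac_background = sum(cell_annotations[i] == celltype for i in background) / len(background)
    if frac_background == 0:
        return math.inf if frac_assigned > 0 else 0.0
    return frac_assigned / frac_background


def filter_high_expression(expression: pd.DataFrame, min_reads: int = 100) -> set[str]:
    """Genes with at least ``min_reads`` total counts across all cells."""
    totals = expression.sum(axis=1)
    return set(totals.index[totals >= min_reads])
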