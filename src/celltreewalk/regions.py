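"""Scoring bulk genomic regions (eQTL SNPs) against the cell-type hierarchy.

A region is scored through the cells in which it is accessible: the influence
(walk-termination probability) from each such cell to every tree node is
summed, normalized by the number of contributing cells, and standardized
across regions to a per-node z-score.  Regions accessible in no cell are
unscoreable and reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hierarchy import CellTypeTree
from .network import AccessibilityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BulkRegion:
    """A genomic interval (0-based half-open) with an optional associated gene.

    An eQTL SNP is a width-1 interval; ``egene`` carries the gene whose
    expression the variant is associated with (metadata only at this stage).
    """

    region_id: str
    chrom: str
    start: int
    end: int
    egene: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"region {self.region_id}: start must be < end")


@dataclass
class RegionLabelScores:
    """Raw, normalized, and z-scored label values for one region."""

    region_id: str
    n_cells: int
    raw: np.ndarray
    normalized: np.ndarray
    z: np.ndarray | None = None
    egene: str | None = None


def regions_from_frame(df: pd.DataFrame, one_based_pos: bool = False) -> list[BulkRegion]:
    """Build regions from a table with region_id/chrom and either start,end or pos.

    With ``one_based_pos`` a 1-based SNP position column ``pos`` is converted
    to the half-open interval [pos-1, pos).
    """
    regions = []
    for _, row in df.iterrows():
        if "pos" in df.columns and ("start" not in df.columns or pd.isna(row.get("start"))):
            pos = int(row["pos"])
            start, end = (pos - 1, pos) if one_based_pos else (pos, pos + 1)
        else:
            start, end = int(row["start"]), int(row["end"])
        regions.append(
            BulkRegion(
                region_id=str(row["region_id"]),
                chrom=str(row["chrom"]),
                start=start,
                end=end,
                egene=str(row["egene"]) if "egene" in df.columns and pd.notna(row["egene"]) else None,
            )
        )
    if len({r.region_id for r in regions}) != len(regions):
        raise ValueError("region_id values must be unique")
    return regions


def overlap_regions_with_cells(
    regions: list[BulkRegion], acc: AccessibilityMatrix
) -> dict[str, set[int]]:
    """Map each region to the set of cell indices in which it is accessible.

    A cell qualifies iff at least one of its accessible peaks intersects the
    region (half-open interval semantics).  Chromosome naming must agree
    between the two inputs.
    """
    import pyranges as pr

    if not regions:
        return {}
    region_chroms = {r.chrom for r in regions}
    peak_chroms = set(acc.peaks["chrom"].unique())
    if not region_chroms & peak_chroms:
        raise ValueError(
            f"no shared chromosome names between regions ({sorted(region_chroms)[:5]}) "
            f"and peaks ({sorted(peak_chroms)[:5]}); check naming convention"
        )

    reg_df = pd.DataFrame(
        {
            "Chromosome": [r.chrom for r in regions],
            "Start": [r.start for r in regions],
            "End": [r.end for r in regions],
            "region_id": [r.region_id for r in regions],
        }
    )
    peak_df = acc.peaks.rename(columns={"chrom": "Chromosome", "start": "Start", "end": "End"}).copy()
    peak_df["peak_idx"] = np.arange(len(peak_df))
    hits = pr.PyRanges(reg_df).join(pr.PyRanges(peak_df[["Chromosome", "Start", "End", "peak_idx"]])).df

    out: dict[str, set[int]] = {r.region_id: set() for r in regions}
    if hits.empty:
        logger.warning("no region overlaps any accessible peak")
        return {rid: cells for rid, cells in out.items()}
    csc = acc.matrix.tocsc()
    csr = acc.matrix.tocsr()
    for rid, grp in hits.groupby("region_id"):
        cells: set[int] = set()
        for p in grp["peak_idx"]:
            row = csr.indices[csr.indptr[p]: csr.indptr[p + 1]]
            cells.update(int(i) for i in row)
        out[str(rid)] = cells
    return out


def score_regions(
    regions: list[BulkRegion],
    cell_map: dict[str, set[int]],
    cell_to_label: np.ndarray,
    tree: CellTypeTree,
) -> tuple[list[RegionLabelScores], list[str]]:
    """Sum cell-to-label influence over each region's accessible cells.

    ``cell_to_label`` is the (n_cells x node_count) block of the influence
    matrix.  Returns (scored regions, ids of unscoreable regions that overlap
    no accessible cell).
    """
    if cell_to_label.shape[1] != tree.node_count:
        raise ValueError("cell-to-label block width must equal the tree node count")
    scored: list[RegionLabelScores] = []
    unscoreable: list[str] = []
    for region in regions:
        cells = cell_map.get(region.region_id, set())
        if not cells:
            unscoreable.append(region.region_id)
            continue
        idx = sorted(cells)
        raw = cell_to_label[idx].sum(axis=0)
        scored.append(
            RegionLabelScores(
                region_id=region.region_id,
                n_cells=len(idx),
                raw=raw,
                normalized=raw / len(idx),
                egene=region.egene,
            )
        )
    return scored, unscoreable


def _region_vector(raw: np.ndarray, n_cells: int, normalization: str) -> np.ndarray:
    if normalization == "per_cell":
        return raw / n_cells
    if normalization == "compositional":
        total = raw.sum()
        return raw / total if total > 0 else raw
    raise ValueError(f"unknown normalization {normalization!r}")


def zscore_regions(
    scores: list[RegionLabelScores],
    mode: str = "across_regions",
    cell_to_label: np.ndarray | None = None,
    n_permutations: int = 200,
    seed: int = 0,
    normalization: str = "per_cell",
) -> list[RegionLabelScores]:
    """Fill the z-score vectors of scored regions (in place; also returned).

    ``across_regions`` (default): each tree-node column of the normalized
    score matrix is standardized over regions (sample sd).  ``permutation``:
    each region's normalized scores are compared against a null of random
    cell subsets of the same size drawn from all cells (requires
    ``cell_to_label``).  Zero-variance columns get z = 0 with a warning.

    ``normalization`` selects the vector that is standardized: ``per_cell``
    divides summed flow by the number of contributing cells; ``compositional``
    divides by the total tree flow, scoring where the flow goes rather than
    how much of it there is, which suppresses spurious root-level labels
    driven by per-type differences in overall label connectivity.
    """
    if not scores:
        return scores
    if mode == "across_regions":
        if len(scores) < 2:
            raise ValueError("across_regions z-scoring needs at least 2 scored regions")
        mat = np.vstack([_region_vector(s.raw, s.n_cells, normalization) for s in scores])
        mean = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=1)
        # near-constant columns (an order of magnitude less relative variation
        # than typical) carry no annotation signal; standardizing them would
        # manufacture significance from numerical noise, so they are treated
        # like zero-variance columns
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), 0.0)
        positive = cv[cv > 0]
        cv_floor = 0.1 * np.median(positive) if positive.size else 0.0
        flat = np.where((sd == 0) | (cv < cv_floor))[0]
        if flat.size:
            logger.warning("near-constant node columns (z set to 0): %s", flat.tolist())
        safe = sd.copy()
        safe[flat] = 1.0
        z = (mat - mean) / safe
        z[:, flat] = 0.0
        for s, zrow in zip(scores, z):
            s.z = zrow
    elif mode == "permutation":
        if cell_to_label is None:
            raise ValueError("permutation mode requires the cell-to-label block")
        rng = np.random.default_rng(seed)
        n_cells = cell_to_label.shape[0]
        for s in scores:
            draws = np.empty((n_permutations, cell_to_label.shape[1]))
            for k in range(n_permutations):
                pick = rng.choice(n_cells, size=s.n_cells, replace=False)
                draws[k] = _region_vector(cell_to_label[pick].sum(axis=0), s.n_cells, normalization)
            mu, sd = draws.mean(axis=0), draws.std(axis=0, ddof=1)
            flat = sd == 0
            if flat.any():
                logger.warning("region %s: zero-variance null columns", s.region_id)
            safe = np.where(flat, 1.0, sd)
            z = (_region_vector(s.raw, s.n_cells, normalization) - mu) / safe
            z[flat] = 0.0
            s.z = z
    else:
        raise ValueError(f"unknown z-score mode {mode!r}")
    return scores


def scores_to_frame(scores: list[RegionLabelScores], tree: CellTypeTree) -> pd.DataFrame:
    """Long-format table: one row per region x tree node."""
    rows = []
    for s in scores:
        for j, node in enumerate(tree.nodes):
            rows.append(
                {
                    "region_id": s.region_id,
                    "egene": s.egene,
                    "node": node,
                    "n_cells": s.n_cells,
                    "raw": s.raw[j],
                    "normalized": s.normalized[j],
                    "z": s.z[j] if s.z is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)


def z_matrix(scores: list[RegionLabelScores]) -> tuple[np.ndarray, list[str]]:
    """Stack per-region z vectors into a (regions x nodes) matrix."""
    if any(s.z is None for s in scores):
        raise ValueError("z-scores not computed; call zscore_regions first")
    return np.vstack([s.z for s in scores]), [s.region_id for s in scores]
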