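"""Readers and writers for the on-disk formats the pipeline consumes and emits.

Accessibility travels as an MTX triplet with BED peaks and a barcode list;
markers, gene activity, eQTLs and all results are TSV; trees are Newick or a
small JSON dialect; planted truth is JSON.  Every result table carries a
header block recording the tool version, a hash of the run configuration,
and the seeds involved, so outputs are replayable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import __version__
from .hierarchy import CellTypeTree, parse_tree
from .network import AccessibilityMatrix, GeneActivityMatrix, MarkerTable
from .regions import BulkRegion, regions_from_frame


class InputValidationError(ValueError):
    """Aggregates every cross-file inconsistency found during loading."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("input validation failed:\n  - " + "\n  - ".join(problems))


# ---------------------------------------------------------------------------
# accessibility


def write_accessibility(acc: AccessibilityMatrix, outdir: str | Path, prefix: str = "atac") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / f"{prefix}.mtx"), acc.matrix.tocoo())
    acc.peaks[["chrom", "start", "end"]].to_csv(
        outdir / f"{prefix}_peaks.bed", sep="\t", header=False, index=False
    )
    pd.Series(acc.cells).to_csv(outdir / f"{prefix}_barcodes.tsv", header=False, index=False)


def read_accessibility(outdir: str | Path, prefix: str = "atac") -> AccessibilityMatrix:
    outdir = Path(outdir)
    matrix = sp.csr_matrix(scipy.io.mmread(str(outdir / f"{prefix}.mtx")))
    peaks = pd.read_csv(
        outdir / f"{prefix}_peaks.bed", sep="\t", header=None, names=["chrom", "start", "end"]
    )
    cells = pd.read_csv(outdir / f"{prefix}_barcodes.tsv", header=None)[0].astype(str).tolist()
    return AccessibilityMatrix(peaks=peaks, cells=cells, matrix=matrix)


# ---------------------------------------------------------------------------
# gene activity, markers, eQTLs, tree


def write_gene_activity(gact: GeneActivityMatrix, path: str | Path) -> None:
    pd.DataFrame(gact.values, index=gact.genes, columns=gact.cells).to_csv(path, sep="\t")


def read_gene_activity(path: str | Path) -> GeneActivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GeneActivityMatrix(
        genes=df.index.astype(str).tolist(),
        cells=df.columns.astype(str).tolist(),
        values=df.to_numpy(dtype=float),
    )


def write_markers(markers: MarkerTable, path: str | Path) -> None:
    markers.table.to_csv(path, sep="\t", index=False)


def read_markers(path: str | Path) -> MarkerTable:
    return MarkerTable(pd.read_csv(path, sep="\t"))


def write_regions(regions: list[BulkRegion], path: str | Path) -> None:
    pd.DataFrame(
        {
            "region_id": [r.region_id for r in regions],
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "egene": [r.egene for r in regions],
        }
    ).to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path, one_based_pos: bool = False) -> list[BulkRegion]:
    return regions_from_frame(pd.read_csv(path, sep="\t"), one_based_pos=one_based_pos)


def _needs_quoting(name: str) -> bool:
    return any(ch in name for ch in "(),:;'[] \t")


def tree_to_newick(tree: CellTypeTree) -> str:
    def fmt(name: str) -> str:
        return "'" + name.replace("'", "''") + "'" if _needs_quoting(name) else name

    def render(node: str) -> str:
        kids = tree.children_of(node)
        if not kids:
            return fmt(node)
        return "(" + ",".join(render(k) for k in kids) + ")" + fmt(node)

    return render(tree.root) + ";"


def tree_to_json(tree: CellTypeTree) -> str:
    def build(node: str) -> dict:
        kids = tree.children_of(node)
        if not kids:
            return {"name": node}
        return {"name": node, "children": [build(k) for k in kids]}

    return json.dumps(build(tree.root), indent=1)


def write_tree(tree: CellTypeTree, path: str | Path) -> None:
    path = Path(path)
    text = tree_to_json(tree) if path.suffix == ".json" else tree_to_newick(tree)
    path.write_text(text + "\n")


def read_tree(path: str | Path) -> CellTypeTree:
    return parse_tree(Path(path).read_text())


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Flat run configuration; every defaulted field is echoed to the run log."""

    atac_dir: str = ""
    atac_prefix: str = "atac"
    gene_activity: str = ""
    markers: str = ""
    tree: str = ""
    eqtls: str = ""
    outdir: str = "celltreewalk_out"
    one_based_pos: bool = False
    alpha: float = 0.5
    label_edge_weight: float = 100.0
    tune_steps: int = 0  # 0 = use the fixed label_edge_weight
    z_threshold: float = 2.0
    z_mode: str = "across_regions"
    z_normalization: str = "compositional"  # compositional | per_cell
    score_distance_min: float = 40.0
    embed_distance_min: float = 8.0
    divergence_calibration: str = "fixed"  # fixed | calibrated
    seed: int = 0
    similarity_metric: str = "jaccard"

    @staticmethod
    def from_file(path: str | Path, **overrides) -> "RunConfig":
        """Parse a flat ``key = value`` text file, applying CLI overrides."""
        values: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
        values.update({k: v for k, v in overrides.items() if v is not None})
        kwargs = {}
        for f in fields(RunConfig):
            if f.name in values:
                raw = values.pop(f.name)
                if f.type == "bool":
                    kwargs[f.name] = str(raw).lower() in ("1", "true", "yes")
                elif f.type in ("int", "float"):
                    kwargs[f.name] = (int if f.type == "int" else float)(raw)
                else:
                    kwargs[f.name] = raw
        if values:
            raise ValueError(f"unknown config keys: {sorted(values)}")
        return RunConfig(**kwargs)

    def hash(self) -> str:
        payload = json.dumps({f.name: getattr(self, f.name) for f in fields(self)}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# result tables with provenance headers


def result_header(config_hash: str, seeds: dict[str, int]) -> str:
    lines = [
        f"# celltreewalk {__version__}",
        f"# config_hash {config_hash}",
    ]
    for name, value in sorted(seeds.items()):
        lines.append(f"# seed {name}={value}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str, seeds: dict[str, int]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(result_header(config_hash, seeds))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
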