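"""Plain-text readers/writers for the standard interchange formats.

Counts travel as Matrix Market (MTX) plus row/column name files,
metadata and interval tables as TSV, summits as narrowPeak (summit
offset in column 10), trees as Newick with a JSON sidecar of node
statistics, truth structures as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from crosstax.taxonomy import CellExpression, TaxonomyTree

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score_int", "strand",
    "signalValue", "pValue", "qValue", "peak",
]


def write_counts_mtx(path_prefix, counts, cell_ids, gene_ids) -> None:
    """Write counts as <prefix>.mtx with .rows / .cols name files."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(np.asarray(counts))
    spio.mmwrite(str(prefix) + ".mtx", mat)
    Path(str(prefix) + ".rows").write_text("\n".join(map(str, cell_ids)) + "\n")
    Path(str(prefix) + ".cols").write_text("\n".join(map(str, gene_ids)) + "\n")


def read_counts_mtx(path_prefix) -> tuple[np.ndarray, list, list]:
    prefix = str(path_prefix)
    mat = spio.mmread(prefix + ".mtx").toarray()
    rows = Path(prefix + ".rows").read_text().splitlines()
    cols = Path(prefix + ".cols").read_text().splitlines()
    return mat, rows, cols


def write_cell_expression(outdir, expr: CellExpression, prefix: str = "counts") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cell_ids = [f"cell{i:06d}" for i in range(expr.n_cells)]
    write_counts_mtx(outdir / prefix, expr.counts, cell_ids, expr.gene_ids)
    meta = expr.obs.copy()
    meta.insert(0, "cell_id", cell_ids)
    meta.to_csv(outdir / f"{prefix}_obs.tsv", sep="\t", index=False)


def read_cell_expression(outdir, prefix: str = "counts") -> CellExpression:
    outdir = Path(outdir)
    counts, _, gene_ids = read_counts_mtx(outdir / prefix)
    obs = pd.read_csv(outdir / f"{prefix}_obs.tsv", sep="\t").drop(columns=["cell_id"])
    return CellExpression(counts=np.asarray(counts), obs=obs, gene_ids=np.array(gene_ids))


def write_narrowpeak(path, summits: pd.DataFrame, flank_hint: int = 250) -> None:
    """Write summits as 10-column narrowPeak; the summit offset goes in col 10."""
    df = pd.DataFrame(summits)
    start = (df["summit"] - flank_hint).clip(lower=0)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": start,
            "end": df["summit"] + flank_hint + 1,
            "name": [f"peak_{i}" for i in range(len(df))],
            "score_int": 0,
            "strand": ".",
            "signalValue": 0.0,
            "pValue": -1.0,
            "qValue": df["score"],
            "peak": df["summit"] - start,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path, cluster: str | None = None) -> pd.DataFrame:
    """Read narrowPeak into a summit table (summit = start + column 10)."""
    df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLUMNS)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "summit": df["start"] + df["peak"],
            "score": df["qValue"],
            "cluster": cluster if cluster is not None else "pooled",
        }
    )
    return out


def write_bed6(path, peaks: pd.DataFrame) -> None:
    """Write peaks as BED6 with the SPM value in the score column."""
    df = pd.DataFrame(peaks)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df.get("cluster", "."),
            "score": df.get("spm", df.get("score", 0.0)),
            "strand": ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_chrom_sizes(path, chrom_sizes: dict) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        chrom, size = line.split("\t")
        out[chrom] = int(size)
    return out


def write_tree(path_prefix, tree: TaxonomyTree) -> None:
    """Write a tree as Newick plus a JSON sidecar of per-node statistics."""
    prefix = str(path_prefix)
    Path(prefix + ".nwk").write_text(tree.to_newick() + "\n")
    nodes = []
    for node in tree.nodes():
        rec = {
            "leaves": sorted(node.leaves),
            "height": node.height,
            "confidence": node.confidence,
        }
        if node.stats is not None:
            rec.update(
                size=node.stats.size,
                species_mixing=node.stats.species_mixing,
                stability=node.stats.stability,
            )
        nodes.append(rec)
    Path(prefix + "_nodes.json").write_text(json.dumps(nodes, indent=1))


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default))
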