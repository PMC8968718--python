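"""Plain-text readers and writers shared by all stages.

Everything is TSV / GMT / JSON so each stage is independently invokable
and diffable; no binary formats.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .instruments import SUMMARY_COLUMNS, LDMatrix, SummaryStats
from .simulate import AnnotationTable, ExpressionMatrix, GroundTruth, Term

__all__ = [
    "write_summary_stats", "read_summary_stats",
    "write_ld", "read_ld",
    "write_matrix", "read_matrix",
    "write_expression", "read_expression",
    "write_gmt", "read_gmt",
    "write_edge_list", "read_edge_list",
    "write_ground_truth", "read_ground_truth",
]


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    stats.table.to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path, trait: str | None = None) -> SummaryStats:
    t = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return SummaryStats(trait or Path(path).stem, t[SUMMARY_COLUMNS])


def write_ld(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(path, sep="\t")


def read_ld(path: str | Path) -> LDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LDMatrix(df.index.tolist(), df.to_numpy(float))


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: ExpressionMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.expr.tsv``, ``<prefix>.probes.tsv`` and ``<prefix>.samples.tsv``."""
    prefix = Path(prefix)
    expr.values.to_csv(prefix.with_suffix(".expr.tsv"), sep="\t")
    expr.probe_to_gene.rename_axis("probe").to_frame().to_csv(
        prefix.with_suffix(".probes.tsv"), sep="\t"
    )
    expr.sample_to_region.rename_axis("sample").to_frame().to_csv(
        prefix.with_suffix(".samples.tsv"), sep="\t"
    )


def read_expression(prefix: str | Path) -> ExpressionMatrix:
    prefix = Path(prefix)
    values = pd.read_csv(prefix.with_suffix(".expr.tsv"), sep="\t", index_col=0)
    probes = pd.read_csv(prefix.with_suffix(".probes.tsv"), sep="\t", index_col=0)["gene"]
    samples = pd.read_csv(prefix.with_suffix(".samples.tsv"), sep="\t", index_col=0)["region"]
    return ExpressionMatrix(values, probes, samples)


def write_gmt(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in table.terms:
            fh.write("\t".join([t.term_id, t.name, *t.genes]) + "\n")


def read_gmt(path: str | Path, ontology: str | None = None) -> AnnotationTable:
    terms = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms.append(Term(parts[0], parts[1], parts[2:]))
    return AnnotationTable(ontology or Path(path).stem, terms)


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tconfidence\n")
        for u, v, c in sorted(graph.edges(data="confidence", default=1.0)):
            fh.write(f"{u}\t{v}\t{c:g}\n")


def read_edge_list(path: str | Path, nodes: list[str] | None = None) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for row in df.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, confidence=float(getattr(row, "confidence", 1.0)))
    return g


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())
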