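"""Readers and writers for the pipeline's external formats.

Tabular inputs and outputs are tab-separated text with a header row.
Genomic annotations enter as standard BED (0-based, half-open) and are
converted to 1-based inclusive coordinates exactly once, here at the
boundary. Networks are exported as SIF and GraphML with deterministic
(lexicographic) edge ordering so repeated runs produce identical bytes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .core import (
    CHROMOSOMES,
    ExpressionMatrix,
    FeatureAnnotation,
    InteractionTable,
    OmicsKind,
    ProteinGeneMap,
    SampleDesign,
)

logger = logging.getLogger("pairomics")

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_design",
    "write_sample_design",
    "read_feature_annotation",
    "write_feature_annotation",
    "read_interaction_table",
    "write_interaction_table",
    "read_protein_gene_map",
    "write_protein_gene_map",
    "write_network_sif",
    "read_network_sif",
    "write_network_graphml",
    "write_table",
    "write_outputs",
]


def read_expression_matrix(path, omics_kind: OmicsKind | str) -> ExpressionMatrix:
    """Read a features x samples abundance TSV (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty expression matrix: {path}")
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ]
    if len(non_numeric):
        raise ValueError(
            f"non-numeric values in sample columns {list(non_numeric)} of {path}"
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, OmicsKind(omics_kind))


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_sample_design(path) -> SampleDesign:
    return SampleDesign(pd.read_csv(path, sep="\t", dtype=str))


def write_sample_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_feature_annotation(
    path, omics_kind: OmicsKind | str, strict: bool = False
) -> FeatureAnnotation:
    """Read a BED file into 1-based inclusive feature coordinates.

    BED intervals are 0-based half-open; internally start = BED start + 1 and
    end = BED end. Records on chromosomes outside 1..22/X/Y are skipped with a
    warning unless ``strict``, in which case they raise.
    """
    kind = OmicsKind(omics_kind)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 4 fields")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            chrom = chrom.removeprefix("chr")
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: empty or inverted interval for {name!r} "
                    f"(BED start {start} >= end {end})"
                )
            if chrom not in CHROMOSOMES:
                msg = f"{path}:{lineno}: feature {name!r} on chromosome {chrom!r} outside 1..22/X/Y"
                if strict:
                    raise ValueError(msg)
                logger.warning("%s; record skipped", msg)
                continue
            records.append((name, kind.value, chrom, start + 1, end))
    if not records:
        raise ValueError(f"no usable records in BED file {path}")
    table = pd.DataFrame(
        records, columns=["feature_id", "omics_kind", "chromosome", "start", "end"]
    )
    return FeatureAnnotation(table)


def write_feature_annotation(annotation: FeatureAnnotation, path) -> None:
    """Write annotation back out as BED (internal 1-based -> 0-based half-open)."""
    t = annotation.table.sort_values("feature_id")
    with open(path, "w") as fh:
        for row in t.itertuples(index=False):
            fh.write(
                f"chr{row.chromosome}\t{row.start - 1}\t{row.end}\t{row.feature_id}\n"
            )


def read_interaction_table(path) -> InteractionTable:
    """Read a miRTarBase-like miRNA->gene table.

    Duplicate (mirna, gene) rows collapse to the strongest support level
    (functional_strong beats other).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"mirna_id", "gene_id", "support"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"interaction table {path} missing columns {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"empty interaction table: {path}")
    rank = {"functional_strong": 0, "other": 1}
    bad = set(df["support"]) - set(rank)
    if bad:
        raise ValueError(f"unknown support levels in {path}: {sorted(bad)}")
    df = (
        df.assign(_rank=df["support"].map(rank))
        .sort_values("_rank")
        .drop_duplicates(["mirna_id", "gene_id"], keep="first")
        .drop(columns="_rank")
        .sort_values(["mirna_id", "gene_id"])
        .reset_index(drop=True)
    )
    return InteractionTable(df)


def write_interaction_table(interactions: InteractionTable, path) -> None:
    interactions.table.sort_values(["mirna_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_protein_gene_map(path) -> ProteinGeneMap:
    return ProteinGeneMap(pd.read_csv(path, sep="\t", dtype=str))


def write_protein_gene_map(mapping: ProteinGeneMap, path) -> None:
    mapping.table.sort_values(["protein_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def _sorted_edges(graph: nx.Graph):
    return sorted((min(u, v), max(u, v), d) for u, v, d in graph.edges(data=True))


def write_network_sif(graph: nx.Graph, path, relation: str = "interacts") -> None:
    """Write a graph in simple interaction format (SIF), one edge per line."""
    with open(path, "w") as fh:
        for u, v, d in _sorted_edges(graph):
            fh.write(f"{u}\t{d.get('relation', relation)}\t{v}\n")


def read_network_sif(path) -> nx.Graph:
    graph = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                graph.add_node(fields[0])
            else:
                source, relation = fields[0], fields[1]
                for target in fields[2:]:
                    graph.add_edge(source, target, relation=relation)
    return graph


def write_network_graphml(graph: nx.Graph, path) -> None:
    # rebuild with sorted nodes/edges so output bytes are run-independent
    ordered = nx.Graph()
    ordered.add_nodes_from(sorted(graph.nodes(data=True)))
    ordered.add_edges_from(_sorted_edges(graph))
    nx.write_graphml(ordered, path)


def write_table(df: pd.DataFrame, path, sort_by=None) -> None:
    """Write a result table as TSV with deterministic row order."""
    out = df.copy()
    if sort_by is None:
        sort_by = [out.columns[0]]
    out = out.sort_values(list(sort_by), kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_outputs(tables: dict, networks: dict, out_dir) -> list[Path]:
    """Write result tables (TSV) and networks (SIF + GraphML) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(tables):
        path = out_dir / f"{name}.tsv"
        write_table(tables[name], path)
        written.append(path)
    for name in sorted(networks):
        sif = out_dir / f"{name}.sif"
        gml = out_dir / f"{name}.graphml"
        write_network_sif(networks[name], sif)
        write_network_graphml(networks[name], gml)
        written.extend([sif, gml])
    logger.info("wrote %d files to %s", len(written), out_dir)
    return written
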