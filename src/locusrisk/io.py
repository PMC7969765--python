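"""Readers and writers for the plain-text formats the tool touches.

TSV for index SNPs, feature tables and posterior output; BED for gene
coordinates; 2-3 column or BioGRID-TAB edge lists for networks; GMT for
gene sets. Parsers never drop rows silently: every merged duplicate edge
and dropped self-loop is counted in the log.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    P_FLOOR,
    FeatureBundle,
    FormatError,
    GeneNetwork,
    GeneRecord,
    GeneSet,
    IndexSNP,
    PosteriorTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_index_snps",
    "read_gene_bed",
    "read_network",
    "read_feature_table",
    "read_gmt",
    "write_posterior_table",
    "read_posterior_table",
]


def read_index_snps(path: str | Path) -> list[IndexSNP]:
    """Read a TSV of index SNPs with header columns snp_id, chrom, pos."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["snp_id", "chrom", "pos"]
        for col in required:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        idx = {c: header.index(c) for c in required}
        snps: list[IndexSNP] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            snp_id = fields[idx["snp_id"]]
            try:
                pos = int(fields[idx["pos"]])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer pos {fields[idx['pos']]!r}"
                ) from None
            if snp_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate snp_id {snp_id!r}")
            seen.add(snp_id)
            snps.append(IndexSNP(snp_id, fields[idx["chrom"]], pos))
    return snps


def read_gene_bed(path: str | Path) -> list[GeneRecord]:
    """Read gene coordinates from BED (chrom, start, end, name[, score, strand])."""
    path = Path(path)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED needs >= 4 columns")
            chrom, start_s, end_s, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "."
            if strand in {"−"}:  # unicode minus
                strand = "-"
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if name in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene symbol {name!r}")
            seen.add(name)
            genes.append(GeneRecord(name, chrom, start, end, strand))
    return genes


def _add_edge(graph: nx.Graph, u: str, v: str, w: float, counts: dict[str, int]) -> None:
    if w < 0 or not np.isfinite(w):
        raise ValidationError(f"negative or non-finite edge weight {w} on {u}-{v}")
    if u == v:
        counts["self_loops"] += 1
        return
    if graph.has_edge(u, v):
        counts["duplicates"] += 1
        graph[u][v]["weight"] = max(graph[u][v]["weight"], w)
    else:
        graph.add_edge(u, v, weight=w)


def read_network(path: str | Path, dialect: str = "generic", name: str | None = None) -> GeneNetwork:
    """Read a weighted undirected edge list.

    dialect="generic": 2-3 column TSV (u, v[, weight; default 1.0]).
    dialect="biogrid_tab": tab-delimited with a header naming two official
    symbol columns ("Official Symbol Interactor A"/"B"); weight 1.0.

    Duplicate edges are merged by max weight; self-loops are dropped.
    Both events are counted in the log.
    """
    path = Path(path)
    graph = nx.Graph()
    counts = {"self_loops": 0, "duplicates": 0}
    if dialect == "generic":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise FormatError(f"{path}:{lineno}: edge needs >= 2 columns")
                w = 1.0
                if len(fields) >= 3 and fields[2] != "":
                    try:
                        w = float(fields[2])
                    except ValueError:
                        raise FormatError(f"{path}:{lineno}: bad weight {fields[2]!r}") from None
                _add_edge(graph, fields[0], fields[1], w, counts)
    elif dialect == "biogrid_tab":
        with path.open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
            try:
                ia = header.index("Official Symbol Interactor A")
                ib = header.index("Official Symbol Interactor B")
            except ValueError:
                raise FormatError(f"{path}: BioGRID-TAB header lacks official symbol columns") from None
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) <= max(ia, ib):
                    continue
                _add_edge(graph, fields[ia], fields[ib], 1.0, counts)
    else:
        raise ValueError(f"unknown network dialect {dialect!r}")
    if counts["self_loops"]:
        logger.warning("%s: dropped %d self-loop(s)", path, counts["self_loops"])
    if counts["duplicates"]:
        logger.info("%s: merged %d duplicate edge(s) by max weight", path, counts["duplicates"])
    return GeneNetwork(name or path.stem, graph)


def read_feature_table(
    path: str | Path,
    pvalue_columns: list[str],
    continuous_columns: list[str],
    gene_column: str = "gene",
) -> FeatureBundle:
    """Read a per-gene feature TSV and split columns into the two categories.

    Missing continuous values are imputed by the per-column median; missing
    p-values are imputed as 1.0 (no evidence). p-values are clamped into
    [1e-300, 1]; values outside [0, 1] beforehand are an error. Imputation
    counts are logged so users can audit the fill-in.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in [gene_column, *pvalue_columns, *continuous_columns]:
        if col not in df.columns:
            raise FormatError(f"{path}: unknown column {col!r}")
    genes = df[gene_column].astype(str).tolist()
    if len(set(genes)) != len(genes):
        raise ValidationError(f"{path}: duplicate gene symbols in {gene_column!r}")

    pv = df[pvalue_columns].astype(float).copy()
    for col in pvalue_columns:
        bad = pv[col].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValidationError(f"{path}: p-value column {col!r} has entries outside [0, 1]")
        n_missing = int(pv[col].isna().sum())
        if n_missing:
            logger.info("%s: imputed %d missing p-value(s) in %s as 1.0", path, n_missing, col)
        pv[col] = pv[col].fillna(1.0).clip(lower=P_FLOOR, upper=1.0)

    cont = df[continuous_columns].astype(float).copy()
    for col in continuous_columns:
        n_missing = int(cont[col].isna().sum())
        if n_missing:
            med = cont[col].median()
            logger.info("%s: imputed %d missing value(s) in %s with median %g", path, n_missing, col, med)
            cont[col] = cont[col].fillna(med)

    pv.index = genes
    cont.index = genes
    return FeatureBundle(genes=genes, pvalues=pv, continuous=cont)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (name, description, genes...)."""
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT needs name, description, >= 1 gene")
            sets.append(GeneSet(fields[0], frozenset(g for g in fields[2:] if g), fields[1]))
    return sets


def write_posterior_table(table: PosteriorTable, path: str | Path) -> None:
    """Write the posterior table as TSV.

    Row order is deterministic: locus order, then PP descending, then gene
    symbol (the tie rule).
    """
    frame = table.to_frame()
    frame = frame.sort_values(
        ["locus", "pp", "gene"], ascending=[True, False, True], kind="mergesort"
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_posterior_table(path: str | Path) -> pd.DataFrame:
    """Read back a posterior TSV written by :func:`write_posterior_table`."""
    return pd.read_csv(path, sep="\t")
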