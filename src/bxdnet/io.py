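"""Readers and writers for the tabular and network formats the pipeline touches.

TSV dialect: tab-separated, UTF-8, lines starting with ``#`` ignored, empty
cells or ``NA`` read as missing.  Genotypes additionally support the
GeneNetwork ``.geno`` dialect (header lines beginning ``@``, columns
Chr, Locus, cM, then strains).  Networks export to SIF and GraphML with
deterministic lexicographic ordering so repeated runs diff cleanly.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import (
    DataModelError,
    ExpressionMatrix,
    GeneSetCollection,
    GenotypeMatrix,
    PhenotypeTable,
    PPIEdgeList,
)

_NA = ("", "NA", "NaN", "nan")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", index_col=0, na_values=list(_NA),
        keep_default_na=False, dtype_backend="numpy_nullable",
    )


def _check_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    try:
        return df.astype(float)
    except (TypeError, ValueError):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise DataModelError(
                    f"{path}: non-numeric cell at row {row!r}, column {col!r}"
                ) from None
        raise


def read_expression(path, condition: str = "combined") -> ExpressionMatrix:
    """Read a genes x strains log2 expression TSV (first column gene id)."""
    df = _read_tsv(path)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise DataModelError(f"{path}: duplicate gene identifier(s): {dup[:5]}")
    return ExpressionMatrix(_check_numeric(df, path), condition=condition)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene", na_rep="NA")


def read_phenotypes(path) -> PhenotypeTable:
    """Read a strains x traits TSV (first column strain id)."""
    df = _read_tsv(path)
    return PhenotypeTable(_check_numeric(df, path))


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.data.to_csv(path, sep="\t", index_label="strain", na_rep="NA")


# ---------------------------------------------------------------------------
# genotypes

DEFAULT_ALLELE_CODES = {"B": 0.0, "D": 1.0, "H": np.nan, "U": np.nan}


def read_genotypes(path, allele_codes: dict | None = None) -> GenotypeMatrix:
    """Read genotypes from TSV or GeneNetwork-style ``.geno``.

    TSV layout: columns ``marker``, ``chrom``, ``pos``, then one column per
    strain with allele symbols (default B -> 0, D -> 1, H/U -> missing) or
    numeric codes.  ``.geno`` layout: ``@``-prefixed header lines, then a
    header row ``Chr  Locus  cM  <strains...>``.
    """
    allele_codes = dict(DEFAULT_ALLELE_CODES if allele_codes is None else allele_codes)
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    meta = [ln for ln in lines if ln.startswith("@")]
    body = [ln for ln in lines if not ln.startswith("@")]
    df = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if cols[:3] == ["chr", "locus", "cm"]:  # .geno dialect
        df = df.rename(columns=dict(zip(df.columns[:3], ["chrom", "marker", "pos"])))
        df = df[["marker", "chrom", "pos"] + list(df.columns[3:])]
        pos_unit = "cM"
    else:
        df.columns = ["marker", "chrom", "pos"] + list(df.columns[3:])
        pos_unit = "cM"
        for ln in meta:
            if ln.lower().startswith("@pos_unit"):
                pos_unit = ln.split(":", 1)[1].strip()
    df = df.set_index("marker")
    marker_map = pd.DataFrame(
        {"chrom": df["chrom"].astype(str), "pos": df["pos"].astype(float)},
        index=df.index,
    )
    strains = df.columns[2:]

    def decode(cell: str) -> float:
        cell = cell.strip()
        if cell in _NA:
            return np.nan
        if cell in allele_codes:
            return allele_codes[cell]
        try:
            v = float(cell)
        except ValueError:
            raise DataModelError(f"unknown allele symbol {cell!r}") from None
        return v

    codes = df[strains].map(decode)
    return GenotypeMatrix(codes, marker_map, pos_unit=pos_unit)


def write_genotypes(geno: GenotypeMatrix, path, symbols: bool = True) -> None:
    """Write genotypes as TSV; ``symbols`` emits B/D/H instead of 0/1/NA."""
    inv = {0.0: "B", 1.0: "D"}
    out = geno.codes.copy()
    if symbols:
        out = out.map(lambda v: "H" if np.isnan(v) else inv[v])
    df = pd.concat([geno.marker_map, out], axis=1)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"@pos_unit: {geno.pos_unit}\n")
        df.to_csv(fh, sep="\t", index_label="marker", na_rep="NA")


# ---------------------------------------------------------------------------
# PPI and gene sets

def read_ppi(path) -> PPIEdgeList:
    """Read a STRING protein-links style TSV (protein1 protein2 combined_score)."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    df.columns = ["protein1", "protein2", "score"] + list(df.columns[3:])
    return PPIEdgeList(df[["protein1", "protein2", "score"]])


def write_ppi(ppi: PPIEdgeList, path) -> None:
    ppi.edges.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataModelError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        name, d, members = parts[0], parts[1], parts[2:]
        sets[name] = {m for m in members if m}
        desc[name] = d
    return GeneSetCollection(sets, desc)


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(coll.sets):
            members = "\t".join(sorted(coll.sets[name]))
            fh.write(f"{name}\t{coll.descriptions.get(name, '')}\t{members}\n")


# ---------------------------------------------------------------------------
# network export

NETWORK_FORMATS = ("SIF", "GraphML", "TSV")


def _sorted_edges(edges) -> list[tuple[str, str, float | None]]:
    out = []
    for e in edges:
        if len(e) == 2:
            u, v, w = str(e[0]), str(e[1]), None
        else:
            u, v, w = str(e[0]), str(e[1]), float(e[2])
        if v < u:
            u, v = v, u
        out.append((u, v, w))
    return sorted(out, key=lambda t: (t[0], t[1]))


def write_network(edges, fmt: str, path, interaction: str = "pp") -> None:
    """Write a weighted edge list as SIF, GraphML or TSV.

    ``edges`` is an iterable of (node1, node2) or (node1, node2, weight).
    Node and edge order in the output is lexicographic for reproducible diffs.
    """
    fmt_norm = fmt.strip().lower()
    if fmt_norm not in {f.lower() for f in NETWORK_FORMATS}:
        raise DataModelError(f"unknown network format {fmt!r}; use SIF, GraphML or TSV")
    rows = _sorted_edges(edges)
    if fmt_norm == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, _ in rows:
                fh.write(f"{u}\t{interaction}\t{v}\n")
    elif fmt_norm == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("node1\tnode2\tweight\n")
            for u, v, w in rows:
                fh.write(f"{u}\t{v}\t{'' if w is None else w}\n")
    else:
        g = nx.Graph()
        for u, v, w in rows:
            if w is None:
                g.add_edge(u, v)
            else:
                g.add_edge(u, v, weight=w)
        # networkx preserves insertion order, already lexicographic
        nx.write_graphml(g, path)


def read_network(path, fmt: str) -> list[tuple[str, str]]:
    """Read back an exported network as a sorted unweighted edge list."""
    fmt_norm = fmt.strip().lower()
    if fmt_norm == "sif":
        edges = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            u, _, v = line.split("\t")
            edges.append((u, v))
    elif fmt_norm == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        edges = list(zip(df["node1"], df["node2"]))
    elif fmt_norm == "graphml":
        g = nx.read_graphml(path)
        edges = list(g.edges())
    else:
        raise DataModelError(f"unknown network format {fmt!r}")
    return [(u, v) for u, v, _ in _sorted_edges(edges)]
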