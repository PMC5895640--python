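"""PPI overlay: high-confidence filtering, module intersection, subnetworks.

High-confidence interactions (score strictly greater than 700 by default) are
mapped onto the co-expression modules; edges whose two endpoints carry the
same non-grey module label are the "common interactions", and connected
components of at least ``min_nodes`` genes within one module are reported as
functional subnetworks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .datamodel import GREY, ModuleAssignment, PPIEdgeList
from .io import write_network

log = logging.getLogger(__name__)


@dataclass
class FilteredPPI:
    edges: pd.DataFrame  # protein1, protein2, score (gene-id namespace)
    min_score: int
    n_unmapped: int = 0


@dataclass
class Subnetwork:
    module: str
    nodes: list[str]
    edges: list[tuple[str, str]]

    @property
    def size(self) -> int:
        return len(self.nodes)


def filter_ppi(
    ppi: PPIEdgeList,
    min_score: int = 700,
    mapping: dict[str, str] | None = None,
) -> FilteredPPI:
    """Keep edges with score strictly above ``min_score``; optionally map
    protein identifiers to gene identifiers (unmapped proteins dropped)."""
    df = ppi.edges
    df = df[df["score"] > min_score].copy()
    n_unmapped = 0
    if mapping is not None:
        mapped1 = df["protein1"].map(mapping)
        mapped2 = df["protein2"].map(mapping)
        drop = mapped1.isna() | mapped2.isna()
        n_unmapped = len(set(df.loc[mapped1.isna(), "protein1"])
                         | set(df.loc[mapped2.isna(), "protein2"]))
        if n_unmapped:
            log.warning("%d unmapped protein(s) dropped", n_unmapped)
        df = df[~drop].copy()
        df["protein1"], df["protein2"] = mapped1[~drop], mapped2[~drop]
        df = PPIEdgeList(df).edges  # re-canonicalize after mapping
    return FilteredPPI(df.reset_index(drop=True), min_score, n_unmapped)


def intersect_with_modules(
    ppi: FilteredPPI,
    assignment: ModuleAssignment,
    adjacency: pd.DataFrame | None = None,
    min_adjacency: float = 0.1,
) -> pd.DataFrame:
    """Common interactions: PPI edges with both endpoints in the same
    non-grey module, annotated with the module label.

    When ``adjacency`` is given, the stricter mode additionally requires
    co-expression adjacency >= ``min_adjacency`` between the endpoints.
    """
    labels = assignment.labels
    df = ppi.edges
    nodes = set(df["protein1"]) | set(df["protein2"])
    known = nodes & set(labels.index)
    if nodes and len(known) < 0.5 * len(nodes):
        log.warning(
            "%d of %d PPI nodes not present among expression genes",
            len(nodes) - len(known), len(nodes),
        )
    lab1 = df["protein1"].map(labels)
    lab2 = df["protein2"].map(labels)
    keep = lab1.notna() & (lab1 == lab2) & (lab1 != GREY)
    out = df[keep].copy()
    out["module"] = lab1[keep]
    if adjacency is not None:
        adj_ok = [
            float(adjacency.loc[u, v]) >= min_adjacency
            for u, v in zip(out["protein1"], out["protein2"])
        ]
        out = out[adj_ok]
    return out.reset_index(drop=True)


def extract_subnetworks(common_edges: pd.DataFrame, min_nodes: int = 5) -> list[Subnetwork]:
    """Connected components within each module's edge set, size >= min_nodes,
    ordered by decreasing size (ties by module then first node)."""
    subnets: list[Subnetwork] = []
    if len(common_edges) == 0:
        return subnets
    for module, grp in common_edges.groupby("module"):
        g = nx.Graph()
        g.add_edges_from(zip(grp["protein1"], grp["protein2"]))
        for comp in nx.connected_components(g):
            if len(comp) >= min_nodes:
                nodes = sorted(comp)
                edges = sorted(
                    (min(u, v), max(u, v))
                    for u, v in g.subgraph(comp).edges()
                )
                subnets.append(Subnetwork(str(module), nodes, edges))
    subnets.sort(key=lambda s: (-s.size, s.module, s.nodes[0]))
    return subnets


def export_subnetworks(
    subnets: list[Subnetwork],
    outdir,
    fmt: str = "SIF",
    node_attributes: pd.DataFrame | None = None,
) -> list[str]:
    """One network file per subnetwork plus a node-attribute table.

    ``node_attributes`` (genes in the index, e.g. module/kME/k_in columns)
    is subset per subnetwork and written alongside.  Returns written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = {"sif": "sif", "graphml": "graphml", "tsv": "tsv"}.get(fmt.strip().lower())
    if ext is None:
        raise ValueError(f"unknown network format {fmt!r}")
    written = []
    for i, sn in enumerate(subnets, start=1):
        stem = f"subnetwork_{i:02d}_{sn.module}"
        path = outdir / f"{stem}.{ext}"
        write_network(sn.edges, fmt, path)
        written.append(str(path))
        if node_attributes is not None:
            attr = node_attributes.reindex(sn.nodes)
            attr_path = outdir / f"{stem}.nodes.tsv"
            attr.to_csv(attr_path, sep="\t", index_label="gene", na_rep="NA")
            written.append(str(attr_path))
    return written
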