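"""Condition-specific bipartite miRNA→gene subnetwork construction.

The screened inverse-correlation pairs are intersected with a reference
miRNA→mRNA interaction edge list (the package consumes any merged edge list;
it does not rebuild one from target databases).  The result is the
condition-specific regulatory subnetwork on which exclusivity scoring
operates: edges are directed miRNA → gene, node sets are exactly the edge
endpoints (no isolated nodes), and each edge carries its (rho, p) provenance
from the correlation screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .data_io import DataValidationError, InteractionEdgeList

logger = logging.getLogger(__name__)


@dataclass
class RegulatorySubnetwork:
    """Bipartite miRNA→gene graph; nodes carry kind = 'miRNA' | 'mRNA'."""

    graph: nx.DiGraph

    @property
    def mirnas(self) -> set:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "miRNA"}

    @property
    def genes(self) -> set:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "mRNA"}

    @property
    def edges(self) -> set:
        return set(self.graph.edges())

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __len__(self) -> int:
        return self.n_edges

    def summary(self) -> dict:
        return {
            "nodes": self.n_nodes,
            "mirnas": len(self.mirnas),
            "genes": len(self.genes),
            "edges": self.n_edges,
        }


def build_subnetwork(
    pairs: pd.DataFrame, reference: InteractionEdgeList
) -> RegulatorySubnetwork:
    """Intersect screened pairs with the reference edge list.

    ``pairs`` must carry columns ``mirna_id, gene_id`` and optionally
    ``rho, p_value``.  An empty intersection yields an empty subnetwork with
    a warning (not an error).  When none of the pair miRNAs occur in the
    reference at all, a loud diagnostic flags a likely id-scheme mismatch.
    """
    g = nx.DiGraph()
    have_rho = "rho" in pairs.columns
    n_pairs = len(pairs)
    for row in pairs.itertuples(index=False):
        edge = (str(row.mirna_id), str(row.gene_id))
        if edge not in reference.edges:
            continue
        g.add_node(edge[0], kind="miRNA")
        g.add_node(edge[1], kind="mRNA")
        attrs = {"rho": float(row.rho), "p_value": float(row.p_value)} if have_rho else {}
        g.add_edge(*edge, **attrs)

    net = RegulatorySubnetwork(g)
    if net.mirnas & net.genes:
        raise DataValidationError("miRNA and gene namespaces overlap in subnetwork")
    if n_pairs and net.n_edges == 0:
        pair_mirnas = {str(m) for m in pairs["mirna_id"]}
        if not (pair_mirnas & reference.mirnas):
            logger.warning(
                "build_subnetwork: 0%% of pair miRNAs found in the reference "
                "network — likely an identifier-scheme mismatch"
            )
        logger.warning("build_subnetwork: empty intersection, empty subnetwork")
    s = net.summary()
    logger.info(
        "subnetwork: %d nodes = %d miRNAs + %d genes, %d edges",
        s["nodes"], s["mirnas"], s["genes"], s["edges"],
    )
    return net


def subnetwork_table(net: RegulatorySubnetwork) -> pd.DataFrame:
    rows = [
        {
            "mirna_id": m,
            "gene_id": g,
            "rho": d.get("rho", float("nan")),
            "p_value": d.get("p_value", float("nan")),
        }
        for m, g, d in sorted(net.graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "rho", "p_value"])


def write_subnetwork(net: RegulatorySubnetwork, path) -> None:
    """Edge-list TSV plus a one-line summary comment is written separately by
    the pipeline; here only the schema'd edge table."""
    subnetwork_table(net).to_csv(path, sep="\t", index=False)


def read_subnetwork(path) -> RegulatorySubnetwork:
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_id": str})
    g = nx.DiGraph()
    for row in df.itertuples(index=False):
        g.add_node(row.mirna_id, kind="miRNA")
        g.add_node(row.gene_id, kind="mRNA")
        g.add_edge(row.mirna_id, row.gene_id,
                   rho=float(row.rho), p_value=float(row.p_value))
    return RegulatorySubnetwork(g)


def write_graphml(net: RegulatorySubnetwork, path) -> None:
    nx.write_graphml(net.graph, path)
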