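"""Regulatory-network assembly and export.

Builds a typed directed graph from negative-regulation miRNA-mRNA pairs and
enriched functional terms: ``targets`` edges (miRNA -> gene), ``annotated``
edges (gene -> term), and optional ``interacts`` edges (gene -> gene) merged
from an external interaction edge table (a BioGRID-style two-column export).
Gene nodes carry an up/down direction from their fold-change sign; term
nodes default to the top-8 enriched terms so desk-scale networks stay
readable.  Exports cover Cytoscape's SIF dialect, GraphML (full attribute
round trip) and a plain edge TSV; hub genes are ranked by total degree.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import networkx as nx
import pandas as pd

from .enrichment import EnrichmentResult, top_k
from .integration import QuadrantPair

logger = logging.getLogger(__name__)

__all__ = [
    "build_network",
    "merge_interactions",
    "export_network",
    "import_network",
    "hub_genes",
]

EDGE_TYPES = ("targets", "annotated", "interacts")


def _gene_direction(fc_mrna, gene: str) -> str:
    if isinstance(fc_mrna, pd.DataFrame):
        if gene not in fc_mrna.index:
            raise KeyError(f"pair references unknown gene {gene!r}")
        val = float(fc_mrna.loc[gene, "log2fc"])
    else:
        if gene not in fc_mrna:
            raise KeyError(f"pair references unknown gene {gene!r}")
        val = float(fc_mrna[gene])
    if val > 0:
        return "up"
    if val < 0:
        return "down"
    return "na"


def build_network(
    negative_pairs: Sequence[QuadrantPair],
    enrichment: Sequence[EnrichmentResult] = (),
    annotation: Optional[pd.DataFrame] = None,
    fc_mrna: Union[pd.DataFrame, Mapping[str, float], None] = None,
    k_terms: Optional[int] = 8,
) -> nx.DiGraph:
    """miRNA / gene / term graph from negative-regulation pairs.

    Nodes are the miRNAs and genes of the pairs plus the enriched terms
    (top ``k_terms`` per namespace; ``None`` keeps all); ``annotated`` edges
    link a pair gene to an included term when the annotation table says so.
    Gene direction comes from the sign of its log2 fold change.
    """
    net = nx.DiGraph()
    for p in negative_pairs:
        direction = _gene_direction(fc_mrna, p.mrna_id) if fc_mrna is not None else "na"
        y = getattr(p, "y", 0.0)
        mi_dir = "up" if y > 0 else ("down" if y < 0 else "na")
        net.add_node(p.mirna_id, node_type="miRNA", direction=mi_dir)
        net.add_node(p.mrna_id, node_type="gene", direction=direction)
        net.add_edge(p.mirna_id, p.mrna_id, edge_type="targets")

    kept_terms = list(enrichment) if k_terms is None else top_k(enrichment, k=k_terms)
    term_ids = set()
    for r in kept_terms:
        net.add_node(r.term, node_type="term", direction="na")
        term_ids.add(r.term)

    if annotation is not None and term_ids:
        genes_present = {n for n, d in net.nodes(data=True) if d["node_type"] == "gene"}
        ann = annotation[["term", "gene"]].astype(str)
        for term, gene in ann.itertuples(index=False):
            if term in term_ids and gene in genes_present:
                net.add_edge(gene, term, edge_type="annotated")
    return net


def merge_interactions(
    network: nx.DiGraph,
    edge_table: Union[pd.DataFrame, str],
    expand: bool = False,
    case_insensitive: bool = False,
    max_malformed_fraction: float = 0.10,
) -> nx.DiGraph:
    """Add gene-gene ``interacts`` edges from a two-column pair table.

    By default an edge is added only when both endpoints already exist as
    gene nodes; with ``expand=True`` first-neighbor genes of existing gene
    nodes are added too.  Self loops are dropped and duplicates (either
    orientation) collapsed.  Malformed rows are skipped with a warning; more
    than 10% malformed aborts.
    """
    if isinstance(edge_table, (str, bytes)) or hasattr(edge_table, "__fspath__"):
        edge_table = pd.read_csv(edge_table, sep="\t", header=None, dtype=str)
    rows = edge_table.iloc[:, :2].values.tolist()

    genes = {n for n, d in network.nodes(data=True) if d.get("node_type") == "gene"}
    lookup = {g.lower(): g for g in genes} if case_insensitive else {g: g for g in genes}

    def resolve(name: str) -> Optional[str]:
        key = name.lower() if case_insensitive else name
        return lookup.get(key)

    seen: set = set()
    n_malformed = 0
    for row in rows:
        a, b = (None if pd.isna(v) else str(v).strip() for v in row)
        if not a or not b:
            n_malformed += 1
            logger.warning("skipping malformed interaction row: %r", row)
            continue
        if a == b:
            continue
        ra, rb = resolve(a), resolve(b)
        if ra is not None and rb is None and expand:
            rb = b
            network.add_node(rb, node_type="gene", direction="na")
            lookup[rb.lower() if case_insensitive else rb] = rb
        elif rb is not None and ra is None and expand:
            ra = a
            network.add_node(ra, node_type="gene", direction="na")
            lookup[ra.lower() if case_insensitive else ra] = ra
        if ra is None or rb is None:
            continue
        key = tuple(sorted((ra, rb)))
        if key in seen or network.has_edge(ra, rb) or network.has_edge(rb, ra):
            continue
        seen.add(key)
        network.add_edge(ra, rb, edge_type="interacts")
    if rows and n_malformed / len(rows) > max_malformed_fraction:
        raise ValueError(
            f"{n_malformed}/{len(rows)} malformed interaction rows "
            f"(> {max_malformed_fraction:.0%}); aborting"
        )
    return network


# ---------------------------------------------------------------------------
# Export / import

def _sif_quote(name: str) -> str:
    return f'"{name}"' if any(c.isspace() for c in name) else name


def _sif_unquote(tok: str) -> str:
    return tok[1:-1] if len(tok) >= 2 and tok[0] == '"' and tok[-1] == '"' else tok


def export_network(network: nx.DiGraph, path, fmt: str) -> None:
    """Write the network as ``sif``, ``graphml`` or edge ``tsv``.

    SIF is one ``source<TAB>edge_type<TAB>target`` line per edge (names with
    whitespace quoted); isolated nodes get a bare-name line.  GraphML
    carries every node and edge attribute and round-trips exactly.
    """
    if fmt == "graphml":
        nx.write_graphml(network, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, d in sorted(network.edges(data=True)):
                fh.write(f"{_sif_quote(u)}\t{d['edge_type']}\t{_sif_quote(v)}\n")
            for n in sorted(nx.isolates(network)):
                fh.write(f"{_sif_quote(n)}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\tedge_type\ttarget\n")
            for u, v, d in sorted(network.edges(data=True)):
                fh.write(f"{u}\t{d['edge_type']}\t{v}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r} (sif, graphml, tsv)")


def import_network(path, fmt: str) -> nx.DiGraph:
    """Read a network written by :func:`export_network`.

    GraphML reproduces the full attributed graph; SIF reproduces the typed
    edge set (node attributes are not part of the dialect).
    """
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "sif":
        net = nx.DiGraph()
        with open(path) as fh:
            for line in fh:
                parts = [_sif_unquote(t) for t in line.rstrip("\n").split("\t") if t]
                if not parts:
                    continue
                if len(parts) == 1:
                    net.add_node(parts[0])
                else:
                    source, etype, targets_ = parts[0], parts[1], parts[2:]
                    for tgt in targets_:
                        net.add_edge(source, tgt, edge_type=etype)
        return net
    raise ValueError(f"unknown import format {fmt!r} (sif, graphml)")


def hub_genes(network: nx.DiGraph, top_n: int = 10) -> List[Tuple[str, int]]:
    """Gene nodes ranked by total degree (all edge types), ties by id."""
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    und = network.to_undirected(as_view=False)
    genes = [
        (n, int(und.degree(n)))
        for n, d in network.nodes(data=True)
        if d.get("node_type") == "gene"
    ]
    genes.sort(key=lambda kv: (-kv[1], kv[0]))
    return genes[:top_n]
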