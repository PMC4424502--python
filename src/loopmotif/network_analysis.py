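"""Integration of closed loops into regulatory networks; hubs, overlaps, subnetworks.

Loops sharing nodes or edges collapse into a single undirected typed graph
per time point.  Node degree (the number of distinct neighbors, direction
ignored) ranks hub regulators; loop sets from different time points are
compared by their (miR, TF, gene) composition; and externally supplied
gene-to-process annotations carve out per-process subnetworks with
Venn-style overlap counts.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import pandas as pd

from .loop_inference import ClosedLoop

__all__ = [
    "integrate",
    "degree_ranking",
    "compare_timepoints",
    "process_subnetworks",
    "export_network",
    "import_network",
]

_ROLE_CLASS = {"mir": "miR", "tf": "TF", "gene": "gene"}


def integrate(loops: list[ClosedLoop]) -> nx.Graph:
    """Union of loop nodes and edges as one undirected typed graph.

    Node attribute ``cls`` in {miR, TF, gene}; edge attribute ``edge_class``;
    edge attribute ``loops`` lists contributing loop keys.
    """
    g = nx.Graph()
    for loop in loops:
        g.add_node(loop.mir, cls="miR")
        g.add_node(loop.tf, cls="TF")
        g.add_node(loop.gene, cls="gene")
        for u, v, cls in (
            (loop.mir, loop.tf, "miR->TF"),
            (loop.mir, loop.gene, "miR->gene"),
            (loop.tf, loop.gene, "TF->gene"),
        ):
            if u == v:
                raise ValueError(f"self-edge in loop {loop.key}")
            if g.has_edge(u, v):
                g.edges[u, v]["loops"].append(loop.key)
            else:
                g.add_edge(u, v, edge_class=cls, loops=[loop.key])
    return g


def degree_ranking(network: nx.Graph, top_k: int = 10) -> dict[str, pd.DataFrame]:
    """Per-class top-k nodes by distinct-neighbor degree, ties broken by id."""
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    records = [
        {"node": n, "cls": data["cls"], "degree": network.degree[n]}
        for n, data in network.nodes(data=True)
    ]
    df = pd.DataFrame(records)
    out = {}
    for cls, sub in df.groupby("cls"):
        ranked = sub.sort_values(
            ["degree", "node"], ascending=[False, True]
        ).reset_index(drop=True)
        out[cls] = ranked.head(top_k)
    return out


def _entity_sets(loops: list[ClosedLoop]) -> dict[str, set[str]]:
    return {
        "mir": {l.mir for l in loops},
        "tf": {l.tf for l in loops},
        "gene": {l.gene for l in loops},
    }


def compare_timepoints(loops_a: list[ClosedLoop], loops_b: list[ClosedLoop]) -> dict:
    """Venn accounting of two loop sets by (miR, TF, gene) composition.

    Returns counts of common/unique loops and, per entity class, of
    common/unique participating entities.
    """
    keys_a = {l.key for l in loops_a}
    keys_b = {l.key for l in loops_b}
    report = {
        "loops": {
            "common": len(keys_a & keys_b),
            "unique_a": len(keys_a - keys_b),
            "unique_b": len(keys_b - keys_a),
        }
    }
    sets_a = _entity_sets(loops_a)
    sets_b = _entity_sets(loops_b)
    for role in ("mir", "tf", "gene"):
        report[role] = {
            "common": len(sets_a[role] & sets_b[role]),
            "unique_a": len(sets_a[role] - sets_b[role]),
            "unique_b": len(sets_b[role] - sets_a[role]),
        }
    return report


def process_subnetworks(
    loops: list[ClosedLoop], annotations: dict[str, set[str]]
) -> dict:
    """Assign loops to biological processes through their gene node.

    ``annotations`` maps process name -> gene id set (e.g. exported from an
    enrichment tool).  A loop belongs to every process containing its gene.
    Returns per-process loop lists plus pairwise and full intersection counts.
    """
    if not annotations:
        raise ValueError("empty annotation table")
    for proc, genes in annotations.items():
        if not genes:
            raise ValueError(f"process {proc!r} has an empty gene set")
    membership = {
        proc: [l for l in loops if l.gene in genes]
        for proc, genes in annotations.items()
    }
    keysets = {proc: {l.key for l in ls} for proc, ls in membership.items()}
    pairwise = {
        (p, q): len(keysets[p] & keysets[q])
        for p, q in combinations(sorted(keysets), 2)
    }
    full = set.intersection(*keysets.values()) if keysets else set()
    return {
        "processes": membership,
        "counts": {proc: len(ls) for proc, ls in membership.items()},
        "pairwise_common": pairwise,
        "all_common": len(full),
    }


def export_network(network: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write the network as GraphML (node attr cls, edge attr edge_class) or TSV."""
    if fmt == "graphml":
        g = network.copy()
        for _, _, data in g.edges(data=True):
            if "loops" in data:  # GraphML cannot hold list attributes
                data["loops"] = ";".join("|".join(k) for k in data["loops"])
        nx.write_graphml(g, path)
    elif fmt == "edgelist_tsv":
        rows = [
            {
                "source": u,
                "target": v,
                "source_cls": network.nodes[u]["cls"],
                "target_cls": network.nodes[v]["cls"],
                "edge_class": data.get("edge_class", ""),
            }
            for u, v, data in network.edges(data=True)
        ]
        cols = ["source", "target", "source_cls", "target_cls", "edge_class"]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_network(path) -> nx.Graph:
    """Read a GraphML export back; inverse of :func:`export_network`."""
    g = nx.read_graphml(path)
    out = nx.Graph()
    for n, data in g.nodes(data=True):
        out.add_node(n, cls=data.get("cls"))
    for u, v, data in g.edges(data=True):
        attrs = {"edge_class": data.get("edge_class")}
        if data.get("loops"):
            attrs["loops"] = [tuple(k.split("|")) for k in data["loops"].split(";")]
        out.add_edge(u, v, **attrs)
    return out
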