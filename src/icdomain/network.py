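"""The bin-level chromatin interaction network and its degree statistics.

Each bin involved in a significant loop is a node; an edge joins two bins
whose regions interact, weighted by the contact count.  Degree here is the
unweighted number of connections of a node (weighted degree — gene
connectivity — lives in :mod:`icdomain.expression`).  Contact classes split
edges by endpoint annotation: P-P (both promoter bins), E-E (both enhancer
bins) and P-E (one of each).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
from scipy import stats

from .annotation import BinAnnotation
from .genome_io import BinId, LoopRecord

CONTACT_CLASSES = ("P-P", "E-E", "P-E")


@dataclass
class ChromatinNetwork:
    """Undirected simple graph over annotated bins, edge weight = contact count."""

    graph: nx.Graph
    label: str = ""

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_class(self, node: BinId) -> str:
        return self.graph.nodes[node]["element_class"]


@dataclass
class DegreeReport:
    """Per-contact-class node degrees with simple summaries."""

    degrees: dict[str, dict[BinId, int]] = field(default_factory=dict)
    summary: dict[str, dict[str, float]] = field(default_factory=dict)


def build_network(
    loops: Sequence[LoopRecord], annotation: BinAnnotation, label: str = ""
) -> ChromatinNetwork:
    """Build the interaction network from pre-filtered significant loops.

    Nodes are the union of loop endpoints, carrying their annotation as
    node attributes; duplicate pair rows merge by summing contact counts.
    """
    g = nx.Graph()
    scheme = annotation.scheme
    for lp in loops:
        id1 = scheme.validate_bin(lp.bin1)
        id2 = scheme.validate_bin(lp.bin2)
        for bin_id in (id1, id2):
            if bin_id not in annotation:
                raise KeyError(f"loop endpoint {bin_id} missing from annotation")
            if bin_id not in g:
                info = annotation[bin_id]
                g.add_node(
                    bin_id,
                    element_class=info.element_class,
                    gene_ids=info.gene_ids,
                    state=info.state,
                    is_cre_of_interest=info.is_cre_of_interest,
                )
        if g.has_edge(id1, id2):
            g[id1][id2]["weight"] += lp.contact_count
        else:
            g.add_edge(id1, id2, weight=lp.contact_count)
    return ChromatinNetwork(graph=g, label=label)


def degree_by_class(net: ChromatinNetwork) -> DegreeReport:
    """Unweighted node degrees within each contact-class subnetwork.

    For class X-Y only edges whose endpoint classes are exactly {X, Y} are
    kept; a node's degree is its edge count in that subnetwork, reported
    for participating nodes only.
    """
    report = DegreeReport()
    class_edges: dict[str, list[tuple[BinId, BinId]]] = {c: [] for c in CONTACT_CLASSES}
    for u, v in net.graph.edges():
        cu, cv = net.node_class(u), net.node_class(v)
        pair = {cu, cv}
        if pair == {"P"}:
            class_edges["P-P"].append((u, v))
        elif pair == {"E"}:
            class_edges["E-E"].append((u, v))
        elif pair == {"P", "E"}:
            class_edges["P-E"].append((u, v))
    for cls, edges in class_edges.items():
        degs: dict[BinId, int] = {}
        for u, v in edges:
            degs[u] = degs.get(u, 0) + 1
            degs[v] = degs.get(v, 0) + 1
        report.degrees[cls] = degs
        if degs:
            values = sorted(degs.values())
            n = len(values)
            median = (
                values[n // 2]
                if n % 2
                else (values[n // 2 - 1] + values[n // 2]) / 2
            )
            report.summary[cls] = {
                "mean": sum(values) / n,
                "median": float(median),
                "max": float(values[-1]),
                "n_nodes": float(n),
                "n_edges": float(len(edges)),
            }
        else:
            report.summary[cls] = {
                "mean": 0.0,
                "median": 0.0,
                "max": 0.0,
                "n_nodes": 0.0,
                "n_edges": 0.0,
            }
    return report


def compare_degree_distributions(
    groups: Mapping[str, Sequence[float]],
) -> dict:
    """Kruskal-Wallis across all groups plus pairwise Mann-Whitney U tests.

    Both are rank tests with tie correction and two-sided asymptotic
    p-values; the omnibus test asks whether the samples originate from the
    same distribution, the pairwise tests compare one sample against
    another.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    labels = list(groups)
    samples = [list(groups[lab]) for lab in labels]
    for lab, s in zip(labels, samples):
        if len(s) == 0:
            raise ValueError(f"group {lab!r} is empty")
    if all(len(set(s)) == 1 for s in samples) and len({s[0] for s in samples}) == 1:
        kw = {"H": 0.0, "p": 1.0}  # all observations tied; scipy rejects this input
    else:
        h, p = stats.kruskal(*samples)
        kw = {"H": float(h), "p": float(p)}
    pairwise: dict[tuple[str, str], dict[str, float]] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            u, p = stats.mannwhitneyu(
                samples[i], samples[j], alternative="two-sided"
            )
            pairwise[(labels[i], labels[j])] = {"U": float(u), "p": float(p)}
    return {"kruskal_wallis": kw, "pairwise": pairwise}


def hub_counts(
    loops: Sequence[LoopRecord], scheme=None
) -> dict[BinId, int]:
    """Number of distinct significant pairs each bin participates in.

    Loops must be pre-merged (one row per pair).  Keys are ``(chrom, k)``
    bin ids when a :class:`~icdomain.genome_io.BinScheme` is supplied,
    otherwise ``(chrom, start)``.
    """
    counts: dict[BinId, int] = {}
    for lp in loops:
        for iv in (lp.bin1, lp.bin2):
            key = scheme.validate_bin(iv) if scheme is not None else (iv.chrom, iv.start)
            counts[key] = counts.get(key, 0) + 1
    return counts


def average_degree(net: ChromatinNetwork) -> float:
    """Average network degree 2|E| / |N|; isolated nodes count in |N|."""
    if net.n_nodes == 0:
        raise ValueError("average degree undefined on an empty network")
    return 2.0 * net.n_edges / net.n_nodes


def write_degree_report(path: str, report: DegreeReport) -> None:
    with open(path, "w") as fh:
        fh.write("contact_class\tchrom\tbin_start\tdegree\n")
        for cls in CONTACT_CLASSES:
            for bin_id in sorted(report.degrees.get(cls, {})):
                fh.write(
                    f"{cls}\t{bin_id[0]}\t{bin_id[1]}\t{report.degrees[cls][bin_id]}\n"
                )


def read_edge_list(path: str, annotation: BinAnnotation) -> ChromatinNetwork:
    """Rebuild a network from the edge-list TSV plus its bin annotation."""
    g = nx.Graph()
    for bin_id, info in annotation.bins.items():
        g.add_node(
            bin_id,
            element_class=info.element_class,
            gene_ids=info.gene_ids,
            state=info.state,
            is_cre_of_interest=info.is_cre_of_interest,
        )
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("node1\t"):
            raise ValueError(f"{path}: not an edge-list table")
        for line in fh:
            n1, n2, w = line.rstrip("\n").split("\t")
            c1, k1 = n1.rsplit(":", 1)
            c2, k2 = n2.rsplit(":", 1)
            g.add_edge((c1, int(k1)), (c2, int(k2)), weight=int(w))
    return ChromatinNetwork(graph=g)


def write_edge_list(path: str, net: ChromatinNetwork) -> None:
    """Plain-text edge list: node1, node2, weight (bins as chrom:index)."""
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tweight\n")
        for u, v in sorted(net.graph.edges()):
            w = net.graph[u][v]["weight"]
            fh.write(f"{u[0]}:{u[1]}\t{v[0]}:{v[1]}\t{w}\n")
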