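"""Memory/responsive gene classification, iCD extraction, erosion and strength.

Transcriptional memory is read out from nascent (metabolically labelled)
RNA across three conditions: vehicle-treated naive cells, stimulated naive
cells and stimulated primed cells.  After spike-in normalization and
replicate averaging, a gene is *responsive* when its naive response
log2 fold change exceeds the cut-off (default 0.5) and *memory* when, in
addition, the primed response is amplified over the naive one by more than
the same cut-off; everything else is nonresponsive.

An iCD (interconnected chromatin domain) is the connected component of the
interaction network containing a gene's promoter bin, restricted to the
promoter's chromosome and ordered genomically.  Erosion removes edges whose
contact count falls below increasing percentiles of the global pair
connectivity distribution and tracks which regions (nodes keeping at least
one incident edge) and promoters survive.  Chromatin-state strength is the
ratio of a state's node fraction between threshold-filtered and unfiltered
iCDs — the state's resilience to erosion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genome_io import BinId, ExpressionTable
from .network import ChromatinNetwork

logger = logging.getLogger(__name__)

DEFAULT_CONDITIONS = ("naive_veh", "naive_atRA", "primed_atRA")
DEFAULT_PERCENTILES = (10, 20, 30, 40, 50, 60, 70, 80, 90)


@dataclass
class ResponseClass:
    """Per-gene memory/responsive/nonresponsive labels and fold changes."""

    labels: dict[str, str]
    lfc_response: pd.Series  # naive stimulated vs naive vehicle
    lfc_memory: pd.Series  # primed stimulated vs naive stimulated
    lfc_cut: float

    def genes(self, label: str) -> list[str]:
        return sorted(g for g, lab in self.labels.items() if lab == label)


@dataclass
class ICD:
    """One promoter's interconnected chromatin domain."""

    promoter_gene: str
    promoter_bin: BinId
    graph: nx.Graph
    genomic_order: list[BinId] = field(default_factory=list)


@dataclass
class ICDPartition:
    """Two-level community structure of an iCD."""

    coarse: dict[BinId, int]
    fine: dict[BinId, int]
    modularity: float


def classify_response(
    nascent: ExpressionTable,
    lfc_cut: float = 0.5,
    pseudocount: float = 0.1,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
) -> ResponseClass:
    """Classify genes from spike-in normalized nascent RNA levels.

    ``lfc_response = log2((naive_stim + ps) / (naive_veh + ps))`` and
    ``lfc_memory = log2((primed_stim + ps) / (naive_stim + ps))``, both on
    replicate-averaged normalized values.  Responsive iff the first exceeds
    ``lfc_cut``; memory iff additionally the second does.
    """
    cond_veh, cond_naive, cond_primed = conditions
    means = nascent.condition_means()
    for cond in conditions:
        if cond not in means.columns:
            raise KeyError(f"condition {cond!r} missing from nascent table")
    if pseudocount <= 0 and (
        (means[cond_veh] == 0).any() or (means[cond_naive] == 0).any()
    ):
        raise ValueError("zero expression values require a positive pseudocount")
    ps = pseudocount
    lfc_r = np.log2((means[cond_naive] + ps) / (means[cond_veh] + ps))
    lfc_m = np.log2((means[cond_primed] + ps) / (means[cond_naive] + ps))
    labels: dict[str, str] = {}
    for gene in means.index:
        if lfc_r[gene] > lfc_cut:
            labels[gene] = "memory" if lfc_m[gene] > lfc_cut else "responsive"
        else:
            labels[gene] = "nonresponsive"
    return ResponseClass(
        labels=labels, lfc_response=lfc_r, lfc_memory=lfc_m, lfc_cut=lfc_cut
    )


def promoter_bins_of(net: ChromatinNetwork, gene: str) -> list[BinId]:
    return sorted(
        n for n, d in net.graph.nodes(data=True) if gene in (d.get("gene_ids") or ())
    )


def extract_icd(net: ChromatinNetwork, gene: str) -> ICD:
    """The connected component around a gene's promoter bin.

    The component is restricted to the promoter's chromosome, and nodes
    are carried in genomic order (the second information layer used for
    clustering).
    """
    pbins = promoter_bins_of(net, gene)
    if not pbins:
        raise KeyError(f"gene {gene!r} has no promoter bin in the network")
    promoter_bin = pbins[0]
    chrom = promoter_bin[0]
    component = nx.node_connected_component(net.graph, promoter_bin)
    nodes = sorted(n for n in component if n[0] == chrom)
    sub = net.graph.subgraph(nodes).copy()
    return ICD(
        promoter_gene=gene,
        promoter_bin=promoter_bin,
        graph=sub,
        genomic_order=nodes,
    )


def cluster_icd(icd: ICD, seed: int = 0, chain_weight: float = 1.0) -> ICDPartition:
    """Two-level seeded community detection on a layered iCD graph.

    The layered graph combines the iCD's weighted interaction edges with a
    chain linking genomically adjacent bins (weight ``chain_weight``),
    realizing the two information layers: interaction structure and
    sequential genomic order.  The coarse level is Louvain modularity
    optimization on the layered graph; the fine level re-clusters the
    interaction edges within each coarse community, and a bin connected
    inside its community only through the adjacency chain is merged with a
    chain neighbour rather than split off.  Modularity of the coarse
    partition on the layered graph is reported.
    """
    nodes = icd.genomic_order
    if len(nodes) < 2:
        part = {n: 0 for n in nodes}
        return ICDPartition(coarse=part, fine=dict(part), modularity=0.0)

    # integer node labels (genomic-order index) keep community detection
    # independent of the interpreter's hash randomization
    index_of = {n: i for i, n in enumerate(nodes)}
    layered = nx.Graph()
    layered.add_nodes_from(range(len(nodes)))
    for u, v, d in icd.graph.edges(data=True):
        layered.add_edge(index_of[u], index_of[v], weight=float(d.get("weight", 1)))
    for i in range(len(nodes) - 1):
        if layered.has_edge(i, i + 1):
            layered[i][i + 1]["weight"] += chain_weight
        else:
            layered.add_edge(i, i + 1, weight=chain_weight)

    communities = nx.community.louvain_communities(layered, weight="weight", seed=seed)
    communities = sorted(
        (sorted(nodes[i] for i in c) for c in communities), key=lambda c: c[0]
    )
    coarse = {n: i for i, comm in enumerate(communities) for n in comm}
    modularity = nx.community.modularity(
        layered,
        [{index_of[n] for n in c} for c in communities],
        weight="weight",
    )

    fine: dict[BinId, int] = {}
    next_label = 0
    order_index = {n: i for i, n in enumerate(nodes)}
    for comm in communities:
        sub = icd.graph.subgraph(comm)
        wired = [n for n in comm if sub.degree(n) > 0]
        chain_only = [n for n in comm if sub.degree(n) == 0]
        if wired:
            wired_sub = nx.Graph()
            wired_sub.add_nodes_from(index_of[n] for n in wired)
            for u, v, d in sub.subgraph(wired).edges(data=True):
                wired_sub.add_edge(
                    index_of[u], index_of[v], weight=float(d.get("weight", 1))
                )
            parts = nx.community.louvain_communities(
                wired_sub, weight="weight", seed=seed
            )
            parts = sorted(
                (sorted(nodes[i] for i in p) for p in parts), key=lambda p: p[0]
            )
        else:
            parts = [sorted(comm)] if comm else []
            chain_only = []
        labels_here: dict[BinId, int] = {}
        for p in parts:
            for n in p:
                labels_here[n] = next_label
            next_label += 1
        # attach chain-only bins to their nearest chain neighbour in the community
        comm_sorted = sorted(comm, key=order_index.__getitem__)
        for n in sorted(chain_only, key=order_index.__getitem__):
            pos = comm_sorted.index(n)
            neighbour = None
            for candidate in comm_sorted[pos - 1 :: -1] if pos > 0 else []:
                if candidate in labels_here:
                    neighbour = candidate
                    break
            if neighbour is None:
                for candidate in comm_sorted[pos + 1 :]:
                    if candidate in labels_here:
                        neighbour = candidate
                        break
            if neighbour is None:
                labels_here[n] = next_label
                next_label += 1
            else:
                labels_here[n] = labels_here[neighbour]
        fine.update(labels_here)
    return ICDPartition(coarse=coarse, fine=fine, modularity=float(modularity))


def nearest_rank_percentile(values: Sequence[float], pct: float) -> float:
    """Nearest-rank percentile of a multiset (no interpolation)."""
    if not 0 < pct <= 100:
        raise ValueError("percentile must be in (0, 100]")
    ordered = sorted(values)
    if not ordered:
        raise ValueError("empty value set")
    rank = math.ceil(pct / 100.0 * len(ordered))
    return ordered[rank - 1]


def _surviving_nodes(icd: ICD, threshold: float) -> set[BinId]:
    """Nodes keeping >= 1 incident edge after dropping edges below threshold.

    A bin isolated in the unfiltered iCD has no edges to lose and is
    retained vacuously.
    """
    survivors: set[BinId] = set()
    for n in icd.graph.nodes:
        deg = icd.graph.degree(n)
        if deg == 0:
            survivors.add(n)
            continue
        if any(
            d.get("weight", 1) >= threshold
            for _, _, d in icd.graph.edges(n, data=True)
        ):
            survivors.add(n)
    return survivors


def erosion_analysis(
    icds_by_group: Mapping[str, Sequence[ICD]],
    global_weights: Sequence[float],
    percentiles: Sequence[int] = DEFAULT_PERCENTILES,
) -> pd.DataFrame:
    """Fraction of regions and promoters surviving increasing erosion.

    Thresholds are the given percentiles (nearest rank) of the global pair
    connectivity distribution; at each threshold, edges with contact count
    below it are removed from every iCD, a region survives if it keeps an
    incident edge, and a promoter survives if its bin does.  Fractions are
    pooled across each group relative to the unfiltered iCDs.
    """
    rows = []
    for group, icds in icds_by_group.items():
        if not icds:
            logger.warning("group %r has no iCDs; omitted from erosion curve", group)
            continue
        total_regions = sum(icd.graph.number_of_nodes() for icd in icds)
        total_promoters = len(icds)
        for pct in percentiles:
            threshold = nearest_rank_percentile(global_weights, pct)
            kept_regions = 0
            kept_promoters = 0
            for icd in icds:
                survivors = _surviving_nodes(icd, threshold)
                kept_regions += len(survivors)
                if icd.promoter_bin in survivors:
                    kept_promoters += 1
            rows.append(
                {
                    "group": group,
                    "percentile": pct,
                    "threshold": threshold,
                    "region_fraction": kept_regions / total_regions,
                    "promoter_fraction": kept_promoters / total_promoters,
                }
            )
    return pd.DataFrame(rows)


def state_strength(
    icds_by_group: Mapping[str, Sequence[ICD]],
    bin_states: Mapping[BinId, str],
    global_weights: Sequence[float],
    percentile: int = 90,
) -> pd.DataFrame:
    """Chromatin-state resilience to connectivity filtering.

    For each group and state: the fraction of that state among nodes
    surviving the percentile threshold (default 90th) divided by its
    fraction among all nodes.  Both fractions, the ratio (``strength``) and
    its reciprocal are reported; groups with no survivors get NaN.
    """
    threshold = nearest_rank_percentile(global_weights, percentile)
    rows = []
    for group, icds in icds_by_group.items():
        all_states: list[str] = []
        surv_states: list[str] = []
        for icd in icds:
            survivors = _surviving_nodes(icd, threshold)
            for n in icd.graph.nodes:
                state = bin_states.get(n, "Others")
                all_states.append(state)
                if n in survivors:
                    surv_states.append(state)
        if not all_states:
            logger.warning("group %r has no nodes; strengths undefined", group)
            continue
        n_all, n_surv = len(all_states), len(surv_states)
        if n_surv == 0:
            logger.warning("group %r has no surviving nodes at p%d", group, percentile)
        for state in sorted(set(all_states)):
            frac_unf = all_states.count(state) / n_all
            frac_fil = surv_states.count(state) / n_surv if n_surv else np.nan
            strength = frac_fil / frac_unf if n_surv else np.nan
            rows.append(
                {
                    "group": group,
                    "state": state,
                    "frac_unfiltered": frac_unf,
                    "frac_filtered": frac_fil,
                    "strength": strength,
                    "strength_reciprocal": (
                        frac_unf / frac_fil if n_surv and frac_fil > 0 else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def collect_global_weights(net: ChromatinNetwork) -> list[float]:
    """All pair connectivities (edge weights) of the network, as a multiset."""
    return [float(d["weight"]) for _, _, d in net.graph.edges(data=True)]


def write_response_classes(path: str, response: ResponseClass) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tlabel\tlfc_response\tlfc_memory\n")
        for gene in sorted(response.labels):
            fh.write(
                f"{gene}\t{response.labels[gene]}\t"
                f"{response.lfc_response[gene]:.6g}\t{response.lfc_memory[gene]:.6g}\n"
            )


def write_icd_edges(path: str, icd: ICD) -> None:
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tweight\n")
        for u, v in sorted(icd.graph.edges()):
            fh.write(
                f"{u[0]}:{u[1]}\t{v[0]}:{v[1]}\t{icd.graph[u][v]['weight']}\n"
            )
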