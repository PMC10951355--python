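"""Coupling network connectivity to gene expression.

Gene connectivity is the weighted degree of a gene's promoter bin(s): the
summed contact counts over all edges incident to any bin carrying the
gene's promoter.  Genes are ranked into connectivity percentile bins
(deciles by default) and, for each bin, the probability that a gene's
transcript count exceeds the population mean is computed twice — directly
as a conditional frequency and through Bayes' theorem,

    P(count > mean | perc) = P(perc | count > mean) * P(count > mean) / P(perc)

— which must agree to numerical precision (the decomposition is an
identity; computing both is the consistency check).

Also here: consensus k-means on per-gene z-scores, per-cell median
signature scores for single-cell matrices, and top-N signature extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .annotation import BinAnnotation
from .network import ChromatinNetwork

logger = logging.getLogger(__name__)


@dataclass
class ConditionalProbabilityTable:
    """P(count > mean | connectivity bin), by direct count and Bayes route."""

    population_mean: float
    n_genes: int
    bins: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: bin, n_genes, n_above, p_direct, p_bayes


def gene_connectivity(
    net: ChromatinNetwork, annotation: BinAnnotation | None = None
) -> dict[str, int]:
    """Summed contact counts over edges incident to each gene's promoter bins.

    A gene spanning several promoter bins sums incident weights over all of
    them (a shared edge between two of its own bins counted once per
    incidence).  Genes whose promoter bin is absent from the network are
    omitted; an isolated promoter bin yields connectivity 0.
    """
    conn: dict[str, int] = {}
    for node, data in net.graph.nodes(data=True):
        genes = data.get("gene_ids") or ()
        if not genes:
            continue
        weight = sum(net.graph[node][nbr]["weight"] for nbr in net.graph.neighbors(node))
        for gene in genes:
            conn[gene] = conn.get(gene, 0) + weight
    return conn


def percentile_bins(
    connectivity: Mapping[str, int], n_bins: int = 10
) -> dict[str, int]:
    """Split genes into connectivity rank quantiles (1 = lowest, n_bins = highest).

    Genes are ranked by (connectivity, gene id) — the gene-id component
    makes tie handling deterministic — and cut into ``n_bins`` nearly equal
    rank blocks.  Ties across a block boundary are logged.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    genes = sorted(connectivity, key=lambda g: (connectivity[g], g))
    if len(genes) < n_bins:
        raise ValueError(f"need at least {n_bins} genes, got {len(genes)}")
    blocks = np.array_split(np.arange(len(genes)), n_bins)
    assignment: dict[str, int] = {}
    for b, idx in enumerate(blocks, start=1):
        for i in idx:
            assignment[genes[i]] = b
    for b, idx in enumerate(blocks[:-1]):
        last, first_next = genes[idx[-1]], genes[blocks[b + 1][0]]
        if connectivity[last] == connectivity[first_next]:
            logger.debug(
                "connectivity tie across bin boundary %d/%d resolved by gene-id order",
                b + 1,
                b + 2,
            )
    return assignment


def conditional_expression_probability(
    bins: Mapping[str, int], expression: Mapping[str, float]
) -> ConditionalProbabilityTable:
    """P(transcript count > population mean | connectivity bin).

    The population mean is taken over the binned gene set.  Each bin's
    probability is computed directly and via the Bayes decomposition; both
    are reported and must agree (checked in the test suite to 1e-12).
    Empty bins are reported with NaN probabilities.
    """
    missing = [g for g in bins if g not in expression]
    if missing:
        raise KeyError(f"expression missing for binned genes: {missing[:5]}")
    genes = sorted(bins)
    counts = np.array([float(expression[g]) for g in genes])
    labels = np.array([bins[g] for g in genes])
    mean = counts.mean()
    above = counts > mean
    n = len(genes)
    n_above_total = int(above.sum())
    rows = []
    for b in sorted(set(labels)):
        sel = labels == b
        n_b = int(sel.sum())
        n_above = int((above & sel).sum())
        if n_b == 0:
            rows.append((b, 0, 0, np.nan, np.nan))
            continue
        p_direct = n_above / n_b
        # Bayes route: P(perc|count>mean) * P(count>mean) / P(perc)
        if n_above_total == 0:
            p_bayes = 0.0
        else:
            p_perc_given_above = n_above / n_above_total
            p_above = n_above_total / n
            p_perc = n_b / n
            p_bayes = p_perc_given_above * p_above / p_perc
        rows.append((b, n_b, n_above, p_direct, p_bayes))
    table = pd.DataFrame(
        rows, columns=["bin", "n_genes", "n_above", "p_direct", "p_bayes"]
    )
    return ConditionalProbabilityTable(
        population_mean=float(mean), n_genes=n, bins=table
    )


def _zscore_rows(expr: pd.DataFrame) -> pd.DataFrame:
    mu = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=0)
    keep = sd > 0
    if (~keep).any():
        logger.warning(
            "dropping %d zero-variance gene rows before clustering", int((~keep).sum())
        )
    expr = expr.loc[keep]
    return expr.sub(mu[keep], axis=0).div(sd[keep], axis=0)


def consensus_kmeans_zscores(
    expr: pd.DataFrame, k: int = 3, repeats: int = 10, seed: int = 0
) -> dict[str, int]:
    """Consensus k-means over per-gene z-scored expression rows.

    k-means is run ``repeats`` times with distinct seeded initializations.
    A majority co-assignment matrix (pairs clustered together in > 50% of
    runs) defines the consensus; among runs agreeing with it on at least
    half of all gene pairs, the one with the lowest within-cluster sum of
    squares is returned.  Labels are renumbered by ascending cluster mean
    of the first sample column, so the output is deterministic under seed.
    """
    if k < 1 or repeats < 1:
        raise ValueError("k and repeats must be >= 1")
    z = _zscore_rows(expr.astype(float))
    if k > len(z):
        raise ValueError(f"k={k} exceeds number of usable genes ({len(z)})")
    x = z.values
    n = len(z)
    runs = []
    for r in range(repeats):
        km = KMeans(n_clusters=k, n_init=1, random_state=seed + r)
        labels = km.fit_predict(x)
        runs.append((labels, float(km.inertia_)))
    # majority co-assignment over the repeats
    co = np.zeros((n, n))
    for labels, _ in runs:
        co += labels[:, None] == labels[None, :]
    majority = co > (len(runs) / 2.0)
    iu = np.triu_indices(n, k=1)
    best = None
    for labels, inertia in runs:
        same = (labels[:, None] == labels[None, :])[iu]
        agreement = float((same == majority[iu]).mean()) if len(iu[0]) else 1.0
        if agreement >= 0.5 and (best is None or inertia < best[1]):
            best = (labels, inertia)
    if best is None:  # cannot happen with >= 1 run agreeing, but stay safe
        best = min(runs, key=lambda t: t[1])
    labels = best[0]
    order = np.argsort(
        [x[labels == c, 0].mean() if (labels == c).any() else np.inf for c in range(k)],
        kind="stable",
    )
    relabel = {int(old): new + 1 for new, old in enumerate(order)}
    return {gene: relabel[int(lab)] for gene, lab in zip(z.index, labels)}


def signature_score(
    cell_matrix: pd.DataFrame, gene_set: Sequence[str]
) -> pd.Series:
    """Per-cell signature enrichment: median expression over the gene set."""
    present = [g for g in gene_set if g in cell_matrix.index]
    if not present:
        raise KeyError(
            f"no signature genes found in matrix; missing e.g. {list(gene_set)[:5]}"
        )
    absent = sorted(set(gene_set) - set(present))
    if absent:
        logger.warning("%d signature genes absent from matrix", len(absent))
    return cell_matrix.loc[present].median(axis=0)


def score_correlation(a: pd.Series, b: pd.Series) -> float:
    """Pearson correlation between two per-cell signature score vectors."""
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    if len(joined) < 2:
        raise ValueError("need at least 2 cells with both scores defined")
    r, _ = stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
    return float(r)


def top_n_signature(expr: Mapping[str, float], n: int = 150) -> list[str]:
    """The n genes with highest expression; boundary ties break by gene id."""
    if n <= 0:
        raise ValueError("n must be positive")
    genes = sorted(expr, key=lambda g: (-float(expr[g]), g))
    if n > len(genes):
        raise ValueError(f"n={n} exceeds number of genes ({len(genes)})")
    if n < len(genes) and float(expr[genes[n - 1]]) == float(expr[genes[n]]):
        logger.warning("expression tie at the top-%d boundary broken by gene-id order", n)
    return genes[:n]


def write_probability_table(path: str, cpt: ConditionalProbabilityTable) -> None:
    with open(path, "w") as fh:
        fh.write(f"# population_mean\t{cpt.population_mean:.10g}\n")
        fh.write(f"# n_genes\t{cpt.n_genes}\n")
        cpt.bins.to_csv(fh, sep="\t", index=False, lineterminator="\n")
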