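"""Synthetic chromatin-interactome generator with planted structure.

The generator emits every input the pipeline consumes — significant loops,
accessibility peaks, TSS models, chromatin-state tracks, bulk/nascent
expression and a single-cell matrix — with the statistical structure the
analysis assumes, so each stage is testable end to end without external
data:

* the genome is tiled into per-gene *territories* of ``territory_bins``
  bins, so each promoter's interconnected domain stays a distinct
  component instead of collapsing into one genome-wide blob;
* memory-gene promoters are wired through many low-contact-count edges,
  responsive promoters through few high-count edges (edge counts Poisson,
  contact counts shifted Poisson with minimum 1);
* super-enhancer states are planted on memory partner bins with elevated
  probability, and SE partners of the same promoter interact with each
  other at high contact counts (super-enhancer cliques), so the SE state
  resists erosion inside memory domains;
* planted hub CREs receive extra edges within a local window of
  neighbouring territories;
* bulk expression is drawn with log-mean increasing in promoter
  connectivity (``expression_coupling`` is the slope on log1p
  connectivity);
* nascent RNA follows a three-condition primed/naive design with per-class
  condition means and per-sample spike-in factors.

Every draw flows from one seeded generator, so an identical seed yields a
byte-identical bundle on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .genome_io import (
    BinId,
    BinScheme,
    ExpressionTable,
    GenomicInterval,
    LoopRecord,
    StateInterval,
    TSSRecord,
    write_expression,
    write_intervals,
    write_tss,
)
from .icd import ResponseClass


@dataclass
class NascentDesign:
    """Per-class nascent condition means and per-sample spike-in factors."""

    class_means: dict[str, tuple[float, float, float]] = dc_field(
        default_factory=lambda: {
            "memory": (10.0, 25.0, 60.0),
            "responsive": (10.0, 25.0, 27.0),
            "other": (10.0, 10.0, 10.0),
        }
    )
    conditions: tuple[str, str, str] = ("naive_veh", "naive_atRA", "primed_atRA")
    n_replicates: int = 2
    spikein_factors: tuple[float, ...] = (1.0, 1.1, 0.9, 1.05, 1.2, 0.8)
    pseudocount: float = 0.1


@dataclass
class SimulationParams:
    seed: int = 1
    bin_size: int = 10_000
    n_chromosomes: int = 1
    chrom_length: int | None = None  # derived from gene count when None
    territory_bins: int = 16
    n_memory_genes: int = 100
    n_responsive_genes: int = 100
    n_other_genes: int = 100
    memory_edge_count_mean: float = 8.0
    responsive_edge_count_mean: float = 2.0
    other_edge_count_mean: float = 3.0
    memory_edge_weight_mean: float = 2.0
    responsive_edge_weight_mean: float = 8.0
    other_edge_weight_mean: float = 4.0
    n_hub_cres: int = 10
    hub_extra_edges: int = 20
    hub_window_territories: int = 2
    expression_coupling: float = 1.0
    baseline_expression: float = 20.0
    noise_dispersion: float = 0.1
    se_on_memory_prob: float = 0.6
    se_background_prob: float = 0.1
    memory_breadth_mean: float = 4000.0
    other_breadth_mean: float = 1000.0
    decoy_loop_fraction: float = 0.1
    n_cells: int = 80
    nascent_design: NascentDesign = dc_field(default_factory=NascentDesign)

    @property
    def n_genes(self) -> int:
        return self.n_memory_genes + self.n_responsive_genes + self.n_other_genes

    def validate(self) -> None:
        if min(
            self.n_memory_genes, self.n_responsive_genes, self.n_other_genes
        ) < 0:
            raise ValueError("gene counts must be non-negative")
        if self.n_genes == 0:
            raise ValueError("need at least one gene")
        if self.territory_bins < 3:
            raise ValueError("territory_bins must be >= 3")
        if not self.memory_edge_count_mean > self.responsive_edge_count_mean:
            import warnings

            warnings.warn(
                "memory_edge_count_mean should exceed responsive_edge_count_mean"
            )
        if not self.memory_edge_weight_mean < self.responsive_edge_weight_mean:
            import warnings

            warnings.warn(
                "memory_edge_weight_mean should be below responsive_edge_weight_mean"
            )


@dataclass
class SyntheticBundle:
    """All generated inputs, in memory, plus ground truth."""

    params: SimulationParams
    scheme: BinScheme
    loops: list[LoopRecord]
    decoy_loops: list[tuple]  # raw BEDPE rows above the q threshold
    atac_peaks: list[GenomicInterval]
    tss: list[TSSRecord]
    states: list[StateInterval]
    super_enhancers: list[GenomicInterval]
    broad_peaks: list[GenomicInterval]
    cre_set: list[GenomicInterval]
    expression: ExpressionTable
    nascent: ExpressionTable
    cell_matrix: pd.DataFrame
    truth: pd.DataFrame  # gene, class, chrom, promoter_bin, connectivity
    hub_bins: list[BinId]
    paths: dict[str, str] = dc_field(default_factory=dict)

    def truth_labels(self) -> dict[str, str]:
        return dict(zip(self.truth["gene"], self.truth["class"]))

    def write(self, out_dir: str | Path) -> dict[str, str]:
        """Write the bundle to ``out_dir`` and record relative paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "loops": "loops.bedpe",
            "atac_peaks": "atac_peaks.bed",
            "tss": "tss.tsv",
            "states": "states.bed",
            "super_enhancers": "superenhancers.bed",
            "broad_peaks": "broad_h3k4me3.bed",
            "cre_set": "cre.bed",
            "expression": "expression.tsv",
            "nascent": "nascent.tsv",
            "nascent_samples": "nascent_samples.tsv",
            "cell_matrix": "cells.tsv",
            "truth": "truth.tsv",
            "manifest": "manifest.yaml",
        }
        # loops: significant records plus decoy rows that fail the q filter
        with open(out / paths["loops"], "w") as fh:
            for lp in self.loops:
                fh.write(
                    f"{lp.bin1.chrom}\t{lp.bin1.start}\t{lp.bin1.end}\t"
                    f"{lp.bin2.chrom}\t{lp.bin2.start}\t{lp.bin2.end}\t"
                    f"{lp.contact_count}\t{lp.q_value:.6g}\n"
                )
            for row in self.decoy_loops:
                fh.write("\t".join(str(x) for x in row) + "\n")
        write_intervals(out / paths["atac_peaks"], self.atac_peaks)
        write_tss(out / paths["tss"], self.tss)
        write_intervals(out / paths["states"], self.states)
        write_intervals(out / paths["super_enhancers"], self.super_enhancers)
        write_intervals(out / paths["broad_peaks"], self.broad_peaks)
        write_intervals(out / paths["cre_set"], self.cre_set)
        write_expression(out / paths["expression"], self.expression)
        write_expression(out / paths["nascent"], self.nascent)
        with open(out / paths["nascent_samples"], "w") as fh:
            fh.write("sample\tcondition\tspikein_factor\n")
            for sample in self.nascent.samples:
                cond = self.nascent.conditions[sample]
                factor = self.nascent.spikein_factors[sample]
                fh.write(f"{sample}\t{cond}\t{factor}\n")
        cells = self.cell_matrix.copy()
        cells.index.name = "gene"
        cells.to_csv(out / paths["cell_matrix"], sep="\t", lineterminator="\n")
        self.truth.to_csv(out / paths["truth"], sep="\t", index=False, lineterminator="\n")
        manifest = {
            "seed": self.params.seed,
            "bin_size": self.params.bin_size,
            "chrom_sizes": {k: int(v) for k, v in self.scheme.chrom_sizes.items()},
            "paths": paths,
            "params": _params_dict(self.params),
        }
        with open(out / paths["manifest"], "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        self.paths = paths
        return paths


def _params_dict(params: SimulationParams) -> dict:
    d = asdict(params)
    d["nascent_design"]["class_means"] = {
        k: list(v) for k, v in d["nascent_design"]["class_means"].items()
    }
    d["nascent_design"]["conditions"] = list(d["nascent_design"]["conditions"])
    d["nascent_design"]["spikein_factors"] = list(
        d["nascent_design"]["spikein_factors"]
    )
    return d


def _shifted_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Integer draws >= 1 with the requested mean (1 + Poisson(mean - 1))."""
    lam = max(mean - 1.0, 0.0)
    return 1 + rng.poisson(lam, size=size)


def simulate(params: SimulationParams | None = None, out_dir: str | Path | None = None) -> SyntheticBundle:
    """Generate a fully consistent synthetic input bundle.

    See the module docstring for the planted structure.  When ``out_dir``
    is given the bundle is also written to disk in the exact dialects the
    readers parse.
    """
    params = params or SimulationParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    bs = params.bin_size
    tb = params.territory_bins
    n_genes = params.n_genes

    # --- genome layout: one territory per gene -------------------------------
    per_chrom = -(-n_genes // params.n_chromosomes)
    needed_len = per_chrom * tb * bs
    if params.chrom_length is not None:
        if params.chrom_length < needed_len:
            raise ValueError(
                f"genome too small: need {needed_len} bp per chromosome for "
                f"{n_genes} genes, got {params.chrom_length}"
            )
        chrom_len = params.chrom_length
    else:
        chrom_len = needed_len
    chrom_sizes = {
        f"chr{i + 1}": chrom_len for i in range(params.n_chromosomes)
    }
    scheme = BinScheme(bin_size=bs, chrom_sizes=chrom_sizes)

    classes = (
        ["memory"] * params.n_memory_genes
        + ["responsive"] * params.n_responsive_genes
        + ["other"] * params.n_other_genes
    )
    classes = [classes[i] for i in rng.permutation(n_genes)]
    genes = [f"g{i:04d}" for i in range(n_genes)]

    territory_of: dict[str, tuple[str, int]] = {}  # gene -> (chrom, first bin k)
    for i, gene in enumerate(genes):
        chrom = f"chr{i // per_chrom + 1}"
        k0 = (i % per_chrom) * tb
        territory_of[gene] = (chrom, k0)

    # --- promoters and TSS ----------------------------------------------------
    tss_records: list[TSSRecord] = []
    promoter_bin: dict[str, BinId] = {}
    strands = rng.choice(["+", "-"], size=n_genes)
    for gene, strand in zip(genes, strands):
        chrom, k0 = territory_of[gene]
        pk = k0 + 1
        tss = pk * bs + bs // 2  # mid-bin, so the promoter stays inside the bin
        tss_records.append(TSSRecord(gene, chrom, int(tss), str(strand)))
        promoter_bin[gene] = (chrom, pk)

    # --- wiring ---------------------------------------------------------------
    edge_count_mean = {
        "memory": params.memory_edge_count_mean,
        "responsive": params.responsive_edge_count_mean,
        "other": params.other_edge_count_mean,
    }
    edge_weight_mean = {
        "memory": params.memory_edge_weight_mean,
        "responsive": params.responsive_edge_weight_mean,
        "other": params.other_edge_weight_mean,
    }
    se_prob = {
        "memory": params.se_on_memory_prob,
        "responsive": params.se_background_prob,
        "other": params.se_background_prob,
    }

    edges: dict[tuple[BinId, BinId], int] = {}

    def add_edge(a: BinId, b: BinId, w: int) -> None:
        if a == b:
            return
        key = (a, b) if a <= b else (b, a)
        edges[key] = edges.get(key, 0) + int(w)

    se_bins: set[BinId] = set()
    partner_bins: set[BinId] = set()
    partners_of: dict[str, list[BinId]] = {}
    for gene, cls in zip(genes, classes):
        chrom, k0 = territory_of[gene]
        pbin = promoter_bin[gene]
        candidates = [k0 + j for j in range(tb) if k0 + j != pbin[1]]
        n_e = max(1, int(rng.poisson(edge_count_mean[cls])))
        n_e = min(n_e, len(candidates))
        picked = rng.choice(candidates, size=n_e, replace=False)
        weights = _shifted_poisson(rng, edge_weight_mean[cls], n_e)
        gene_partners: list[BinId] = []
        for k, w in zip(sorted(int(k) for k in picked), weights):
            partner = (chrom, k)
            add_edge(pbin, partner, int(w))
            gene_partners.append(partner)
            partner_bins.add(partner)
            if rng.random() < se_prob[cls]:
                se_bins.add(partner)
        partners_of[gene] = gene_partners
        # super-enhancer cliques: SE partners of one promoter interact with
        # each other at high contact counts
        gene_se = [p for p in gene_partners if p in se_bins]
        if len(gene_se) >= 2:
            chain_w = _shifted_poisson(
                rng, params.responsive_edge_weight_mean, len(gene_se) - 1
            )
            for (a, b), w in zip(zip(gene_se, gene_se[1:]), chain_w):
                add_edge(a, b, int(w))

    # --- planted hub CREs -----------------------------------------------------
    hub_bins: list[BinId] = []
    partner_list = sorted(partner_bins)
    if params.n_hub_cres > 0 and partner_list:
        idx = rng.choice(
            len(partner_list),
            size=min(params.n_hub_cres, len(partner_list)),
            replace=False,
        )
        hub_bins = [partner_list[i] for i in sorted(int(i) for i in idx)]
        window = params.hub_window_territories * tb
        for hub in hub_bins:
            chrom, k = hub
            max_k = scheme.n_bins(chrom) - 1
            lo, hi = max(0, k - window), min(max_k, k + window)
            candidates = [j for j in range(lo, hi + 1) if j != k]
            n_extra = min(params.hub_extra_edges, len(candidates))
            picked = rng.choice(candidates, size=n_extra, replace=False)
            weights = _shifted_poisson(rng, params.other_edge_weight_mean, n_extra)
            for j, w in zip(sorted(int(j) for j in picked), weights):
                add_edge(hub, (chrom, j), int(w))

    # --- loop records ---------------------------------------------------------
    loops: list[LoopRecord] = []
    keys = sorted(edges)
    qvals = rng.uniform(1e-6, 0.009, size=len(keys))
    for (a, b), q in zip(keys, qvals):
        loops.append(
            LoopRecord(
                scheme.bin_interval(a),
                scheme.bin_interval(b),
                edges[(a, b)],
                float(q),
            )
        )
    # decoy rows above the significance threshold, to exercise the filter
    decoys: list[tuple] = []
    n_decoys = int(round(params.decoy_loop_fraction * len(loops)))
    for _ in range(n_decoys):
        chrom = f"chr{int(rng.integers(params.n_chromosomes)) + 1}"
        n_bins_c = scheme.n_bins(chrom)
        k1, k2 = sorted(int(x) for x in rng.choice(n_bins_c, size=2, replace=False))
        iv1, iv2 = scheme.bin_interval((chrom, k1)), scheme.bin_interval((chrom, k2))
        decoys.append(
            (
                iv1.chrom,
                iv1.start,
                iv1.end,
                iv2.chrom,
                iv2.start,
                iv2.end,
                int(rng.integers(1, 10)),
                round(float(rng.uniform(0.02, 0.5)), 6),
            )
        )

    # --- peaks, CREs, states --------------------------------------------------
    def bin_peak(b: BinId) -> GenomicInterval:
        start = b[1] * bs + bs // 2 - 250
        return GenomicInterval(b[0], start, start + 500)

    atac_peaks = [bin_peak(b) for b in sorted(partner_bins)]
    cre_set = [bin_peak(b) for b in hub_bins]
    super_enhancers = [
        scheme.bin_interval(b) for b in sorted(se_bins)
    ]
    states: list[StateInterval] = []
    for gene in genes:
        states.append(
            StateInterval(scheme.bin_interval(promoter_bin[gene]), "ActivePromoter")
        )
    for b in sorted(partner_bins - se_bins):
        label = "ActiveEnhancer" if rng.random() < 0.8 else "WeakEnhancer"
        states.append(StateInterval(scheme.bin_interval(b), label))

    # broad promoter H3K4me3 domains: wide at memory promoters, narrow elsewhere
    broad_peaks: list[GenomicInterval] = []
    for rec, cls in zip(tss_records, classes):
        mean_w = (
            params.memory_breadth_mean if cls == "memory" else params.other_breadth_mean
        )
        width = max(200, int(rng.normal(mean_w, mean_w * 0.15)))
        start = max(0, rec.tss - width // 2)
        broad_peaks.append(GenomicInterval(rec.chrom, start, start + width))

    # --- connectivity & expression -------------------------------------------
    conn: dict[str, int] = {g: 0 for g in genes}
    pbin_to_gene = {promoter_bin[g]: g for g in genes}
    for (a, b), w in edges.items():
        for endpoint in (a, b):
            g = pbin_to_gene.get(endpoint)
            if g is not None:
                conn[g] += w

    log_mean = np.log(params.baseline_expression) + params.expression_coupling * np.log1p(
        np.array([conn[g] for g in genes], dtype=float)
    )
    n_rep = 3
    expr_cols = {}
    for r in range(n_rep):
        lam = np.exp(log_mean + rng.normal(0, params.noise_dispersion, size=n_genes))
        expr_cols[f"rep{r + 1}"] = rng.poisson(lam).astype(float)
    expression = ExpressionTable(
        values=pd.DataFrame(expr_cols, index=pd.Index(genes, name="gene"))
    )

    # --- nascent RNA with spike-in design ------------------------------------
    design = params.nascent_design
    samples = []
    conditions: dict[str, str] = {}
    factors: dict[str, float] = {}
    i_sample = 0
    for cond in design.conditions:
        for r in range(design.n_replicates):
            name = f"{cond}_{r + 1}"
            samples.append(name)
            conditions[name] = cond
            factors[name] = float(
                design.spikein_factors[i_sample % len(design.spikein_factors)]
            )
            i_sample += 1
    nascent_vals = {}
    class_of = dict(zip(genes, classes))
    for name in samples:
        cond_i = design.conditions.index(conditions[name])
        true_means = np.array(
            [design.class_means[class_of[g]][cond_i] for g in genes], dtype=float
        )
        noisy = true_means * np.exp(
            rng.normal(0, params.noise_dispersion, size=n_genes)
        )
        nascent_vals[name] = np.round(noisy * factors[name], 4)
    nascent = ExpressionTable(
        values=pd.DataFrame(nascent_vals, index=pd.Index(genes, name="gene")),
        conditions=conditions,
        spikein_factors=factors,
    )

    # --- single-cell matrix ---------------------------------------------------
    cell_lam = np.array(
        [design.class_means[class_of[g]][2] for g in genes], dtype=float
    ) / 5.0
    cells = pd.DataFrame(
        rng.poisson(cell_lam[:, None], size=(n_genes, params.n_cells)).astype(float),
        index=pd.Index(genes, name="gene"),
        columns=[f"cell{j:03d}" for j in range(params.n_cells)],
    )

    truth = pd.DataFrame(
        {
            "gene": genes,
            "class": classes,
            "chrom": [territory_of[g][0] for g in genes],
            "promoter_bin": [promoter_bin[g][1] for g in genes],
            "connectivity": [conn[g] for g in genes],
            "n_partners": [len(partners_of[g]) for g in genes],
        }
    )

    bundle = SyntheticBundle(
        params=params,
        scheme=scheme,
        loops=loops,
        decoy_loops=decoys,
        atac_peaks=atac_peaks,
        tss=tss_records,
        states=states,
        super_enhancers=super_enhancers,
        broad_peaks=broad_peaks,
        cre_set=cre_set,
        expression=expression,
        nascent=nascent,
        cell_matrix=cells,
        truth=truth,
        hub_bins=hub_bins,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def truth_evaluation(
    bundle: SyntheticBundle, predicted: ResponseClass
) -> dict[str, dict[str, float]]:
    """Confusion counts and recovery rates of predicted response classes.

    The synthetic class ``other`` corresponds to a predicted
    ``nonresponsive`` label.
    """
    truth = bundle.truth_labels()
    alias = {"other": "nonresponsive"}
    truth = {g: alias.get(c, c) for g, c in truth.items()}
    pred = predicted.labels
    if set(truth) != set(pred):
        raise ValueError("gene sets of truth and prediction differ")
    out: dict[str, dict[str, float]] = {}
    for cls in ("memory", "responsive", "nonresponsive"):
        tp = sum(1 for g in truth if truth[g] == cls and pred[g] == cls)
        fp = sum(1 for g in truth if truth[g] != cls and pred[g] == cls)
        fn = sum(1 for g in truth if truth[g] == cls and pred[g] != cls)
        tn = len(truth) - tp - fp - fn
        out[cls] = {
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "tn": tn,
            "recall": tp / (tp + fn) if tp + fn else float("nan"),
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
        }
    return out
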