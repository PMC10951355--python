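"""Promoter/enhancer element definitions and bin annotation.

Promoters are windows around the TSS (default 2.5 kb upstream to 100 bp
downstream); regulatory elements (enhancers) are accessibility peaks that do
not fall within an exclusion window (default 1.5 kb) of any promoter.  Every
bin that participates in at least one significant loop is annotated with an
element class (P if it overlaps a promoter, else E if it overlaps an
enhancer, else "other"), its linked genes, an optional CRE-of-interest flag,
and a single chromatin state chosen by a fixed precedence hierarchy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .genome_io import (
    STATE_RANK,
    BinId,
    BinScheme,
    GenomicInterval,
    LoopRecord,
    StateInterval,
    TSSRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class ElementTable:
    """Promoter intervals per gene plus non-promoter enhancer peaks."""

    promoters: dict[str, GenomicInterval]
    enhancers: list[GenomicInterval]


@dataclass(frozen=True)
class BinInfo:
    """Annotation attached to one network bin."""

    element_class: str  # "P", "E" or "other"
    gene_ids: frozenset[str] = frozenset()
    state: str | None = None
    is_cre_of_interest: bool = False


@dataclass
class BinAnnotation:
    """Mapping from bin id to :class:`BinInfo` for all loop-participating bins."""

    scheme: BinScheme
    bins: dict[BinId, BinInfo] = field(default_factory=dict)

    def __getitem__(self, bin_id: BinId) -> BinInfo:
        return self.bins[bin_id]

    def __contains__(self, bin_id: BinId) -> bool:
        return bin_id in self.bins

    def __len__(self) -> int:
        return len(self.bins)


def _interval_tree(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def make_promoters(
    tss_records: Sequence[TSSRecord],
    up: int = 2500,
    down: int = 100,
    chrom_sizes: Mapping[str, int] | None = None,
) -> dict[str, GenomicInterval]:
    """Build promoter windows around each TSS.

    On the + strand the promoter is ``[tss - up, tss + down)``; on the -
    strand it is mirrored to ``[tss - down, tss + up)``.  Windows are
    clipped at 0 and, when ``chrom_sizes`` is given, at the chromosome end.
    """
    if up < 0 or down < 0:
        raise ValueError("up and down must be non-negative")
    if up + down == 0:
        raise ValueError("degenerate promoter: up + down must be > 0")
    promoters: dict[str, GenomicInterval] = {}
    for rec in tss_records:
        if rec.strand == "+":
            start, end = rec.tss - up, rec.tss + down
        else:
            start, end = rec.tss - down, rec.tss + up
        start = max(0, start)
        if chrom_sizes is not None:
            end = min(end, chrom_sizes[rec.chrom])
        if start >= end:
            raise ValidationError(
                f"promoter for {rec.gene_id} degenerate after clipping"
            )
        promoters[rec.gene_id] = GenomicInterval(rec.chrom, start, end, rec.strand)
    return promoters


def classify_elements(
    peaks: Sequence[GenomicInterval],
    promoters: Mapping[str, GenomicInterval],
    window: int = 1500,
) -> ElementTable:
    """Split accessibility peaks into enhancers vs promoter-overlapping peaks.

    A peak is an enhancer iff the peak extended by ``window`` on both sides
    intersects no promoter; peaks within the window are absorbed into the
    promoter class and do not appear as enhancers.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    trees = _interval_tree(promoters.values())
    enhancers: list[GenomicInterval] = []
    for peak in peaks:
        tree = trees.get(peak.chrom)
        ext_start = max(0, peak.start - window)
        ext_end = peak.end + window
        if tree is None or not tree.overlap(ext_start, ext_end):
            enhancers.append(peak)
    return ElementTable(promoters=dict(promoters), enhancers=enhancers)


def annotate_bins(
    scheme: BinScheme,
    loops: Sequence[LoopRecord],
    elements: ElementTable,
    cre_set: Sequence[GenomicInterval] = (),
) -> BinAnnotation:
    """Annotate every loop-participating bin with element class and genes.

    Class precedence is P > E > other: a bin overlapping both a promoter
    and an enhancer is P.  ``gene_ids`` collects every gene whose promoter
    intersects the bin; ``is_cre_of_interest`` flags overlap with
    ``cre_set`` (e.g. differentially accessible CREs).
    """
    promoter_trees: dict[str, IntervalTree] = {}
    for gene, iv in elements.promoters.items():
        promoter_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, gene)
    enhancer_trees = _interval_tree(elements.enhancers)
    cre_trees = _interval_tree(cre_set)

    bin_ids: set[BinId] = set()
    for lp in loops:
        bin_ids.add(scheme.validate_bin(lp.bin1))
        bin_ids.add(scheme.validate_bin(lp.bin2))

    annotation = BinAnnotation(scheme=scheme)
    for bin_id in sorted(bin_ids):
        iv = scheme.bin_interval(bin_id)
        genes = frozenset(
            hit.data
            for hit in promoter_trees.get(iv.chrom, IntervalTree()).overlap(
                iv.start, iv.end
            )
        )
        if genes:
            element_class = "P"
        elif enhancer_trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end):
            element_class = "E"
        else:
            element_class = "other"
        is_cre = bool(
            cre_trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end)
        )
        annotation.bins[bin_id] = BinInfo(
            element_class=element_class, gene_ids=genes, is_cre_of_interest=is_cre
        )
    return annotation


def assign_states(
    annotation: BinAnnotation,
    states: Sequence[StateInterval],
    super_enhancers: Sequence[GenomicInterval] = (),
    broad_peaks: Sequence[GenomicInterval] = (),
) -> BinAnnotation:
    """Assign exactly one chromatin state per bin by precedence.

    Super-enhancers outrank broad H3K4me3 peaks, which outrank the ChromHMM
    states (ActivePromoter down to Heterochromatin); bins overlapping no
    state interval are labelled Others.  Ties within a rank are resolved by
    the largest bin overlap, logged at debug level.
    """
    all_states = list(states)
    all_states += [StateInterval(iv, "SuperEnhancer") for iv in super_enhancers]
    all_states += [StateInterval(iv, "BroadPeak") for iv in broad_peaks]
    trees: dict[str, IntervalTree] = {}
    for st in all_states:
        trees.setdefault(st.interval.chrom, IntervalTree()).addi(
            st.interval.start, st.interval.end, st.state
        )

    out = BinAnnotation(scheme=annotation.scheme)
    for bin_id, info in annotation.bins.items():
        iv = annotation.scheme.bin_interval(bin_id)
        hits = trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end)
        best_state = "Others"
        best_rank = STATE_RANK["Others"]
        best_overlap = -1
        for hit in sorted(hits, key=lambda h: (STATE_RANK[h.data], h.begin, h.end)):
            rank = STATE_RANK[hit.data]
            overlap = min(hit.end, iv.end) - max(hit.begin, iv.start)
            if rank < best_rank or (rank == best_rank and overlap > best_overlap):
                if rank == best_rank and best_overlap >= 0:
                    logger.debug(
                        "bin %s: same-rank state tie resolved by largest overlap",
                        bin_id,
                    )
                best_state, best_rank, best_overlap = hit.data, rank, overlap
        out.bins[bin_id] = replace(info, state=best_state)
    return out


def breadth_at_tss(
    peaks: Sequence[GenomicInterval], tss_records: Sequence[TSSRecord]
) -> dict[str, int | None]:
    """Width of the (widest) peak covering each gene's TSS base, else None.

    Used to compare breadth of promoter H3K4me3 domains between gene
    groups; broad domains mark cell-identity genes.
    """
    trees = _interval_tree(peaks)
    out: dict[str, int | None] = {}
    for rec in tss_records:
        hits = trees.get(rec.chrom, IntervalTree()).overlap(rec.tss, rec.tss + 1)
        out[rec.gene_id] = max((h.end - h.begin for h in hits), default=None)
    return out


def read_bin_annotation(path: str, scheme: BinScheme) -> BinAnnotation:
    """Read back the TSV written by :func:`write_bin_annotation`."""
    annotation = BinAnnotation(scheme=scheme)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise ValidationError(f"{path}: not an annotated-bin table")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            chrom, start = fields[0], int(fields[1])
            bin_id = (chrom, start // scheme.bin_size)
            genes = frozenset(g for g in fields[4].split(",") if g)
            annotation.bins[bin_id] = BinInfo(
                element_class=fields[3],
                gene_ids=genes,
                state=fields[5] or None,
                is_cre_of_interest=bool(int(fields[6])),
            )
    return annotation


def write_bin_annotation(path: str, annotation: BinAnnotation) -> None:
    """Emit annotated bins as TSV (chrom, start, end, class, genes, state, is_cre)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tclass\tgenes\tstate\tis_cre\n")
        for bin_id in sorted(annotation.bins):
            iv = annotation.scheme.bin_interval(bin_id)
            info = annotation.bins[bin_id]
            genes = ",".join(sorted(info.gene_ids))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{info.element_class}\t"
                f"{genes}\t{info.state or ''}\t{int(info.is_cre_of_interest)}\n"
            )
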