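"""Genomic file formats and the binning scheme.

All coordinates are 0-based half-open (BED convention): an interval covers
positions ``start`` to ``end - 1``.  Bins are fixed-size genomic tiles
``[k*bin_size, (k+1)*bin_size)`` clipped to the chromosome end; a bin is
identified by ``(chrom, k)``.  These bins are the node unit of the chromatin
interaction network.

Readers accept the plain-text dialects the pipeline exchanges: BEDPE-like
loop tables (FitHiChIP-style significant-interaction output), BED3/BED4
interval files, and TSV expression matrices with an optional sample sheet
carrying condition labels and spike-in factors.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Closed vocabulary of chromatin states, ordered from highest to lowest
#: precedence for bin annotation (see :func:`icdomain.annotation.assign_states`).
STATE_HIERARCHY: tuple[str, ...] = (
    "SuperEnhancer",
    "BroadPeak",
    "ActivePromoter",
    "ActiveEnhancer",
    "WeakPromoter",
    "WeakEnhancer",
    "InactivePoisedPromoter",
    "Insulator",
    "PolycombRepressed",
    "Heterochromatin",
    "Others",
)

STATE_RANK: Mapping[str, int] = {s: i for i, s in enumerate(STATE_HIERARCHY)}

#: Default mapping from common segmentation labels to the state vocabulary.
DEFAULT_STATE_ALIASES: Mapping[str, str] = {
    "SuperEnhancer": "SuperEnhancer",
    "Super_Enhancer": "SuperEnhancer",
    "Super Enhancer": "SuperEnhancer",
    "BroadPeak": "BroadPeak",
    "Broad_Peak": "BroadPeak",
    "Broad Peak": "BroadPeak",
    "ActivePromoter": "ActivePromoter",
    "Active Promoter": "ActivePromoter",
    "Active_Promoter": "ActivePromoter",
    "TssA": "ActivePromoter",
    "ActiveEnhancer": "ActiveEnhancer",
    "Active Enhancer": "ActiveEnhancer",
    "Active_Enhancer": "ActiveEnhancer",
    "Enh": "ActiveEnhancer",
    "WeakPromoter": "WeakPromoter",
    "Weak Promoter": "WeakPromoter",
    "Weak_Promoter": "WeakPromoter",
    "WeakEnhancer": "WeakEnhancer",
    "Weak Enhancer": "WeakEnhancer",
    "Weak_Enhancer": "WeakEnhancer",
    "EnhWk": "WeakEnhancer",
    "InactivePoisedPromoter": "InactivePoisedPromoter",
    "Inactive/Poised Promoter": "InactivePoisedPromoter",
    "Poised Promoter": "InactivePoisedPromoter",
    "TssBiv": "InactivePoisedPromoter",
    "Insulator": "Insulator",
    "CTCF": "Insulator",
    "PolycombRepressed": "PolycombRepressed",
    "Polycomb-repressed": "PolycombRepressed",
    "ReprPC": "PolycombRepressed",
    "Heterochromatin": "Heterochromatin",
    "Het": "Heterochromatin",
    "Others": "Others",
}


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic region, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class StateInterval:
    """A segmentation interval carrying one chromatin-state label."""

    interval: GenomicInterval
    state: str

    def __post_init__(self) -> None:
        if self.state not in STATE_RANK:
            raise ValidationError(f"unknown chromatin state {self.state!r}")


BinId = tuple[str, int]


@dataclass(frozen=True)
class BinScheme:
    """Fixed-size genome tiling; bin identity is ``(chrom, k)``."""

    bin_size: int
    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValidationError(f"chromosome {chrom} has non-positive length")

    def n_bins(self, chrom: str) -> int:
        size = self.chrom_sizes[chrom]
        return -(-size // self.bin_size)

    def bin_index(self, chrom: str, pos: int) -> int:
        if chrom not in self.chrom_sizes:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValidationError(f"position {pos} outside {chrom}")
        return pos // self.bin_size

    def bin_interval(self, bin_id: BinId) -> GenomicInterval:
        chrom, k = bin_id
        start = k * self.bin_size
        end = min(start + self.bin_size, self.chrom_sizes[chrom])
        return GenomicInterval(chrom, start, end)

    def validate_bin(self, iv: GenomicInterval) -> BinId:
        """Snap an interval claimed to be a bin onto the scheme, or fail."""
        if iv.chrom not in self.chrom_sizes:
            raise ValidationError(f"unknown chromosome {iv.chrom!r}")
        if iv.start % self.bin_size != 0:
            raise ValidationError(
                f"bin start {iv.chrom}:{iv.start} not aligned to {self.bin_size} bp"
            )
        k = iv.start // self.bin_size
        expected = self.bin_interval((iv.chrom, k))
        if iv.end != expected.end:
            raise ValidationError(
                f"bin end {iv.end} does not match scheme (expected {expected.end})"
            )
        return (iv.chrom, k)


@dataclass(frozen=True)
class LoopRecord:
    """A significant chromatin contact between two ordered bins.

    ``contact_count`` is the pair's connectivity: the number of times this
    bin pair was sequenced in a contact.  ``q_value`` is the FDR from the
    loop caller.
    """

    bin1: GenomicInterval
    bin2: GenomicInterval
    contact_count: int
    q_value: float

    def __post_init__(self) -> None:
        if (self.bin1.chrom, self.bin1.start) == (self.bin2.chrom, self.bin2.start):
            raise ValidationError("self-loop (bin1 == bin2) rejected")
        if (self.bin1.chrom, self.bin1.start) > (self.bin2.chrom, self.bin2.start):
            raise ValidationError("bins out of order (bin1 must sort before bin2)")
        if self.contact_count < 1:
            raise ValidationError(f"contact_count {self.contact_count} < 1")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValidationError(f"q_value {self.q_value} outside [0, 1]")


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site: the first transcribed base of a gene."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if self.tss < 0:
            raise ValidationError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"TSS strand must be +/-, got {self.strand!r}")


@dataclass
class ExpressionTable:
    """Gene x sample expression values with optional spike-in factors.

    ``values`` is a DataFrame indexed by gene id with one column per sample;
    ``conditions`` maps sample -> condition label; ``spikein_factors`` maps
    sample -> positive scale factor and, when present, must cover every
    sample.  :meth:`normalized` divides each sample column by its factor.
    """

    values: pd.DataFrame
    conditions: Mapping[str, str] = field(default_factory=dict)
    spikein_factors: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValidationError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            dupes = sorted(self.values.index[self.values.index.duplicated()])
            raise ValidationError(f"duplicate gene ids: {dupes}")
        if self.spikein_factors is not None:
            missing = set(self.values.columns) - set(self.spikein_factors)
            if missing:
                raise ValidationError(
                    f"spike-in factors missing for samples: {sorted(missing)}"
                )
            for s, f in self.spikein_factors.items():
                if f <= 0:
                    raise ValidationError(f"non-positive spike-in factor for {s}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def normalized(self) -> pd.DataFrame:
        """Spike-in normalized values: raw / per-sample factor."""
        if self.spikein_factors is None:
            return self.values.copy()
        factors = pd.Series(
            {s: self.spikein_factors[s] for s in self.values.columns}, dtype=float
        )
        return self.values.div(factors, axis=1)

    def condition_means(self) -> pd.DataFrame:
        """Average normalized replicates per condition label."""
        if not self.conditions:
            raise ValidationError("no condition labels available")
        norm = self.normalized()
        groups: dict[str, list[str]] = {}
        for sample in norm.columns:
            cond = self.conditions.get(sample)
            if cond is None:
                raise ValidationError(f"sample {sample!r} has no condition label")
            groups.setdefault(cond, []).append(sample)
        return pd.DataFrame(
            {cond: norm[cols].mean(axis=1) for cond, cols in groups.items()}
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _loop_rows(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and not _is_number(row[1] if len(row) > 1 else ""):
                continue  # optional header
            yield lineno, row


def _is_number(s: str) -> bool:
    try:
        float(s)
    except (TypeError, ValueError):
        return False
    return True


def read_loops(
    path: str | Path,
    scheme: BinScheme,
    q_threshold: float = 0.01,
    allow_trans: bool = False,
) -> list[LoopRecord]:
    """Read a BEDPE-like loop table, keeping significant cis contacts.

    Expected columns: chrom1, start1, end1, chrom2, start2, end2,
    contact_count, q_value (tab-separated, optional header).  Records with
    ``q_value > q_threshold`` are dropped (default 0.01, the FDR cut used
    for significant loops).  Pair order is normalized so bin1 sorts before
    bin2, and duplicate pairs are merged by summing contact counts (keeping
    the smaller q).  Inter-chromosomal pairs are rejected unless
    ``allow_trans``.
    """
    merged: dict[tuple[BinId, BinId], LoopRecord] = {}
    for lineno, row in _loop_rows(Path(path)):
        if len(row) < 8:
            raise FormatError(f"{path}:{lineno}: expected >= 8 columns, got {len(row)}")
        try:
            c1, s1, e1, c2, s2, e2 = (
                row[0],
                int(row[1]),
                int(row[2]),
                row[3],
                int(row[4]),
                int(row[5]),
            )
            count = int(row[6])
            q = float(row[7])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if count < 0:
            raise ValidationError(f"{path}:{lineno}: negative contact count")
        if q > q_threshold:
            continue
        if c1 != c2 and not allow_trans:
            raise ValidationError(
                f"{path}:{lineno}: inter-chromosomal pair {c1}/{c2} "
                "(pass allow_trans=True to keep)"
            )
        try:
            b1 = GenomicInterval(c1, s1, e1)
            b2 = GenomicInterval(c2, s2, e2)
            id1 = scheme.validate_bin(b1)
            id2 = scheme.validate_bin(b2)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        if id2 < id1:
            b1, b2, id1, id2 = b2, b1, id2, id1
        key = (id1, id2)
        if key in merged:
            prev = merged[key]
            merged[key] = replace(
                prev,
                contact_count=prev.contact_count + count,
                q_value=min(prev.q_value, q),
            )
        else:
            merged[key] = LoopRecord(b1, b2, count, q)
    return [merged[k] for k in sorted(merged)]


def write_loops(path: str | Path, loops: Sequence[LoopRecord]) -> None:
    """Write loops as 8-column BEDPE (tab-separated, newline-terminated)."""
    with open(path, "w") as fh:
        for lp in loops:
            fh.write(
                f"{lp.bin1.chrom}\t{lp.bin1.start}\t{lp.bin1.end}\t"
                f"{lp.bin2.chrom}\t{lp.bin2.start}\t{lp.bin2.end}\t"
                f"{lp.contact_count}\t{lp.q_value:.6g}\n"
            )


def read_intervals(
    path: str | Path,
    kind: str = "peaks",
    aliases: Mapping[str, str] | None = None,
) -> list[GenomicInterval] | list[StateInterval]:
    """Read a BED3+ file as peaks or a BED4 segmentation as states.

    For ``kind="states"`` the 4th column label is mapped through an alias
    table onto the state vocabulary; unknown labels fall back to ``Others``
    with a logged warning.
    """
    if kind not in ("peaks", "states"):
        raise ValueError(f"kind must be 'peaks' or 'states', got {kind!r}")
    alias_map = dict(DEFAULT_STATE_ALIASES)
    if aliases:
        alias_map.update(aliases)
    out: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            if kind == "peaks":
                out.append(iv)
            else:
                if len(fields) < 4:
                    raise FormatError(
                        f"{path}:{lineno}: state BED requires a 4th label column"
                    )
                label = fields[3]
                state = alias_map.get(label)
                if state is None:
                    logger.warning(
                        "%s:%d: unknown state label %r mapped to Others",
                        path,
                        lineno,
                        label,
                    )
                    state = "Others"
                out.append(StateInterval(iv, state))
    return out


def write_intervals(
    path: str | Path, intervals: Sequence[GenomicInterval | StateInterval]
) -> None:
    with open(path, "w") as fh:
        for item in intervals:
            if isinstance(item, StateInterval):
                iv = item.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{item.state}\n")
            else:
                fh.write(f"{item.chrom}\t{item.start}\t{item.end}\n")


def read_tss(path: str | Path, dedup: str = "upstream") -> list[TSSRecord]:
    """Read a TSS table (gene, chrom, tss, strand).

    ``dedup="upstream"`` keeps the most upstream TSS per gene (smallest
    coordinate on +, largest on -); ``dedup="all"`` keeps every record.
    """
    if dedup not in ("upstream", "all"):
        raise ValueError(f"dedup must be 'upstream' or 'all', got {dedup!r}")
    records: list[TSSRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] in ("gene", "gene_id"):
                continue
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                records.append(
                    TSSRecord(fields[0], fields[1], int(fields[2]), fields[3])
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    if dedup == "all":
        return records
    best: dict[str, TSSRecord] = {}
    for rec in records:
        prev = best.get(rec.gene_id)
        if prev is None:
            best[rec.gene_id] = rec
            continue
        if rec.strand == "+":
            if rec.tss < prev.tss:
                best[rec.gene_id] = rec
        else:
            if rec.tss > prev.tss:
                best[rec.gene_id] = rec
    return [best[g] for g in sorted(best)]


def write_tss(path: str | Path, records: Sequence[TSSRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tchrom\ttss\tstrand\n")
        for rec in records:
            fh.write(f"{rec.gene_id}\t{rec.chrom}\t{rec.tss}\t{rec.strand}\n")


def read_expression(
    path: str | Path, sample_sheet: str | Path | None = None
) -> ExpressionTable:
    """Read a TSV expression matrix (gene id column first, samples after).

    An optional sample sheet (TSV: sample, condition, spikein_factor) adds
    condition labels and spike-in factors; factors must cover every sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError(f"duplicate gene ids: {dupes}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    conditions: dict[str, str] = {}
    factors: dict[str, float] | None = None
    if sample_sheet is not None:
        sheet = pd.read_csv(sample_sheet, sep="\t")
        required = {"sample", "condition"}
        if not required.issubset(sheet.columns):
            raise FormatError(f"{sample_sheet}: needs columns {sorted(required)}")
        conditions = dict(zip(sheet["sample"], sheet["condition"]))
        if "spikein_factor" in sheet.columns:
            factors = {
                s: float(f) for s, f in zip(sheet["sample"], sheet["spikein_factor"])
            }
    return ExpressionTable(values=df, conditions=conditions, spikein_factors=factors)


def write_expression(path: str | Path, table: ExpressionTable) -> None:
    out = table.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", lineterminator="\n")
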