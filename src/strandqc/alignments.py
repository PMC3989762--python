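"""Reading, classifying and filtering single-end alignments.

Reads are held column-wise in a :class:`ReadSet` (numpy arrays, sorted by
(chromosome, start)).  All coordinates are 0-based half-open; SAM input is
converted on load.  The 5' end of a read is its ``start`` on the forward
(Watson) strand and ``end - 1`` on the reverse (Crick) strand — every
downstream strand-shift computation anchors on that position, so the
convention is fixed here and nowhere else.

Read classes follow common ChIP-seq QC practice:

* *duplicate* — shares (chromosome, strand, 5' position) with another read;
  one read per position stack (highest mapping quality, then input order)
  stays unflagged.
* *multi-mapped* — mapping quality below a threshold (default 1, i.e. MAPQ 0,
  which BWA assigns to reads with several equally good placements).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam

__all__ = [
    "AlignedRead",
    "ReadSet",
    "QCWarning",
    "load_alignments",
    "mark_duplicates",
    "mark_multimapped",
    "compute_nrf",
    "nrf_flag",
    "apply_filters",
    "write_reads_bed",
]

# NRF guideline: a library is flagged when >= 20% of reads are duplicates
# at a depth of >= 10 million mapped reads.
NRF_DUP_FRACTION = 0.20
NRF_MIN_READS = 10_000_000

DEFAULT_MAPQ_THRESHOLD = 1


class QCWarning(UserWarning):
    """Non-fatal irregularity in a QC computation (degenerate metric etc.)."""


@dataclass(frozen=True)
class AlignedRead:
    """One single-end alignment (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"
    mapq: int
    duplicate: bool = False
    multimapped: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def read_length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


class ReadSet:
    """Column-wise container for aligned reads, sorted by (chromosome, start).

    Parameters
    ----------
    chrom_names
        Ordered chromosome names; ``chrom_code`` indexes into this tuple.
    chrom_code, start, end, is_reverse, mapq
        Per-read arrays (equal length).
    duplicate, multimapped
        Class flags; default all-False.
    provenance
        Ordered tuple of filter stages already applied, drawn from
        {"dedup", "blacklist"}.
    chrom_lengths
        Optional name -> length mapping (captured from the SAM header).
    """

    def __init__(
        self,
        chrom_names: Sequence[str],
        chrom_code: np.ndarray,
        start: np.ndarray,
        end: np.ndarray,
        is_reverse: np.ndarray,
        mapq: np.ndarray,
        duplicate: np.ndarray | None = None,
        multimapped: np.ndarray | None = None,
        provenance: tuple[str, ...] = (),
        chrom_lengths: Mapping[str, int] | None = None,
        duplicates_marked: bool = False,
        _sorted: bool = False,
    ) -> None:
        n = len(start)
        self.chrom_names = tuple(chrom_names)
        self.chrom_code = np.asarray(chrom_code, dtype=np.int32)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        self.is_reverse = np.asarray(is_reverse, dtype=bool)
        self.mapq = np.asarray(mapq, dtype=np.int16)
        self.duplicate = (
            np.zeros(n, dtype=bool) if duplicate is None else np.asarray(duplicate, bool)
        )
        self.multimapped = (
            np.zeros(n, dtype=bool) if multimapped is None else np.asarray(multimapped, bool)
        )
        self.provenance = tuple(provenance)
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else None
        self.duplicates_marked = duplicates_marked
        if np.any(self.start >= self.end):
            raise ValueError("every read must satisfy start < end")
        if not _sorted:
            order = np.lexsort((self.start, self.chrom_code))
            self._reorder(order)

    def _reorder(self, order: np.ndarray) -> None:
        for name in ("chrom_code", "start", "end", "is_reverse", "mapq", "duplicate", "multimapped"):
            setattr(self, name, getattr(self, name)[order])

    # ------------------------------------------------------------------
    @property
    def total_count(self) -> int:
        return len(self.start)

    def __len__(self) -> int:
        return self.total_count

    @property
    def five_prime(self) -> np.ndarray:
        return np.where(self.is_reverse, self.end - 1, self.start)

    @property
    def read_length(self) -> np.ndarray:
        return self.end - self.start

    @property
    def n_duplicated(self) -> int:
        return int(self.duplicate.sum())

    @property
    def n_multimapped(self) -> int:
        return int(self.multimapped.sum())

    def class_counts(self) -> dict[str, int]:
        return {
            "all": self.total_count,
            "duplicated": self.n_duplicated,
            "multimapped": self.n_multimapped,
        }

    def chroms_present(self) -> list[str]:
        codes = np.unique(self.chrom_code)
        return [self.chrom_names[c] for c in codes]

    def per_chrom(self) -> Iterator[tuple[str, slice]]:
        """Yield (chromosome name, slice into the sorted arrays)."""
        if self.total_count == 0:
            return
        bounds = np.searchsorted(self.chrom_code, np.arange(len(self.chrom_names) + 1))
        for code, name in enumerate(self.chrom_names):
            lo, hi = bounds[code], bounds[code + 1]
            if hi > lo:
                yield name, slice(int(lo), int(hi))

    def subset(self, mask: np.ndarray, provenance: tuple[str, ...] | None = None) -> "ReadSet":
        return ReadSet(
            self.chrom_names,
            self.chrom_code[mask],
            self.start[mask],
            self.end[mask],
            self.is_reverse[mask],
            self.mapq[mask],
            self.duplicate[mask],
            self.multimapped[mask],
            provenance=self.provenance if provenance is None else provenance,
            chrom_lengths=self.chrom_lengths,
            duplicates_marked=self.duplicates_marked,
            _sorted=True,
        )

    def copy(self) -> "ReadSet":
        return self.subset(np.ones(self.total_count, dtype=bool))

    def iter_reads(self) -> Iterator[AlignedRead]:
        for i in range(self.total_count):
            yield AlignedRead(
                chrom=self.chrom_names[self.chrom_code[i]],
                start=int(self.start[i]),
                end=int(self.end[i]),
                strand="-" if self.is_reverse[i] else "+",
                mapq=int(self.mapq[i]),
                duplicate=bool(self.duplicate[i]),
                multimapped=bool(self.multimapped[i]),
            )

    @classmethod
    def from_reads(
        cls,
        reads: Iterable[AlignedRead],
        chrom_names: Sequence[str] | None = None,
        chrom_lengths: Mapping[str, int] | None = None,
    ) -> "ReadSet":
        reads = list(reads)
        if chrom_names is None:
            seen: dict[str, None] = {}
            for r in reads:
                seen.setdefault(r.chrom, None)
            chrom_names = sorted(seen)
        index = {name: i for i, name in enumerate(chrom_names)}
        return cls(
            chrom_names,
            np.array([index[r.chrom] for r in reads], dtype=np.int32),
            np.array([r.start for r in reads], dtype=np.int64),
            np.array([r.end for r in reads], dtype=np.int64),
            np.array([r.strand == "-" for r in reads], dtype=bool),
            np.array([r.mapq for r in reads], dtype=np.int16),
            np.array([r.duplicate for r in reads], dtype=bool),
            np.array([r.multimapped for r in reads], dtype=bool),
            chrom_lengths=chrom_lengths,
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"ReadSet({self.total_count} reads, {len(self.chroms_present())} chroms, "
            f"provenance={list(self.provenance)})"
        )


# ----------------------------------------------------------------------
# Loading


def load_alignments(
    path: str | Path,
    chrom_subset: Sequence[str] | None = None,
    effective_read_length: int | None = None,
) -> ReadSet:
    """Load mapped, primary, single-end alignments from a SAM/BAM file.

    Unmapped (0x4), secondary (0x100) and supplementary (0x800) records are
    dropped.  When ``chrom_subset`` is given only those chromosomes are kept
    (every requested name must exist in the header).  When
    ``effective_read_length`` is given each read is re-trimmed *in
    coordinates* to that length, anchored at its 5' end — forward reads keep
    ``start``, reverse reads keep ``end`` — which reproduces the geometry of
    trimming all reads to a common length before alignment.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        header_names = list(fh.references)
        header_lengths = dict(zip(fh.references, fh.lengths))
        if chrom_subset is not None:
            missing = [c for c in chrom_subset if c not in header_names]
            if len(missing) == len(list(chrom_subset)):
                raise ValueError(
                    "none of the requested chromosomes are in the file header: "
                    + ", ".join(missing)
                )
            if missing:
                warnings.warn(
                    "requested chromosomes absent from header: " + ", ".join(missing),
                    QCWarning,
                    stacklevel=2,
                )
            keep = [c for c in chrom_subset if c in header_names]
        else:
            keep = header_names
        keep_set = set(keep)

        chrom_code: list[int] = []
        start: list[int] = []
        end: list[int] = []
        is_reverse: list[bool] = []
        mapq: list[int] = []
        index = {name: i for i, name in enumerate(keep)}
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            name = rec.reference_name
            if name not in keep_set:
                continue
            chrom_code.append(index[name])
            start.append(rec.reference_start)
            end.append(rec.reference_end)
            is_reverse.append(rec.is_reverse)
            mapq.append(rec.mapping_quality)

    rs = ReadSet(
        keep,
        np.array(chrom_code, dtype=np.int32),
        np.array(start, dtype=np.int64),
        np.array(end, dtype=np.int64),
        np.array(is_reverse, dtype=bool),
        np.array(mapq, dtype=np.int16),
        chrom_lengths={c: header_lengths[c] for c in keep},
    )
    if effective_read_length is not None:
        rs = set_effective_read_length(rs, effective_read_length)
    return rs


def set_effective_read_length(reads: ReadSet, length: int) -> ReadSet:
    """Trim every read span to ``length`` bp, anchored at the 5' end."""
    if length <= 0:
        raise ValueError("effective read length must be positive")
    out = reads.copy()
    fwd = ~out.is_reverse
    out.end = np.where(fwd, out.start + length, out.end)
    out.start = np.where(fwd, out.start, out.end - length)
    if np.any(out.start < 0):
        raise ValueError("effective read length pushes a reverse read before position 0")
    return out


# ----------------------------------------------------------------------
# Classification


def _dedup_key(reads: ReadSet) -> tuple[np.ndarray, ...]:
    return (reads.chrom_code, reads.is_reverse, reads.five_prime)


def mark_duplicates(reads: ReadSet) -> ReadSet:
    """Flag positional duplicates: reads sharing (chrom, strand, 5' position).

    Within each stack exactly one read stays unflagged — the one with the
    highest mapping quality, ties broken by input (sorted) order.  No reads
    are removed.
    """
    out = reads.copy()
    n = out.total_count
    if n == 0:
        out.duplicates_marked = True
        return out
    chrom, rev, fp = _dedup_key(out)
    # survivor-first order within each (chrom, strand, 5') group
    order = np.lexsort((np.arange(n), -out.mapq.astype(np.int32), fp, rev, chrom))
    c_o, r_o, f_o = chrom[order], rev[order], fp[order]
    new_group = np.ones(n, dtype=bool)
    new_group[1:] = (c_o[1:] != c_o[:-1]) | (r_o[1:] != r_o[:-1]) | (f_o[1:] != f_o[:-1])
    dup_sorted = ~new_group
    duplicate = np.empty(n, dtype=bool)
    duplicate[order] = dup_sorted
    out.duplicate = duplicate
    out.duplicates_marked = True
    return out


def mark_multimapped(reads: ReadSet, mapq_threshold: int = DEFAULT_MAPQ_THRESHOLD) -> ReadSet:
    """Flag reads with mapping quality below ``mapq_threshold``."""
    if mapq_threshold < 0:
        raise ValueError("mapq_threshold must be >= 0")
    out = reads.copy()
    out.multimapped = out.mapq < mapq_threshold
    return out


# ----------------------------------------------------------------------
# Library complexity


def nrf_flag(nrf: float, total_count: int) -> bool:
    """True when the library fails the duplication guideline.

    The guideline flags libraries in which at least 20% of reads are
    duplicates at a depth of at least 10 million reads; below that depth a
    high duplicate fraction is not by itself evidence of low complexity.
    """
    # 1e-12 guards the >= comparison against float round-off at the boundary
    return (1.0 - nrf) >= NRF_DUP_FRACTION - 1e-12 and total_count >= NRF_MIN_READS


def compute_nrf(reads: ReadSet) -> tuple[float, bool]:
    """Non-Redundant Fraction: distinct (chrom, strand, 5') tuples / reads.

    Returns ``(nrf, failed)`` where ``failed`` applies the 20%-at-10M rule.
    """
    n = reads.total_count
    if n == 0:
        raise ValueError("cannot compute NRF of an empty ReadSet")
    chrom, rev, fp = _dedup_key(reads)
    key = np.stack([chrom.astype(np.int64), rev.astype(np.int64), fp], axis=1)
    distinct = len(np.unique(key, axis=0))
    nrf = distinct / n
    return nrf, nrf_flag(nrf, n)


# ----------------------------------------------------------------------
# Filtering


def reads_overlapping_mask(reads: ReadSet, intervals) -> np.ndarray:
    """Boolean mask of reads whose aligned span overlaps any interval (>=1 bp)."""
    from .intervals import IntervalSet, merge  # local import to avoid a cycle

    iset: IntervalSet = intervals if intervals.is_merged else merge(intervals)
    mask = np.zeros(reads.total_count, dtype=bool)
    per_chrom = iset.chrom_arrays()
    for name, sl in reads.per_chrom():
        if name not in per_chrom:
            continue
        istart, iend = per_chrom[name]
        a, b = reads.start[sl], reads.end[sl]
        # merged+sorted intervals: read [a,b) overlaps one iff the first
        # interval with end > a starts before b
        idx = np.searchsorted(iend, a, side="right")
        hit = (idx < len(istart)) & (istart[np.minimum(idx, len(istart) - 1)] < b)
        mask[sl] = hit
    return mask


def apply_filters(
    reads: ReadSet,
    stages: Sequence[str],
    blacklist=None,
) -> ReadSet:
    """Apply filter stages in order; result is order-independent.

    ``dedup`` removes duplicate-flagged reads (marking them first if
    needed); ``blacklist`` removes reads whose span overlaps any blacklist
    interval.  Provenance is extended with each applied stage.
    """
    valid = {"dedup", "blacklist"}
    unknown = set(stages) - valid
    if unknown:
        raise ValueError(f"unknown filter stages: {sorted(unknown)}")
    if "blacklist" in stages and blacklist is None:
        raise ValueError("blacklist stage requested but no blacklist IntervalSet given")
    out = reads
    for stage in stages:
        if stage == "dedup":
            if not out.duplicates_marked:
                out = mark_duplicates(out)
            out = out.subset(~out.duplicate, provenance=out.provenance + ("dedup",))
        elif stage == "blacklist":
            mask = reads_overlapping_mask(out, blacklist)
            out = out.subset(~mask, provenance=out.provenance + ("blacklist",))
    return out


# ----------------------------------------------------------------------
# Export


def write_reads_bed(reads: ReadSet, path: str | Path) -> None:
    """Export as BED6 (name = class flags, score = MAPQ)."""
    with open(path, "w") as fh:
        for r in reads.iter_reads():
            labels = []
            if r.duplicate:
                labels.append("duplicate")
            if r.multimapped:
                labels.append("multimapped")
            name = ",".join(labels) or "read"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{r.mapq}\t{r.strand}\n")
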