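"""Interval algebra over blacklists and peak sets.

Blacklists (curated regions of experiment-independent artifact signal) and
peak calls both arrive as BED files; this module provides the small interval
algebra the QC analytics need — merging, pairwise and three-way overlap
statistics, per-class composition, per-region read counts / RPKM, and fold
enrichment of reads over a region set.

Coordinates are 0-based half-open (BED native).  An :class:`IntervalSet`
keeps its intervals in a pandas DataFrame with columns
``chrom, start, end, label``; the ``label`` column carries the region class
(e.g. a repeat class from the BED name column) and may be empty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "OverlapSummary",
    "load_bed",
    "write_bed",
    "merge",
    "intersect",
    "overlap_summary",
    "threeway_venn",
    "class_composition",
    "count_reads_in_set",
    "rpkm_per_region",
    "fold_enrichment",
    "load_chrom_sizes",
]

COLUMNS = ["chrom", "start", "end", "label"]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalSet:
    """Named set of labelled genomic intervals."""

    def __init__(self, name: str, df: pd.DataFrame, merged: bool = False) -> None:
        self.name = name
        df = df.reset_index(drop=True)[COLUMNS].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["label"] = df["label"].fillna("").astype(str)
        if (df["start"] >= df["end"]).any():
            bad = df.index[(df["start"] >= df["end"])][0]
            raise ValueError(f"interval {bad} has start >= end")
        self.df = df
        self.merged = merged

    # ------------------------------------------------------------------
    @classmethod
    def from_intervals(
        cls, name: str, intervals: Sequence[GenomicInterval], merged: bool = False
    ) -> "IntervalSet":
        df = pd.DataFrame(
            [(iv.chrom, iv.start, iv.end, iv.label) for iv in intervals], columns=COLUMNS
        )
        if not len(intervals):
            df = pd.DataFrame({c: [] for c in COLUMNS})
        return cls(name, df, merged=merged)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def is_merged(self) -> bool:
        return self.merged

    @property
    def region_count(self) -> int:
        return len(self.df)

    @property
    def total_bp(self) -> int:
        """Genomic bp covered (overlaps collapsed if the set is unmerged)."""
        if self.merged:
            return int((self.df["end"] - self.df["start"]).sum())
        return merge(self).total_bp

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.label)
            for r in self.df.itertuples(index=False)
        ]

    def chrom_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends), sorted by start."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.df.groupby("chrom", sort=True):
            sub = sub.sort_values(["start", "end"])
            out[str(chrom)] = (
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
            )
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"IntervalSet({self.name!r}, {len(self)} regions, merged={self.merged})"


# ----------------------------------------------------------------------
# BED I/O


def load_bed(path: str | Path, name: str | None = None) -> IntervalSet:
    """Load BED3+ intervals; the name column (4th), if present, becomes the label."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
            if start < 0:
                raise ValueError(f"{path}: line {lineno}: negative start")
            label = parts[3] if len(parts) > 3 else ""
            rows.append((parts[0], start, end, label))
    df = pd.DataFrame(rows, columns=COLUMNS) if rows else pd.DataFrame({c: [] for c in COLUMNS})
    return IntervalSet(name or path.stem, df)


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in iset.df.itertuples(index=False):
            if r.label:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def load_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV (name, length) -> dict."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 'name length'")
            sizes[parts[0]] = int(parts[1])
    return sizes


# ----------------------------------------------------------------------
# Algebra


def merge(iset: IntervalSet) -> IntervalSet:
    """Collapse overlapping and book-ended intervals.

    Labels of collapsed intervals are joined with ',' over distinct values
    (in first-seen order); coverage in bp is preserved exactly.
    """
    rows = []
    for chrom, sub in iset.df.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"])
        cur_s = cur_e = None
        labels: list[str] = []
        for r in sub.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e, labels = r.start, r.end, [r.label] if r.label else []
            elif r.start <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, r.end)
                if r.label and r.label not in labels:
                    labels.append(r.label)
            else:
                rows.append((chrom, cur_s, cur_e, ",".join(labels)))
                cur_s, cur_e, labels = r.start, r.end, [r.label] if r.label else []
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, ",".join(labels)))
    df = pd.DataFrame(rows, columns=COLUMNS) if rows else pd.DataFrame({c: [] for c in COLUMNS})
    return IntervalSet(iset.name, df, merged=True)


def _ensure_merged(iset: IntervalSet) -> IntervalSet:
    return iset if iset.is_merged else merge(iset)


def intersect(a: IntervalSet, b: IntervalSet, name: str | None = None) -> IntervalSet:
    """bp-level intersection of two (internally merged) sets."""
    am, bm = _ensure_merged(a), _ensure_merged(b)
    bmap = bm.chrom_arrays()
    rows = []
    for chrom, (astart, aend) in am.chrom_arrays().items():
        if chrom not in bmap:
            continue
        bstart, bend = bmap[chrom]
        i = j = 0
        while i < len(astart) and j < len(bstart):
            s = max(astart[i], bstart[j])
            e = min(aend[i], bend[j])
            if s < e:
                rows.append((chrom, int(s), int(e), ""))
            if aend[i] <= bend[j]:
                i += 1
            else:
                j += 1
    df = pd.DataFrame(rows, columns=COLUMNS) if rows else pd.DataFrame({c: [] for c in COLUMNS})
    return IntervalSet(name or f"{a.name}&{b.name}", df, merged=True)


def _regions_hitting(query: IntervalSet, target: IntervalSet) -> int:
    """Number of query regions overlapping (>=1 bp) any target region."""
    tmap = _ensure_merged(target).chrom_arrays()
    hits = 0
    for chrom, sub in query.df.groupby("chrom", sort=False):
        if chrom not in tmap:
            continue
        tstart, tend = tmap[chrom]
        qs = sub["start"].to_numpy(np.int64)
        qe = sub["end"].to_numpy(np.int64)
        idx = np.searchsorted(tend, qs, side="right")
        ok = (idx < len(tstart)) & (tstart[np.minimum(idx, len(tstart) - 1)] < qe)
        hits += int(ok.sum())
    return hits


@dataclass
class OverlapSummary:
    """Pairwise overlap statistics between two region sets.

    Region counts use an any-overlap (>=1 bp) criterion; bp statistics come
    from the exact interval intersection of the merged sets.  Percentages are
    relative to each set's own totals.
    """

    name_a: str
    name_b: str
    regions_a: int
    regions_b: int
    bp_a: int
    bp_b: int
    shared_regions_a: int
    shared_regions_b: int
    shared_bp: int

    @property
    def pct_regions_a(self) -> float:
        return 100.0 * self.shared_regions_a / self.regions_a if self.regions_a else 0.0

    @property
    def pct_regions_b(self) -> float:
        return 100.0 * self.shared_regions_b / self.regions_b if self.regions_b else 0.0

    @property
    def pct_bp_a(self) -> float:
        return 100.0 * self.shared_bp / self.bp_a if self.bp_a else 0.0

    @property
    def pct_bp_b(self) -> float:
        return 100.0 * self.shared_bp / self.bp_b if self.bp_b else 0.0

    def to_dict(self) -> dict:
        return {
            "set_a": self.name_a,
            "set_b": self.name_b,
            "regions_a": self.regions_a,
            "regions_b": self.regions_b,
            "bp_a": self.bp_a,
            "bp_b": self.bp_b,
            "shared_regions_a": self.shared_regions_a,
            "shared_regions_b": self.shared_regions_b,
            "pct_regions_a": self.pct_regions_a,
            "pct_regions_b": self.pct_regions_b,
            "shared_bp": self.shared_bp,
            "pct_bp_a": self.pct_bp_a,
            "pct_bp_b": self.pct_bp_b,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def overlap_summary(a: IntervalSet, b: IntervalSet) -> OverlapSummary:
    am, bm = _ensure_merged(a), _ensure_merged(b)
    inter = intersect(am, bm)
    return OverlapSummary(
        name_a=a.name,
        name_b=b.name,
        regions_a=am.region_count,
        regions_b=bm.region_count,
        bp_a=am.total_bp,
        bp_b=bm.total_bp,
        shared_regions_a=_regions_hitting(am, bm),
        shared_regions_b=_regions_hitting(bm, am),
        shared_bp=inter.total_bp,
    )


def threeway_venn(a: IntervalSet, b: IntervalSet, c: IntervalSet) -> dict[str, int]:
    """bp of every membership combination of three sets (inclusion-exclusion)."""
    am, bm, cm = (_ensure_merged(s) for s in (a, b, c))
    ab = intersect(am, bm).total_bp
    ac = intersect(am, cm).total_bp
    bc = intersect(bm, cm).total_bp
    abc = intersect(intersect(am, bm), cm).total_bp
    return {
        f"{a.name}_only": am.total_bp - ab - ac + abc,
        f"{b.name}_only": bm.total_bp - ab - bc + abc,
        f"{c.name}_only": cm.total_bp - ac - bc + abc,
        f"{a.name}_{b.name}": ab - abc,
        f"{a.name}_{c.name}": ac - abc,
        f"{b.name}_{c.name}": bc - abc,
        f"{a.name}_{b.name}_{c.name}": abc,
    }


def class_composition(iset: IntervalSet) -> pd.DataFrame:
    """Per-class region counts/fractions and bp/fractions.

    The empty label is its own class.  Both bases (region count and bp) are
    reported because published class-composition pies rarely state which one
    they use.
    """
    df = iset.df.copy()
    df["length"] = df["end"] - df["start"]
    grouped = df.groupby("label", sort=True).agg(
        region_count=("start", "size"), bp=("length", "sum")
    )
    grouped["region_fraction"] = grouped["region_count"] / grouped["region_count"].sum()
    grouped["bp_fraction"] = grouped["bp"] / grouped["bp"].sum()
    return grouped.reset_index().rename(columns={"label": "class"})


# ----------------------------------------------------------------------
# Reads vs regions


def _class_mask(reads, class_filter: str) -> np.ndarray:
    if class_filter == "all":
        return np.ones(reads.total_count, dtype=bool)
    if class_filter == "duplicated":
        return reads.duplicate
    if class_filter == "multimapped":
        return reads.multimapped
    raise ValueError(f"unknown read class {class_filter!r}")


def count_reads_in_set(reads, iset: IntervalSet, class_filter: str = "all") -> tuple[int, float]:
    """Reads of a class whose span overlaps the set; percent of *all* reads.

    The percentage denominator is the full ReadSet size regardless of the
    class filter, so class percentages are directly comparable.
    """
    from .alignments import reads_overlapping_mask

    total = reads.total_count
    if total == 0:
        raise ValueError("empty ReadSet")
    mask = reads_overlapping_mask(reads, iset) & _class_mask(reads, class_filter)
    count = int(mask.sum())
    return count, 100.0 * count / total


def rpkm_per_region(reads, iset: IntervalSet) -> np.ndarray:
    """RPKM per interval, in the set's original interval order.

    A read counts in every region its span overlaps, so on an unmerged set a
    read may contribute to several regions.
    """
    total = reads.total_count
    if total == 0:
        raise ValueError("empty ReadSet")
    lengths = (iset.df["end"] - iset.df["start"]).to_numpy(np.int64)
    counts = np.zeros(len(iset.df), dtype=np.int64)

    starts_by_chrom: dict[str, np.ndarray] = {}
    ends_by_chrom: dict[str, np.ndarray] = {}
    for name, sl in reads.per_chrom():
        starts_by_chrom[name] = np.sort(reads.start[sl])
        ends_by_chrom[name] = np.sort(reads.end[sl])
    for chrom, sub in iset.df.groupby("chrom", sort=False):
        if chrom not in starts_by_chrom:
            continue
        rs = starts_by_chrom[chrom]
        re_ = ends_by_chrom[chrom]
        qs = sub["start"].to_numpy(np.int64)
        qe = sub["end"].to_numpy(np.int64)
        # reads overlapping [qs,qe): start < qe minus end <= qs
        n_before_end = np.searchsorted(rs, qe, side="left")
        n_ended = np.searchsorted(re_, qs, side="right")
        counts[sub.index.to_numpy()] = n_before_end - n_ended
    return counts / ((lengths / 1000.0) * (total / 1_000_000.0))


def fold_enrichment(reads, iset: IntervalSet, genome_bp: int) -> float:
    """Read density inside the set relative to the genome-wide density."""
    set_bp = iset.total_bp
    if set_bp <= 0:
        raise ValueError("region set covers zero bp")
    if genome_bp < set_bp:
        raise ValueError("genome_bp smaller than the set's coverage")
    total = reads.total_count
    if total == 0:
        raise ValueError("empty ReadSet")
    inside, _ = count_reads_in_set(reads, iset, "all")
    return (inside / set_bp) / (total / genome_bp)
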