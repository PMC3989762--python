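"""Strand cross-correlation profiles and the metrics built on them.

The profile correlates, for each candidate shift ``d`` in ``0..max_shift``,
the per-base Watson 5'-end counts ``w[x]`` with the Crick 5'-end counts
``c[x + d]`` (Pearson, over the overlapping range), per chromosome, combined
across chromosomes by a read-count-weighted mean.

Geometry and conventions
------------------------
A sequenced fragment of length ``f`` leaves a Watson 5' end at its start
``s`` and a Crick 5' end at ``s + f - 1`` (the Crick 5' position is the
rightmost aligned base).  The Pearson argmax therefore falls at shift
``f - 1`` and fragment lengths are reported as ``argmax_shift + 1``.  A
duplicated read stack — Watson and Crick stacks whose 5' ends sit exactly a
read length apart — peaks at shift ``r - 1`` and is thus reported as a
fragment length equal to the read length ``r``: the "phantom" read-length
peak.  ``cc_at_read_length`` is accordingly the profile value at shift
``r - 1``.

Metrics
-------
* FSC — cross-correlation at the estimated fragment length (raw value).
* NSC — FSC / min(cc): enrichment over the flat background baseline.
* RSC — (FSC - min(cc)) / (cc(r) - min(cc)): fragment-length vs phantom
  signal; > 1 means genuine signal dominates the artifact peak.
* exo-NSC — max(cc) / min(cc) on a blacklist-filtered library: the ChIP-exo
  replacement for NSC, where fragment- and read-length peaks co-occur and
  the standard decomposition breaks down.

The per-shift Pearson is computed from the sparse 5'-count representation
(pairwise position differences binned into shifts, prefix sums for the
window means/variances), which is exact and fast for realistic read
densities; tests check it to 1e-12 against a dense brute-force Pearson.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignments import QCWarning, ReadSet

__all__ = [
    "StrandCounts",
    "CrossCorrProfile",
    "CrossCorrMetrics",
    "strand_counts",
    "cross_correlation",
    "estimate_fragment_length",
    "compute_metrics",
    "compute_exo_nsc",
    "class_profiles",
    "paired_peak_fragment_length",
]

DEFAULT_MAX_SHIFT = 400
READ_LENGTH_EXCLUSION_BP = 5  # mask f in [r-5, r+5] when excluding the phantom peak


@dataclass
class StrandCounts:
    """Sparse per-base 5'-end counts for one chromosome."""

    chrom: str
    chrom_length: int
    watson_pos: np.ndarray  # sorted unique 5' positions, forward strand
    watson_count: np.ndarray
    crick_pos: np.ndarray
    crick_count: np.ndarray

    @property
    def n_watson(self) -> int:
        return int(self.watson_count.sum())

    @property
    def n_crick(self) -> int:
        return int(self.crick_count.sum())

    def dense(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense (watson, crick) count vectors of length chrom_length."""
        w = np.zeros(self.chrom_length, dtype=np.int64)
        c = np.zeros(self.chrom_length, dtype=np.int64)
        w[self.watson_pos] = self.watson_count
        c[self.crick_pos] = self.crick_count
        return w, c


def strand_counts(reads: ReadSet, chrom_lengths: Mapping[str, int]) -> dict[str, StrandCounts]:
    """5'-end count vectors per chromosome (sparse)."""
    out: dict[str, StrandCounts] = {}
    fp = reads.five_prime
    for name, sl in reads.per_chrom():
        if name not in chrom_lengths:
            raise ValueError(f"no length known for chromosome {name}")
        length = chrom_lengths[name]
        rev = reads.is_reverse[sl]
        fw = fp[sl][~rev]
        rv = fp[sl][rev]
        if fw.max(initial=-1) >= length or rv.max(initial=-1) >= length:
            raise ValueError(f"5' position beyond {name} length {length}")
        wp, wc = np.unique(fw, return_counts=True)
        cp, cc = np.unique(rv, return_counts=True)
        out[name] = StrandCounts(name, length, wp, wc, cp, cc)
    return out


@dataclass
class CrossCorrProfile:
    shifts: np.ndarray  # 0..max_shift
    cc: np.ndarray  # combined Pearson per shift
    read_length: int
    frag_length_est: int  # argmax shift + 1 (global argmax, ties -> smallest)
    provenance: tuple[str, ...] = ()
    n_reads: int = 0

    @property
    def cc_min(self) -> float:
        return float(np.nanmin(self.cc))

    @property
    def cc_max(self) -> float:
        return float(np.nanmax(self.cc))

    @property
    def cc_at_read_length(self) -> float:
        return self.cc_at_fragment_length(self.read_length)

    @property
    def cc_at_frag_length(self) -> float:
        """FSC: profile value at the estimated fragment length."""
        return self.cc_at_fragment_length(self.frag_length_est)

    def cc_at_fragment_length(self, frag_length: int) -> float:
        shift = frag_length - 1
        if not 0 <= shift < len(self.cc):
            raise ValueError(f"fragment length {frag_length} outside the shift grid")
        return float(self.cc[shift])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"shift": self.shifts, "cc": self.cc})


def _pair_difference_sums(
    pw: np.ndarray, cw: np.ndarray, pc: np.ndarray, cc: np.ndarray, max_shift: int
) -> np.ndarray:
    """Sxy(d) = sum_x w[x] * c[x+d] for d in 0..max_shift, via sparse pairs."""
    sxy = np.zeros(max_shift + 1)
    if len(pw) == 0 or len(pc) == 0:
        return sxy
    lo = np.searchsorted(pc, pw, side="left")
    hi = np.searchsorted(pc, pw + max_shift, side="right")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return sxy
    w_idx = np.repeat(np.arange(len(pw)), counts)
    offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    c_idx = np.repeat(lo, counts) + offsets
    diffs = pc[c_idx] - pw[w_idx]
    weights = cw[w_idx].astype(float) * cc[c_idx].astype(float)
    np.add.at(sxy, diffs, weights)
    return sxy


def _profile_one_chrom(sc: StrandCounts, max_shift: int) -> np.ndarray:
    """Pearson(watson[0:L-d], crick[d:L]) for every shift d; NaN when degenerate."""
    L = sc.chrom_length
    if max_shift >= L:
        raise ValueError(f"max_shift {max_shift} >= chromosome length {L}")
    d = np.arange(max_shift + 1)
    n = (L - d).astype(float)

    pw, cw = sc.watson_pos, sc.watson_count.astype(float)
    pc, cc = sc.crick_pos, sc.crick_count.astype(float)

    sxy = _pair_difference_sums(pw, cw, pc, cc, max_shift)

    # prefix sums: Sx(d) = sum of watson counts at positions < L-d
    cum_w = np.concatenate(([0.0], np.cumsum(cw)))
    cum_w2 = np.concatenate(([0.0], np.cumsum(cw**2)))
    kx = np.searchsorted(pw, L - d, side="left")
    sx, sxx = cum_w[kx], cum_w2[kx]

    # Sy(d) = sum of crick counts at positions >= d
    cum_c = np.concatenate(([0.0], np.cumsum(cc)))
    cum_c2 = np.concatenate(([0.0], np.cumsum(cc**2)))
    ky = np.searchsorted(pc, d, side="left")
    sy = cum_c[-1] - cum_c[ky]
    syy = cum_c2[-1] - cum_c2[ky]

    var_x = n * sxx - sx**2
    var_y = n * syy - sy**2
    denom = np.sqrt(var_x * var_y)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (n * sxy - sx * sy) / denom
    out[denom <= 0] = np.nan
    return out


def cross_correlation(
    reads: ReadSet,
    chrom_lengths: Mapping[str, int],
    max_shift: int = DEFAULT_MAX_SHIFT,
    read_length: int | None = None,
) -> CrossCorrProfile:
    """Combined strand cross-correlation profile over shifts 0..max_shift.

    Chromosomes need at least 2 reads on each strand to contribute; the
    combined value per shift is the read-count-weighted mean of per-
    chromosome Pearson correlations.  ``read_length`` defaults to the modal
    aligned length of the reads.
    """
    counts = strand_counts(reads, chrom_lengths)
    usable: list[tuple[StrandCounts, float]] = []
    for name, sc in counts.items():
        if sc.n_watson >= 2 and sc.n_crick >= 2:
            usable.append((sc, float(sc.n_watson + sc.n_crick)))
        else:
            warnings.warn(
                f"chromosome {name} skipped in cross-correlation "
                f"({sc.n_watson} Watson / {sc.n_crick} Crick reads)",
                QCWarning,
                stacklevel=2,
            )
    if not usable:
        raise ValueError("no chromosome has >=2 reads on both strands")

    shifts = np.arange(max_shift + 1)
    profiles = np.full((len(usable), max_shift + 1), np.nan)
    weights = np.zeros(len(usable))
    for i, (sc, wgt) in enumerate(usable):
        profiles[i] = _profile_one_chrom(sc, max_shift)
        weights[i] = wgt
    valid = ~np.isnan(profiles)
    if not valid.any(axis=0).all():
        warnings.warn(
            "some shifts have no defined correlation on any chromosome", QCWarning, stacklevel=2
        )
    wmat = np.where(valid, weights[:, None], 0.0)
    wsum = wmat.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        combined = np.nansum(profiles * wmat, axis=0) / wsum
    combined[wsum == 0] = np.nan

    if read_length is None:
        lengths, freq = np.unique(reads.read_length, return_counts=True)
        read_length = int(lengths[np.argmax(freq)])
    frag = int(np.nanargmax(combined)) + 1  # ties -> smallest shift
    return CrossCorrProfile(
        shifts=shifts,
        cc=combined,
        read_length=read_length,
        frag_length_est=frag,
        provenance=reads.provenance,
        n_reads=reads.total_count,
    )


def estimate_fragment_length(
    profile: CrossCorrProfile, exclude_read_length: bool = False
) -> int:
    """Fragment length estimate: global argmax, optionally masking the phantom peak.

    Without exclusion this reproduces the failure mode of artifact-heavy
    unfiltered libraries, which report the read length.  With
    ``exclude_read_length`` fragment lengths within +/-5 bp of the read
    length are masked before taking the argmax.
    """
    cc = profile.cc.copy()
    if exclude_read_length:
        r = profile.read_length
        lo = max(0, r - 1 - READ_LENGTH_EXCLUSION_BP)
        hi = min(len(cc), r - 1 + READ_LENGTH_EXCLUSION_BP + 1)
        cc[lo:hi] = -np.inf
    return int(np.nanargmax(cc)) + 1


@dataclass
class CrossCorrMetrics:
    fsc: float
    nsc: float | None
    rsc: float | None
    exo_nsc: float | None = None
    frag_length: int = 0
    read_length: int = 0
    read_length_peak_dominant: bool = False
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fsc": self.fsc,
            "nsc": self.nsc,
            "rsc": self.rsc,
            "exo_nsc": self.exo_nsc,
            "frag_length": self.frag_length,
            "read_length": self.read_length,
            "read_length_peak_dominant": self.read_length_peak_dominant,
            "notes": list(self.notes),
        }


def compute_metrics(profile: CrossCorrProfile) -> CrossCorrMetrics:
    """NSC, RSC and FSC from a profile; degenerate cases become notes, not errors."""
    notes: list[str] = []
    cc_min = profile.cc_min
    cc_r = profile.cc_at_read_length
    frag_excl = estimate_fragment_length(profile, exclude_read_length=True)
    fsc = profile.cc_at_fragment_length(frag_excl)
    dominant = cc_r > fsc

    nsc = rsc = None
    if cc_min <= 0:
        notes.append("cc_min <= 0: NSC and RSC undefined (no positive background baseline)")
    else:
        nsc = fsc / cc_min
        denom = cc_r - cc_min
        if denom == 0:
            notes.append("cc(read length) equals cc_min: RSC undefined")
        else:
            rsc = (fsc - cc_min) / denom
    if "blacklist" in profile.provenance:
        notes.append(
            "profile computed after blacklist filtering: the read-length value may "
            "reflect the tail of the fragment-length peak, inflating RSC"
        )
        if notes:
            warnings.warn(notes[-1], QCWarning, stacklevel=2)
    return CrossCorrMetrics(
        fsc=fsc,
        nsc=nsc,
        rsc=rsc,
        frag_length=frag_excl,
        read_length=profile.read_length,
        read_length_peak_dominant=dominant,
        notes=notes,
    )


def compute_exo_nsc(profile: CrossCorrProfile) -> float | None:
    """ChIP-exo NSC: max(cc) / min(cc) over the full shift grid.

    Requires a blacklist-filtered library — the ratio is meaningful only
    after aberrant signal has been removed.  Returns None (with a warning)
    when the profile minimum is not positive.
    """
    if "blacklist" not in profile.provenance:
        raise ValueError(
            "exo-NSC requires a blacklist-filtered ReadSet; apply the blacklist "
            "stage before computing the profile"
        )
    cc_min = profile.cc_min
    if cc_min <= 0:
        warnings.warn("cc_min <= 0: exo-NSC undefined", QCWarning, stacklevel=2)
        return None
    return profile.cc_max / cc_min


def class_profiles(
    reads: ReadSet,
    peaks,
    blacklist,
    chrom_lengths: Mapping[str, int],
    max_shift: int = DEFAULT_MAX_SHIFT,
    read_length: int | None = None,
) -> dict[str, CrossCorrProfile | None]:
    """Cross-correlation profiles of read classes.

    Classes: reads in peaks, reads in blacklist regions, duplicated reads,
    and duplicated reads inside / outside peaks.  In clean data the in-peaks
    and dup-in-peaks profiles peak near the fragment length while the
    in-blacklist and dup-outside-peaks profiles peak at the read length —
    the two faces of duplicated signal.  A class with fewer than 2 reads on
    either strand yields None with a warning.
    """
    from .alignments import mark_duplicates, reads_overlapping_mask

    if not reads.duplicates_marked:
        reads = mark_duplicates(reads)
    in_peaks = reads_overlapping_mask(reads, peaks)
    in_bl = reads_overlapping_mask(reads, blacklist)
    dup = reads.duplicate
    masks = {
        "in_peaks": in_peaks,
        "in_blacklist": in_bl,
        "duplicated": dup,
        "dup_in_peaks": dup & in_peaks,
        "dup_outside_peaks": dup & ~in_peaks,
    }
    out: dict[str, CrossCorrProfile | None] = {}
    for name, mask in masks.items():
        subset = reads.subset(mask)
        try:
            out[name] = cross_correlation(
                subset, chrom_lengths, max_shift=max_shift, read_length=read_length
            )
        except ValueError:
            warnings.warn(
                f"class {name!r} too sparse for a cross-correlation profile",
                QCWarning,
                stacklevel=2,
            )
            out[name] = None
    return out


def paired_peak_fragment_length(
    reads: ReadSet,
    chrom_lengths: Mapping[str, int],
    window: int = 300,
    mfold: float = 10.0,
) -> float | None:
    """Fragment length from paired strand summits (sliding-window method).

    Per strand, 5'-end counts are summed in sliding windows of ``window`` bp;
    positions whose window count reaches ``mfold`` times the genome-wide mean
    window count become candidates, contiguous candidate runs collapse to
    their maximal position (summit).  Each Watson summit pairs with the
    nearest Crick summit strictly downstream within (0, 4*window]; the
    estimate is the median summit distance.  Returns None (with a warning)
    when no summit pair exists — e.g. featureless background — and is pulled
    toward the read length by artifact stacks tall enough to qualify.
    """
    counts = strand_counts(reads, chrom_lengths)
    genome_bp = sum(chrom_lengths[c] for c in counts)
    n_w = sum(sc.n_watson for sc in counts.values())
    n_c = sum(sc.n_crick for sc in counts.values())
    if genome_bp == 0 or n_w == 0 or n_c == 0:
        warnings.warn("paired-peak estimate undefined: no reads", QCWarning, stacklevel=2)
        return None
    thresholds = {
        "w": mfold * n_w * window / genome_bp,
        "c": mfold * n_c * window / genome_bp,
    }
    distances: list[float] = []
    for sc in counts.values():
        summits = {}
        for strand, pos, cnt in (
            ("w", sc.watson_pos, sc.watson_count),
            ("c", sc.crick_pos, sc.crick_count),
        ):
            summits[strand] = _window_summits(
                pos, cnt, sc.chrom_length, window, thresholds[strand]
            )
        for ws in summits["w"]:
            downstream = summits["c"][summits["c"] > ws]
            if len(downstream):
                d = downstream[0] - ws
                if 0 < d <= 4 * window:
                    distances.append(float(d))
    if not distances:
        warnings.warn(
            "paired-peak estimate undefined: no Watson/Crick summit pairs met the "
            f"mfold={mfold} criterion",
            QCWarning,
            stacklevel=2,
        )
        return None
    return float(np.median(distances))


def _window_summits(
    pos: np.ndarray, cnt: np.ndarray, length: int, window: int, threshold: float
) -> np.ndarray:
    """Centers of contiguous runs of window positions exceeding the threshold."""
    if len(pos) == 0:
        return np.asarray([], dtype=np.int64)
    # windowed count at window start x: reads with 5' in [x, x+window)
    starts = np.arange(0, max(1, length - window + 1))
    cum = np.concatenate(([0], np.cumsum(cnt)))
    win = cum[np.searchsorted(pos, starts + window, side="left")] - cum[
        np.searchsorted(pos, starts, side="left")
    ]
    hot = win >= threshold
    if not hot.any():
        return np.asarray([], dtype=np.int64)
    step = np.diff(hot.astype(np.int8))
    run_starts_arr = np.flatnonzero(step == 1) + 1
    run_ends_arr = np.flatnonzero(step == -1) + 1
    if hot[0]:
        run_starts_arr = np.concatenate(([0], run_starts_arr))
    if hot[-1]:
        run_ends_arr = np.concatenate((run_ends_arr, [len(hot)]))
    summits = []
    for s, e in zip(run_starts_arr, run_ends_arr):
        peak = s + int(np.argmax(win[s:e]))
        summits.append(peak + window // 2)  # window center as the summit
    return np.asarray(summits, dtype=np.int64)
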