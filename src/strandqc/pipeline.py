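"""Iterative QC over filter stages.

Filter-stage interactions are the whole point of this report: every metric
is evaluated at each of the four stages {none, dedup, blacklist, both}, and
the headline values follow the recommended ordering —

* NSC/RSC from the *unfiltered* stage (blacklisting removes the read-length
  peak these ratios are anchored on);
* SSD both before and after blacklisting (the drop measures how much of the
  coverage inequality was artifact);
* the cross-correlation profile inspected *after* blacklisting, where loss
  of the read-length peak indicates successful artifact removal.

ChIP-exo mode changes defaults only: duplicates are retained (exo libraries
duplicate legitimately at protected borders), RSC is suppressed (fragment-
and read-length peaks co-occur), and the adapted exo-NSC is reported on
blacklist-filtered stages.  All four stages are still computed for
transparency.

Flags are advisory strings with stable identifiers, never exit-code
failures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import crosscorr as xc
from .alignments import (
    QCWarning,
    ReadSet,
    apply_filters,
    compute_nrf,
    load_alignments,
    mark_duplicates,
    mark_multimapped,
    reads_overlapping_mask,
)
from .coverage import SSDResult, compute_ssd, ssd_flag
from .intervals import IntervalSet

__all__ = ["STAGES", "StageMetrics", "QCReport", "run_qc", "fsc_ratio_table"]

STAGES = ("none", "dedup", "blacklist", "both")
_STAGE_FILTERS: dict[str, tuple[str, ...]] = {
    "none": (),
    "dedup": ("dedup",),
    "blacklist": ("blacklist",),
    "both": ("dedup", "blacklist"),
}

FLAG_NRF = "NRF_LOW_COMPLEXITY"
FLAG_SSD = "INPUT_SSD_GE_CHIP"
FLAG_PHANTOM_PERSISTS = "READ_LENGTH_PEAK_PERSISTS"
FLAG_FRAGLEN_IS_READLEN = "FRAGLEN_EQUALS_READLEN"


@dataclass
class StageMetrics:
    stage: str
    n_reads: int
    nrf: float | None = None
    duplicate_pct: float | None = None
    multimapped_pct: float | None = None
    blacklist_read_pct: float | None = None
    ssd: float | None = None
    frag_length: int | None = None
    fsc: float | None = None
    nsc: float | None = None
    rsc: float | None = None
    exo_nsc: float | None = None
    read_length_peak_dominant: bool | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_reads": self.n_reads,
            "nrf": self.nrf,
            "duplicate_pct": self.duplicate_pct,
            "multimapped_pct": self.multimapped_pct,
            "blacklist_read_pct": self.blacklist_read_pct,
            "ssd": self.ssd,
            "frag_length": self.frag_length,
            "fsc": self.fsc,
            "nsc": self.nsc,
            "rsc": self.rsc,
            "exo_nsc": self.exo_nsc,
            "read_length_peak_dominant": self.read_length_peak_dominant,
            "notes": list(self.notes),
        }


@dataclass
class QCReport:
    sample_id: str
    mode: str  # chipseq | chipexo
    stages: dict[str, StageMetrics]
    headline: dict
    fsc_ratios: dict[str, float | None]
    flags: list[str]
    inputs: dict
    profiles: dict[str, xc.CrossCorrProfile] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "mode": self.mode,
            "stages": {k: v.to_dict() for k, v in self.stages.items()},
            "headline": self.headline,
            "fsc_ratios": self.fsc_ratios,
            "flags": list(self.flags),
            "inputs": self.inputs,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([m.to_dict() for m in self.stages.values()]).set_index("stage")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _as_readset(source, chrom_subset=None, effective_read_length=None) -> ReadSet:
    if isinstance(source, ReadSet):
        return source
    return load_alignments(
        source, chrom_subset=chrom_subset, effective_read_length=effective_read_length
    )


def run_qc(
    sample,
    input_control=None,
    blacklist: IntervalSet | None = None,
    peaks: IntervalSet | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
    mode: str = "chipseq",
    max_shift: int = xc.DEFAULT_MAX_SHIFT,
    read_length: int | None = None,
    chrom_subset: Sequence[str] | None = None,
    sample_id: str = "sample",
    mapq_threshold: int = 1,
) -> QCReport:
    """Full staged QC report for one sample (path to SAM/BAM, or a ReadSet).

    ``input_control`` is used only for the post-blacklist SSD comparison.
    ``peaks``, when given, enables the read-class profile decomposition
    downstream via :func:`strandqc.crosscorr.class_profiles` (not part of
    the report body).  ``chrom_lengths`` defaults to the lengths in the SAM
    header.
    """
    if mode not in ("chipseq", "chipexo"):
        raise ValueError("mode must be 'chipseq' or 'chipexo'")
    reads = _as_readset(sample, chrom_subset, read_length)
    if chrom_lengths is None:
        chrom_lengths = reads.chrom_lengths
    if not chrom_lengths:
        raise ValueError("chromosome lengths are required (chrom_lengths or SAM header)")
    reads = mark_duplicates(mark_multimapped(reads, mapq_threshold))

    stage_filters = dict(_STAGE_FILTERS)
    if blacklist is None:
        stage_filters = {k: v for k, v in stage_filters.items() if "blacklist" not in v}

    stages: dict[str, StageMetrics] = {}
    profiles: dict[str, xc.CrossCorrProfile] = {}
    for stage, filters in stage_filters.items():
        sub = apply_filters(reads, filters, blacklist=blacklist)
        m = StageMetrics(stage=stage, n_reads=sub.total_count)
        if sub.total_count == 0:
            m.notes.append("no reads at this stage")
            stages[stage] = m
            continue
        nrf, _failed = compute_nrf(sub)
        m.nrf = nrf
        m.duplicate_pct = 100.0 * sub.n_duplicated / sub.total_count
        m.multimapped_pct = 100.0 * sub.n_multimapped / sub.total_count
        if blacklist is not None:
            m.blacklist_read_pct = float(
                100.0 * reads_overlapping_mask(sub, blacklist).mean()
            )
        m.ssd = compute_ssd(sub, chrom_lengths).ssd
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", QCWarning)
                profile = xc.cross_correlation(
                    sub, chrom_lengths, max_shift=max_shift, read_length=read_length
                )
        except ValueError as exc:
            m.notes.append(f"cross-correlation undefined: {exc}")
            stages[stage] = m
            continue
        profiles[stage] = profile
        m.frag_length = profile.frag_length_est
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", QCWarning)
            metrics = xc.compute_metrics(profile)
        m.fsc = metrics.fsc
        m.nsc = metrics.nsc
        m.read_length_peak_dominant = metrics.read_length_peak_dominant
        m.notes.extend(metrics.notes)
        if mode == "chipexo":
            m.rsc = None
            m.notes.append("RSC suppressed: fragment- and read-length peaks co-occur in ChIP-exo")
            if "blacklist" in profile.provenance:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", QCWarning)
                    m.exo_nsc = xc.compute_exo_nsc(profile)
        else:
            m.rsc = metrics.rsc
        stages[stage] = m

    # ------------------------------------------------------------------
    fsc_ratios = _fsc_ratios(stages)

    headline_stage = stages.get("none")
    headline: dict = {
        "nsc": headline_stage.nsc if headline_stage else None,
        "rsc": headline_stage.rsc if headline_stage else None,
        "frag_length": headline_stage.frag_length if headline_stage else None,
        "ssd_prefilter": headline_stage.ssd if headline_stage else None,
        "ssd_postblacklist": stages["blacklist"].ssd if "blacklist" in stages else None,
    }
    if mode == "chipexo":
        # recommended exo processing: blacklist removal, duplicates retained
        headline["exo_nsc"] = (
            stages["blacklist"].exo_nsc if "blacklist" in stages else None
        )

    flags: list[str] = []
    if headline_stage is not None and headline_stage.nrf is not None:
        from .alignments import nrf_flag

        if nrf_flag(headline_stage.nrf, headline_stage.n_reads):
            flags.append(FLAG_NRF)
    input_ssd = chip_ssd = None
    if input_control is not None and blacklist is not None:
        ctrl = _as_readset(input_control, chrom_subset, read_length)
        ctrl = mark_duplicates(mark_multimapped(ctrl, mapq_threshold))
        ctrl_bl = apply_filters(ctrl, ("blacklist",), blacklist=blacklist)
        chip_bl = apply_filters(reads, ("blacklist",), blacklist=blacklist)
        input_res = compute_ssd(ctrl_bl, chrom_lengths)
        chip_res = compute_ssd(chip_bl, chrom_lengths)
        input_ssd, chip_ssd = input_res.ssd, chip_res.ssd
        if ssd_flag(chip_res, input_res) == "warn":
            flags.append(FLAG_SSD)
    headline["input_ssd_postblacklist"] = input_ssd
    if "blacklist" in stages and stages["blacklist"].read_length_peak_dominant:
        flags.append(FLAG_PHANTOM_PERSISTS)
    if headline_stage is not None and headline_stage.frag_length is not None:
        r = profiles["none"].read_length if "none" in profiles else None
        if r is not None and headline_stage.frag_length == r:
            flags.append(FLAG_FRAGLEN_IS_READLEN)

    return QCReport(
        sample_id=sample_id,
        mode=mode,
        stages=stages,
        headline=headline,
        fsc_ratios=fsc_ratios,
        flags=flags,
        inputs={
            "blacklist": blacklist.name if blacklist is not None else None,
            "peaks": peaks.name if peaks is not None else None,
            "input_control": input_control is not None,
            "max_shift": max_shift,
            "mode": mode,
            "stages_evaluated": list(stage_filters),
        },
        profiles=profiles,
    )


def _fsc_ratios(stages: dict[str, StageMetrics]) -> dict[str, float | None]:
    base = stages.get("none")
    out: dict[str, float | None] = {}
    if base is None or base.fsc is None or base.fsc <= 0:
        warnings.warn("FSC at the unfiltered stage is not positive; ratios undefined",
                      QCWarning, stacklevel=3)
        return {s: None for s in stages if s != "none"}
    for name, m in stages.items():
        if name == "none":
            continue
        out[name] = (m.fsc / base.fsc) if m.fsc is not None else None
    return out


def fsc_ratio_table(report: QCReport) -> pd.DataFrame:
    """Per-stage FSC / FSC(none), the filter-impact summary for ChIP signal."""
    rows = [
        {"stage": stage, "fsc_ratio": ratio} for stage, ratio in report.fsc_ratios.items()
    ]
    return pd.DataFrame(rows)
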