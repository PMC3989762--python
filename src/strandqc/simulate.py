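"""Synthetic single-end aligned reads with the structure ChIP QC metrics assume.

The generator emits coordinate-sorted SAM plus ground truth (site and
artifact BEDs, config echo).  Three experiment layouts:

* ``simulate_chip`` — point-source binding sites: fragments of length ``f0``
  centered on each site (Gaussian positional jitter), sequenced from a
  uniformly chosen end, so Watson 5' ends cluster at ``site - f0/2`` and
  Crick 5' ends at ``site + f0/2 - 1``; plus background and artifact stacks.
* ``simulate_input`` — background (and optional artifact stacks) only.
* ``simulate_exo`` — exonuclease-trimmed libraries: reads abut the protected
  site edges (Watson 5' at ``site - b``, Crick 5' at ``site + b - 1`` for a
  small border offset ``b``), with near-zero jitter and hence high
  *legitimate* duplication.

Artifact stacks emit ``depth`` forward reads with their 5' end at the stack
position and ``depth`` reverse reads with their 5' end exactly one read
length downstream (minus one), the geometry that produces the read-length
("phantom") cross-correlation spike.

Background reads are drawn from a two-level accessibility field: a fraction
of the genome lies in open "islands" that receive most of the background
mass.  Real input coverage shares such regional structure between the two
strands, and it is exactly that shared structure which gives cross-
correlation profiles their flat positive baseline — without it the profile
minimum straddles zero and every background-anchored ratio (NSC, exo-NSC)
is undefined.  Setting ``background_island_weight`` equal to
``background_island_fraction`` recovers an iid-uniform background.

Randomness: one integer seed; independent sub-streams per component (site
placement, site reads, background, islands, strands, mapq) so changing one
component's parameters does not perturb the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .intervals import IntervalSet, GenomicInterval

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_chip", "simulate_input", "simulate_exo"]

_STREAMS = {"sites": 1, "site_reads": 2, "background": 3, "islands": 4, "stacks": 5, "mapq": 6}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic library.

    Defaults describe a small but realistic transcription-factor ChIP on a
    toy genome: 40 point sites averaging 50 reads each (~2000 site reads,
    i.e. a FRiP of ~8%), 20000 background reads, fragment length 150 bp,
    reads 28 bp, and 10 bp fragment-position jitter.  Artifact stacks are
    off by default; ``with_stacks`` adds them.  Background dominates the
    library, as it does in real data — that, plus the shared accessibility
    field, is what gives profiles a positive baseline for NSC-style ratios.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"sim1": 500_000, "sim2": 300_000}
    )
    n_sites: int = 40
    fragment_length: int = 150
    read_length: int = 28
    reads_per_site_mean: float = 50.0
    reads_per_site_dispersion: float = 10.0  # NB size parameter; inf -> Poisson
    jitter_sd: float = 10.0
    background_reads: int = 20000
    background_island_fraction: float = 0.1
    background_island_weight: float = 0.8
    background_island_size: int = 5000
    artifact_stacks: Sequence[tuple[str, int, int]] = ()  # (chrom, position, depth)
    multimapped_fraction: float = 0.02
    exo_mode: bool = False
    exo_border: int = 10
    exo_jitter_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (self.fragment_length > self.read_length > 0):
            raise ValueError("need fragment_length > read_length > 0")
        if self.n_sites < 0 or self.background_reads < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.background_island_fraction <= 1:
            raise ValueError("background_island_fraction must be in [0,1]")
        if not 0 <= self.background_island_weight <= 1:
            raise ValueError("background_island_weight must be in [0,1]")
        for chrom, pos, depth in self.artifact_stacks:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"stack on unknown chromosome {chrom}")
            if not 0 <= pos <= self.chrom_lengths[chrom] - self.read_length:
                raise ValueError(f"stack at {chrom}:{pos} outside chromosome bounds")
            if depth < 0:
                raise ValueError("stack depth must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(_STREAMS[stream],))
        )

    def with_stacks(
        self, n_stacks: int, depth: int, seed_offset: int = 0
    ) -> "SimulationConfig":
        """Copy of the config with randomly placed artifact stacks.

        Stacks are kept clear of the binding-site windows (site +/- fragment
        length, widened by the jitter range): artifact and ChIP signal live
        in disjoint regions so the emitted truth BEDs cleanly separate the
        two read classes.
        """
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed) + seed_offset, spawn_key=(99,))
        )
        chroms = list(self.chrom_lengths)
        lengths = np.array([self.chrom_lengths[c] for c in chroms], dtype=float)
        site_map: dict[str, list[int]] = {c: [] for c in chroms}
        if self.n_sites:
            for chrom, pos in _place_sites(self):
                site_map[chrom].append(pos)
        exclude = (
            self.fragment_length + int(6 * self.jitter_sd) + 3 * self.read_length
        )
        stacks = []
        margin = 3 * self.read_length
        for _ in range(n_stacks):
            for _attempt in range(1000):
                c = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
                pos = int(rng.integers(margin, self.chrom_lengths[c] - margin))
                if all(abs(pos - s) > exclude for s in site_map[c]):
                    break
            else:
                raise ValueError("could not place artifact stacks clear of sites")
            stacks.append((c, pos, depth))
        return dataclasses.replace(self, artifact_stacks=tuple(stacks))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chrom_lengths"] = dict(self.chrom_lengths)
        d["artifact_stacks"] = [list(s) for s in self.artifact_stacks]
        return d


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside the reads."""

    sites: IntervalSet  # site windows (site +/- fragment_length), label 'site'
    artifacts: IntervalSet  # stack regions (position - r .. position + 2r)
    site_positions: list[tuple[str, int]]
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        from .intervals import write_bed

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "sites": out_dir / "truth_sites.bed",
            "artifacts": out_dir / "truth_artifacts.bed",
            "config": out_dir / "config.json",
        }
        write_bed(self.sites, paths["sites"])
        write_bed(self.artifacts, paths["artifacts"])
        paths["config"].write_text(json.dumps(self.config.to_dict(), indent=2) + "\n")
        return paths


# ----------------------------------------------------------------------
# Internals


def _place_sites(config: SimulationConfig) -> list[tuple[str, int]]:
    """Random site positions, spacing > 2*fragment_length, away from edges."""
    rng = config.rng("sites")
    f0 = config.fragment_length
    margin = f0 + int(6 * config.jitter_sd) + config.read_length
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    # allot sites to chromosomes proportionally to length
    alloc = rng.multinomial(config.n_sites, lengths / lengths.sum())
    sites: list[tuple[str, int]] = []
    spacing = 2 * f0 + 1
    for chrom, k in zip(chroms, alloc):
        L = config.chrom_lengths[chrom]
        usable = L - 2 * margin - (int(k) - 1) * spacing
        if k and usable <= 0:
            raise ValueError(f"chromosome {chrom} too short for {k} sites")
        # k ordered draws + mandatory spacing => min distance > 2*f0
        offsets = np.sort(rng.integers(0, usable + 1, size=int(k)))
        positions = margin + offsets + spacing * np.arange(int(k))
        sites.extend((chrom, int(p)) for p in positions)
    return sites


def _truth(config: SimulationConfig, sites: list[tuple[str, int]]) -> SimulationTruth:
    f0, r = config.fragment_length, config.read_length
    site_iv = [
        GenomicInterval(c, max(0, p - f0), min(config.chrom_lengths[c], p + f0), "site")
        for c, p in sites
    ]
    art_iv = [
        GenomicInterval(c, max(0, pos - r), min(config.chrom_lengths[c], pos + 2 * r), "stack")
        for c, pos, depth in config.artifact_stacks
        if depth > 0
    ]
    return SimulationTruth(
        sites=IntervalSet.from_intervals("truth_sites", site_iv),
        artifacts=IntervalSet.from_intervals("truth_artifacts", art_iv),
        site_positions=sites,
        config=config,
    )


def _site_reads(
    config: SimulationConfig, sites: list[tuple[str, int]]
) -> list[tuple[str, int, bool]]:
    """(chrom, start, is_reverse) for fragment-sequencing site reads."""
    rng = config.rng("site_reads")
    f0, r = config.fragment_length, config.read_length
    reads: list[tuple[str, int, bool]] = []
    for chrom, site in sites:
        n = _draw_count(rng, config.reads_per_site_mean, config.reads_per_site_dispersion)
        if n == 0:
            continue
        centers = site + np.round(rng.normal(0.0, config.jitter_sd, size=n)).astype(np.int64)
        frag_start = centers - f0 // 2
        frag_end = frag_start + f0
        reverse = rng.random(n) < 0.5
        start = np.where(reverse, frag_end - r, frag_start)
        L = config.chrom_lengths[chrom]
        start = np.clip(start, 0, L - r)
        reads.extend((chrom, int(s), bool(v)) for s, v in zip(start, reverse))
    return reads


def _exo_site_reads(
    config: SimulationConfig, sites: list[tuple[str, int]]
) -> list[tuple[str, int, bool]]:
    """Reads tightly abutting the protected site borders (high duplication)."""
    rng = config.rng("site_reads")
    b, r = config.exo_border, config.read_length
    reads: list[tuple[str, int, bool]] = []
    for chrom, site in sites:
        n = _draw_count(rng, config.reads_per_site_mean, config.reads_per_site_dispersion)
        if n == 0:
            continue
        jitter = np.clip(
            np.round(rng.normal(0.0, config.exo_jitter_sd, size=n)), -2, 2
        ).astype(np.int64)
        reverse = rng.random(n) < 0.5
        five_prime = np.where(reverse, site + b - 1, site - b) + jitter
        start = np.where(reverse, five_prime - r + 1, five_prime)
        L = config.chrom_lengths[chrom]
        start = np.clip(start, 0, L - r)
        reads.extend((chrom, int(s), bool(v)) for s, v in zip(start, reverse))
    return reads


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if not np.isfinite(dispersion):
        return int(rng.poisson(mean))
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _background_reads(config: SimulationConfig) -> list[tuple[str, int, bool]]:
    """Background 5' positions from the two-level accessibility field."""
    n = config.background_reads
    if n == 0:
        return []
    rng = config.rng("background")
    island_rng = config.rng("islands")
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=np.int64)
    r = config.read_length

    # non-overlapping open islands per chromosome
    islands: dict[str, np.ndarray] = {}
    size = config.background_island_size
    for chrom, L in zip(chroms, lengths):
        k = int(round(config.background_island_fraction * L / size))
        if k == 0:
            islands[chrom] = np.asarray([], dtype=np.int64)
            continue
        slot = L // k
        starts = np.arange(k) * slot + island_rng.integers(0, max(1, slot - size), size=k)
        islands[chrom] = starts

    alloc = rng.multinomial(n, lengths / lengths.sum())
    reads: list[tuple[str, int, bool]] = []
    for chrom, L, k in zip(chroms, lengths, alloc):
        k = int(k)
        if k == 0:
            continue
        st = islands[chrom]
        w_island = config.background_island_weight if len(st) else 0.0
        in_island = rng.random(k) < w_island
        pos = np.empty(k, dtype=np.int64)
        n_is = int(in_island.sum())
        if n_is:
            which = rng.integers(0, len(st), size=n_is)
            pos[in_island] = st[which] + rng.integers(0, size, size=n_is)
        pos[~in_island] = rng.integers(0, L, size=k - n_is)
        reverse = rng.random(k) < 0.5
        start = np.where(reverse, pos - r + 1, pos)
        start = np.clip(start, 0, L - r)
        reads.extend((chrom, int(s), bool(v)) for s, v in zip(start, reverse))
    return reads


def _stack_reads(config: SimulationConfig) -> list[tuple[str, int, bool]]:
    r = config.read_length
    reads: list[tuple[str, int, bool]] = []
    for chrom, pos, depth in config.artifact_stacks:
        # forward 5' at pos, reverse 5' at pos + r - 1: both spans [pos, pos+r)
        reads.extend((chrom, pos, False) for _ in range(depth))
        reads.extend((chrom, pos, True) for _ in range(depth))
    return reads


def _write_sam(
    config: SimulationConfig, reads: list[tuple[str, int, bool]], path: str | Path
) -> None:
    rng = config.rng("mapq")
    r = config.read_length
    chrom_order = {c: i for i, c in enumerate(config.chrom_lengths)}
    reads = sorted(reads, key=lambda t: (chrom_order[t[0]], t[1], t[2]))
    mm = rng.random(len(reads)) < config.multimapped_fraction
    seq = "A" * r
    qual = "I" * r
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, L in config.chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{L}\n")
        fh.write("@PG\tID:strandqc\tPN:strandqc-simulate\n")
        for i, (chrom, start, reverse) in enumerate(reads):
            flag = 16 if reverse else 0
            mapq = 0 if mm[i] else 37
            fh.write(
                f"sim{i:07d}\t{flag}\t{chrom}\t{start + 1}\t{mapq}\t{r}M\t*\t0\t0\t{seq}\t{qual}\n"
            )


# ----------------------------------------------------------------------
# Public generators


def simulate_chip(
    config: SimulationConfig, out_sam: str | Path
) -> tuple[Path, SimulationTruth]:
    """Point-source ChIP library: site fragments + background + artifact stacks."""
    config.validate()
    if config.exo_mode:
        raise ValueError("use simulate_exo for exo_mode configs")
    sites = _place_sites(config)
    reads = _site_reads(config, sites) + _background_reads(config) + _stack_reads(config)
    _write_sam(config, reads, out_sam)
    return Path(out_sam), _truth(config, sites)


def simulate_input(
    config: SimulationConfig, out_sam: str | Path
) -> tuple[Path, SimulationTruth]:
    """Input control: background (and optional artifact stacks), no sites."""
    config.validate()
    reads = _background_reads(config) + _stack_reads(config)
    _write_sam(config, reads, out_sam)
    return Path(out_sam), _truth(config, [])


def simulate_exo(
    config: SimulationConfig, out_sam: str | Path
) -> tuple[Path, SimulationTruth]:
    """ChIP-exo library: edge-stacked site reads + background + stacks."""
    if not config.exo_mode:
        raise ValueError("simulate_exo requires exo_mode=True")
    config.validate()
    sites = _place_sites(config)
    reads = _exo_site_reads(config, sites) + _background_reads(config) + _stack_reads(config)
    _write_sam(config, reads, out_sam)
    return Path(out_sam), _truth(config, sites)
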