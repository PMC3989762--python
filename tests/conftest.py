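"""Shared fixtures: hand-built read sets, and cached simulated libraries."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pytest

from strandqc import (
    AlignedRead,
    QCWarning,
    ReadSet,
    load_alignments,
    mark_duplicates,
)
from strandqc.simulate import (
    SimulationConfig,
    simulate_chip,
    simulate_exo,
    simulate_input,
)


def make_readset(triples, chrom_lengths=None, read_length=28, mapq=37):
    """ReadSet from (chrom, five_prime, strand) triples."""
    reads = []
    for item in triples:
        chrom, fp, strand = item[:3]
        q = item[3] if len(item) > 3 else mapq
        if strand == "+":
            reads.append(AlignedRead(chrom, fp, fp + read_length, "+", q))
        else:
            reads.append(AlignedRead(chrom, fp - read_length + 1, fp + 1, "-", q))
    names = sorted(chrom_lengths) if chrom_lengths else None
    return ReadSet.from_reads(reads, chrom_names=names, chrom_lengths=chrom_lengths)


def dense_pearson_profile(watson, crick, max_shift):
    """Brute-force oracle: Pearson(w[0:L-d], c[d:L]) per shift on dense vectors."""
    L = len(watson)
    out = np.full(max_shift + 1, np.nan)
    for d in range(max_shift + 1):
        x = np.asarray(watson[: L - d], dtype=float)
        y = np.asarray(crick[d:], dtype=float)
        if x.std() == 0 or y.std() == 0:
            continue
        out[d] = np.corrcoef(x, y)[0, 1]
    return out


@pytest.fixture(scope="session")
def std_chip(tmp_path_factory):
    """Standard ChIP fixture: 40 deep sites, background, 10 artifact stacks."""
    cfg = SimulationConfig(seed=20, reads_per_site_mean=100.0).with_stacks(10, 100)
    out = tmp_path_factory.mktemp("chip")
    sam, truth = simulate_chip(cfg, out / "chip.sam")
    reads = mark_duplicates(load_alignments(sam, effective_read_length=cfg.read_length))
    return cfg, reads, truth


@pytest.fixture(scope="session")
def std_input(tmp_path_factory):
    """Matched input control: background + stacks, no sites."""
    cfg = SimulationConfig(seed=21, n_sites=0).with_stacks(10, 100, seed_offset=1)
    out = tmp_path_factory.mktemp("input")
    sam, truth = simulate_input(cfg, out / "input.sam")
    reads = mark_duplicates(load_alignments(sam, effective_read_length=cfg.read_length))
    return cfg, reads, truth


@pytest.fixture(scope="session")
def std_exo(tmp_path_factory):
    """ChIP-exo fixture: edge-stacked site reads, background, 5 stacks."""
    cfg = SimulationConfig(
        seed=22, exo_mode=True, chrom_lengths={"sim1": 2_000_000},
        n_sites=40, background_reads=40_000,
    ).with_stacks(5, 100)
    out = tmp_path_factory.mktemp("exo")
    sam, truth = simulate_exo(cfg, out / "exo.sam")
    reads = mark_duplicates(load_alignments(sam, effective_read_length=cfg.read_length))
    return cfg, reads, truth


@pytest.fixture(autouse=True)
def _quiet_qc_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", QCWarning)
        yield
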