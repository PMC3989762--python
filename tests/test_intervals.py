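"""Interval algebra, overlap statistics and region read counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strandqc import (
    GenomicInterval,
    IntervalSet,
    class_composition,
    count_reads_in_set,
    fold_enrichment,
    intersect,
    load_bed,
    load_chrom_sizes,
    merge,
    overlap_summary,
    rpkm_per_region,
    threeway_venn,
    write_bed,
)

from conftest import make_readset


def iset(name, triples):
    ivs = []
    for t in triples:
        c, s, e = t[:3]
        ivs.append(GenomicInterval(c, s, e, t[3] if len(t) > 3 else ""))
    return IntervalSet.from_intervals(name, ivs)


def bitmap(intervals, length=1000, chrom="chr1"):
    """Per-base occupancy oracle."""
    bits = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            bits[iv.start:iv.end] = True
    return bits


interval_sets = st.lists(
    st.tuples(st.integers(0, 950), st.integers(1, 50)), min_size=1, max_size=40
).map(lambda pairs: IntervalSet.from_intervals(
    "rand", [GenomicInterval("chr1", s, s + w) for s, w in pairs]))


class TestBedIO:
    def test_bed3_round_trip(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t10\nchr1\t20\t30\nchr2\t5\t6\n")
        s = load_bed(p)
        assert len(s) == 3
        assert list(s.df["label"]) == ["", "", ""]
        out = tmp_path / "b.bed"
        write_bed(s, out)
        again = load_bed(out)
        assert again.df[["chrom", "start", "end", "label"]].equals(
            s.df[["chrom", "start", "end", "label"]])

    def test_bed6_labels(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t10\tALR/Alpha\t1000\t.\nchr1\t20\t30\tBSR/Beta\t1000\t.\n")
        s = load_bed(p)
        assert list(s.df["label"]) == ["ALR/Alpha", "BSR/Beta"]

    def test_malformed_line_cites_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        lines = [f"chr1\t{i * 10}\t{i * 10 + 5}" for i in range(6)]
        lines.append("chr1\t100\t90")  # line 7: start >= end
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="line 7"):
            load_bed(p)

    def test_chrom_sizes(self, tmp_path):
        p = tmp_path / "sizes.tsv"
        p.write_text("chr1\t1000\nchr2\t500\n")
        assert load_chrom_sizes(p) == {"chr1": 1000, "chr2": 500}


class TestMerge:
    def test_overlapping(self):
        m = merge(iset("a", [("chr1", 0, 10), ("chr1", 5, 15)]))
        assert [(r.start, r.end) for r in m.df.itertuples()] == [(0, 15)]

    def test_book_ended(self):
        m = merge(iset("a", [("chr1", 0, 10), ("chr1", 10, 20)]))
        assert len(m) == 1 and m.total_bp == 20

    def test_disjoint_unchanged(self):
        m = merge(iset("a", [("chr1", 0, 10), ("chr1", 20, 30)]))
        assert len(m) == 2

    def test_labels_joined_distinct(self):
        s = iset("a", [("chr1", 0, 10, "x"), ("chr1", 5, 15, "y"), ("chr1", 8, 12, "x")])
        assert merge(s).df["label"].tolist() == ["x,y"]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(interval_sets)
    def test_total_bp_matches_bitmap_and_idempotent(self, s):
        m = merge(s)
        assert m.total_bp == int(bitmap(s.intervals()).sum())
        again = merge(m)
        assert again.df[["chrom", "start", "end"]].equals(m.df[["chrom", "start", "end"]])


class TestOverlapSummary:
    def test_manual_arithmetic(self):
        a = iset("A", [("chr1", 0, 10), ("chr1", 20, 30)])
        b = iset("B", [("chr1", 5, 15)])
        o = overlap_summary(a, b)
        assert (o.shared_regions_a, o.regions_a) == (1, 2)
        assert o.pct_regions_a == 50.0
        assert (o.shared_regions_b, o.pct_regions_b) == (1, 100.0)
        assert o.shared_bp == 5

    def test_identical_sets(self):
        a = iset("A", [("chr1", 0, 10), ("chr2", 5, 25)])
        o = overlap_summary(a, a)
        assert o.pct_regions_a == o.pct_regions_b == 100.0
        assert o.pct_bp_a == o.pct_bp_b == 100.0
        assert o.shared_bp == 30

    def test_disjoint_sets(self):
        a = iset("A", [("chr1", 0, 10)])
        b = iset("B", [("chr1", 10, 20)])  # book-ended, zero overlap
        o = overlap_summary(a, b)
        assert o.shared_bp == 0 and o.shared_regions_a == 0 and o.pct_bp_b == 0.0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(interval_sets, interval_sets)
    def test_shared_bp_symmetric_and_matches_bitmap(self, a, b):
        o1 = overlap_summary(a, b)
        o2 = overlap_summary(b, a)
        assert o1.shared_bp == o2.shared_bp
        expected = int((bitmap(a.intervals()) & bitmap(b.intervals())).sum())
        assert o1.shared_bp == expected


def test_threeway_venn_matches_bitmap():
    rng = np.random.default_rng(11)
    sets = []
    for name in "ABC":
        ivs = [GenomicInterval("chr1", int(s), int(s) + int(w))
               for s, w in zip(rng.integers(0, 900, 25), rng.integers(1, 60, 25))]
        sets.append(IntervalSet.from_intervals(name, ivs))
    venn = threeway_venn(*sets)
    ba, bb, bc = (bitmap(s.intervals()) for s in sets)
    assert venn["A_only"] == int((ba & ~bb & ~bc).sum())
    assert venn["A_B"] == int((ba & bb & ~bc).sum())
    assert venn["A_B_C"] == int((ba & bb & bc).sum())
    assert sum(venn.values()) == int((ba | bb | bc).sum())


class TestClassComposition:
    def test_region_fractions(self):
        s = iset("a", [("chr1", 0, 10, "x"), ("chr1", 20, 30, "x"),
                       ("chr1", 40, 50, "y"), ("chr1", 60, 80, "z")])
        comp = class_composition(s).set_index("class")
        assert comp.loc["x", "region_fraction"] == 0.5
        assert comp.loc["y", "region_fraction"] == 0.25
        assert comp.loc["z", "bp"] == 20
        assert abs(comp["region_fraction"].sum() - 1.0) < 1e-12
        assert abs(comp["bp_fraction"].sum() - 1.0) < 1e-12

    def test_single_class(self):
        s = iset("a", [("chr1", 0, 10, "only"), ("chr1", 20, 30, "only")])
        comp = class_composition(s)
        assert comp["region_fraction"].tolist() == [1.0]

    def test_dominant_classes_match_line_count_oracle(self, tmp_path):
        # blacklist-style BED where two repeat classes dominate
        rng = np.random.default_rng(5)
        labels = ["ALR/Alpha"] * 70 + ["BSR/Beta"] * 15 + ["rRNA"] * 10 + ["Tar1"] * 5
        lines = [
            f"chr1\t{i * 100}\t{i * 100 + 50}\t{labels[i]}" for i in range(len(labels))
        ]
        p = tmp_path / "der_like.bed"
        p.write_text("\n".join(lines) + "\n")
        comp = class_composition(load_bed(p)).set_index("class")
        from collections import Counter
        oracle = Counter(l.split("\t")[3] for l in lines)
        top2 = comp["region_count"].nlargest(2)
        assert set(top2.index) == {"ALR/Alpha", "BSR/Beta"}
        assert top2.sum() == oracle["ALR/Alpha"] + oracle["BSR/Beta"]
        assert top2.sum() / len(labels) == 0.85


class TestReadCounting:
    def test_twenty_percent(self):
        rs = make_readset([("chr1", 100 * i, "+") for i in range(1, 11)], read_length=10)
        s = iset("a", [("chr1", 95, 215)])  # covers reads at 100 and 200
        count, pct = count_reads_in_set(rs, s)
        assert (count, pct) == (2, 20.0)

    def test_empty_set_counts_zero(self):
        rs = make_readset([("chr1", 100, "+")])
        count, pct = count_reads_in_set(rs, IntervalSet.from_intervals("e", []))
        assert (count, pct) == (0, 0.0)

    def test_class_percent_uses_full_denominator(self):
        from strandqc import mark_duplicates
        rs = mark_duplicates(make_readset(
            [("chr1", 100, "+")] * 4 + [("chr1", 500, "+")] * 6, read_length=10))
        s = iset("a", [("chr1", 90, 120)])
        count, pct = count_reads_in_set(rs, s, class_filter="duplicated")
        assert count == 3  # 4 reads in the stack, 1 survivor
        assert pct == 30.0  # of all 10 reads, not of the 8 duplicates

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(9)
        rs = make_readset(
            [("chr1", int(p), "+") for p in rng.integers(0, 5000, 300)], read_length=30)
        ivs = [GenomicInterval("chr1", int(s), int(s + w))
               for s, w in zip(rng.integers(0, 5000, 20), rng.integers(10, 200, 20))]
        s = IntervalSet.from_intervals("r", ivs)
        count, _ = count_reads_in_set(rs, s)
        oracle = sum(
            any(a < iv.end and b > iv.start for iv in ivs)
            for a, b in zip(rs.start, rs.end)
        )
        assert count == oracle

    def test_all_geq_duplicated(self, std_chip):
        cfg, reads, truth = std_chip
        c_all, _ = count_reads_in_set(reads, truth.artifacts, "all")
        c_dup, _ = count_reads_in_set(reads, truth.artifacts, "duplicated")
        assert c_all >= c_dup


class TestRPKM:
    def test_unit_case(self):
        # 10 reads in a 1000 bp region out of 1,000,000 total -> RPKM 10
        from strandqc import ReadSet

        n = 1_000_000
        start = np.concatenate([
            1000 + 50 * np.arange(10),          # in the region, on chr1
            np.arange(n - 10) * 10,             # the rest on chr2
        ])
        code = np.concatenate([np.zeros(10, np.int32), np.ones(n - 10, np.int32)])
        rs = ReadSet(("chr1", "chr2"), code, start, start + 20,
                     np.zeros(n, bool), np.full(n, 37, np.int16))
        s = iset("a", [("chr1", 1000, 2000)])
        rpkm = rpkm_per_region(rs, s)
        assert rpkm.shape == (1,)
        assert rpkm[0] == pytest.approx(10.0)

    def test_region_without_reads_is_zero(self):
        rs = make_readset([("chr1", 100, "+")])
        s = iset("a", [("chr1", 5000, 6000)])
        assert rpkm_per_region(rs, s)[0] == 0.0

    def test_scale_invariance(self):
        triples = [("chr1", 100 + 7 * i, "+") for i in range(50)]
        s = iset("a", [("chr1", 120, 300), ("chr1", 320, 400)])
        one = rpkm_per_region(make_readset(triples), s)
        two = rpkm_per_region(make_readset(triples * 2), s)
        np.testing.assert_allclose(one, two)


class TestFoldEnrichment:
    def test_all_reads_in_one_percent(self):
        rs = make_readset([("chr1", 100 + i, "+") for i in range(50)], read_length=10)
        s = iset("a", [("chr1", 0, 1000)])
        assert fold_enrichment(rs, s, genome_bp=100_000) == pytest.approx(100.0)

    def test_uniform_reads_near_one(self):
        rng = np.random.default_rng(1)
        rs = make_readset(
            [("chr1", int(p), "+") for p in rng.integers(0, 99_000, 5000)], read_length=10)
        s = iset("a", [("chr1", 10_000, 60_000)])
        fe = fold_enrichment(rs, s, genome_bp=100_000)
        assert 0.9 < fe < 1.1

    def test_stack_fixture_density_ratio(self):
        # 200 stack reads inside a 100 bp region, 800 elsewhere on 10 kb
        triples = [("chr1", 500, "+")] * 200 + [
            ("chr1", 2000 + 8 * i, "+") for i in range(800)]
        rs = make_readset(triples, read_length=10)
        s = iset("a", [("chr1", 450, 550)])
        expected = (200 / 100) / (1000 / 10_000)
        assert fold_enrichment(rs, s, genome_bp=10_000) == pytest.approx(expected)


def test_merge_intersect_agree_with_pyranges():
    """Cross-check the interval engine against an independent implementation."""
    pr = pytest.importorskip("pyranges")
    import pandas as pd

    rng = np.random.default_rng(17)
    def rand_set(name):
        starts = rng.integers(0, 10_000, 60)
        widths = rng.integers(1, 300, 60)
        return IntervalSet.from_intervals(
            name, [GenomicInterval("chr1", int(s), int(s + w))
                   for s, w in zip(starts, widths)])
    a, b = rand_set("A"), rand_set("B")
    to_pr = lambda s: pr.PyRanges(pd.DataFrame({
        "Chromosome": s.df["chrom"], "Start": s.df["start"], "End": s.df["end"]}))
    am = merge(a)
    pm = to_pr(a).merge()
    assert am.total_bp == int((pm.End - pm.Start).sum())
    got = intersect(a, b).total_bp
    pi = to_pr(a).intersect(to_pr(b)).merge()
    assert got == int((pi.End - pi.Start).sum())
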