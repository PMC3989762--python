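# strandqc

Filter-stage-aware quality control for ChIP-seq and ChIP-exo experiments.

ChIP-seq QC metrics are not filter-neutral: removing duplicated reads or
masking blacklisted regions changes the very numbers used to judge a
library, sometimes qualitatively (an excellent library can look mediocre
after the "wrong" preprocessing, and vice versa). `strandqc` computes the
established metrics at **every** filter stage — no filtering, duplicate
removal, blacklist removal, both — and reports them in the order in which
they remain interpretable, instead of pretending one number fits all
pipelines.

## Metrics

For single-end reads with strand-specific 5′-end count vectors `w[x]`
(Watson) and `c[x]` (Crick), the strand cross-correlation profile is the
Pearson correlation per candidate shift δ,

    cc(δ) = cor( w[x], c[x + δ] ),   δ = 0 … max_shift,

computed per chromosome and combined by a read-count-weighted mean.
A sequenced fragment of length *f* leaves its Watson 5′ end at the fragment
start and its Crick 5′ end at the last base, so genuine ChIP signal peaks
at δ = f − 1 (fragment lengths are reported as δ + 1); duplicated artifact
stacks place Watson/Crick 5′ ends exactly a read length *r* apart and
create the "phantom" peak at the read length.

* **NRF** — non-redundant fraction: distinct (chromosome, strand, 5′
  position) tuples over total reads; flagged at ≥ 20% duplicates for
  libraries of ≥ 10 million reads.
* **SSD** — coverage inequality: length-weighted mean across chromosomes of
  the population standard deviation of per-base depth, divided by
  (total reads / 10⁶). Exactly invariant to whole-library duplication,
  highly sensitive to artifact stacks.
* **FSC** — cc at the estimated fragment length.
* **NSC** = FSC / min(cc); **RSC** = (FSC − min cc) / (cc(r) − min cc).
* **exo-NSC** = max(cc) / min(cc) on a blacklist-filtered library — the
  ChIP-exo replacement for NSC, where fragment- and read-length peaks
  co-occur and RSC is not meaningful.

The package also ships blacklist interval analytics (merging, pairwise and
three-way overlap, class composition, per-region RPKM, fold enrichment),
two fragment-length estimators (cross-correlation argmax with optional
phantom-peak exclusion, and a paired strand-summit method), read-class
profile decomposition (in peaks / in blacklist / duplicated, inside and
outside peaks), and a synthetic aligned-read simulator with ground truth.

## Worked example

Simulate an artifact-laden ChIP library and run the staged report:

```
strandqc simulate --mode chip --out sim --seed 7 --n-stacks 10
strandqc qc --bam sim/reads.sam --blacklist sim/truth_artifacts.bed \
            --peaks sim/truth_sites.bed --read-length 28 --out qc
```

The run prints `FLAG: FRAGLEN_EQUALS_READLEN` and `qc/report.json` contains
(abridged):

```
stage      n_reads   NRF     SSD     frag_length   FSC     NSC     RSC
none       23897     0.857   179.3   28            0.014   2.48    0.010
dedup      20489     1.000    93.5   151           0.094   1.81    2.33
blacklist  21848     0.935    99.4   151           0.117   2.42    4.69
both       20422     1.000    93.6   147           0.094   1.81    2.48
```

Reading it the recommended way: at the unfiltered stage the fragment-length
estimate collapses to the read length (28 bp — the phantom peak, hence the
flag) and RSC is ~0.01, i.e. artifact signal dwarfs ChIP signal.
Blacklisting removes the stacks: the estimate recovers to ~150 bp, RSC
rises to 4.7, and SSD drops from 179 to 99 — the drop quantifies how much
of the coverage inequality was artifact. Duplicate removal alone also
rescues the estimate but at the price of depleting fragment-length signal
(FSC 0.094 vs 0.117), which is why the headline NSC/RSC are taken from the
unfiltered stage and SSD is reported both before and after blacklisting.

The same library API is available from Python:

```python
from strandqc import load_alignments, mark_duplicates, apply_filters, \
    cross_correlation, compute_metrics, load_bed

reads = mark_duplicates(load_alignments("sim/reads.sam", effective_read_length=28))
blacklist = load_bed("sim/truth_artifacts.bed")
filtered = apply_filters(reads, ("dedup", "blacklist"), blacklist=blacklist)
profile = cross_correlation(filtered, reads.chrom_lengths)
print(profile.frag_length_est, compute_metrics(profile).to_dict())
```

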