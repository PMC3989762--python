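# Methods

This note records the definitions, conventions and design decisions behind
`strandqc`, in the order a reader meets them in the code.

## Coordinates and the 5′ convention

All coordinates are 0-based half-open (BED native; SAM converted on load).
The 5′ end of a read is `start` on the forward (Watson) strand and
`end − 1` on the reverse (Crick) strand. Every strand-shift computation
anchors on these positions, so a fragment of length *f* contributes a
Watson 5′ end at its start *s* and a Crick 5′ end at *s + f − 1*. The
cross-correlation argmax therefore falls at shift *f − 1*, and fragment
lengths are reported as `argmax + 1` ("end-inclusive" convention). This
makes a duplicated stack — Watson and Crick 5′ stacks exactly a read length
*r* apart — report a fragment length of exactly *r*, which is the classic
failure mode of unfiltered artifact-heavy libraries. `cc_at_read_length`
is correspondingly the profile value at shift *r − 1*. Off-by-one choices
here shift every profile; they are fixed in `alignments.py`/`crosscorr.py`
and nowhere else.

When `effective_read_length` is given, read spans are re-trimmed in
coordinate space to that length anchored at the 5′ end, reproducing the
geometry of trimming all reads to a common length before alignment.

## Read classes and filters

* Duplicates are keyed on (chromosome, strand, 5′ position) only — the
  positional definition appropriate to single-end data; no sequence
  comparison. One read per stack survives: highest mapping quality, ties
  broken by position-sorted input order (the data give no principled
  survivor rule; this one is deterministic).
* Multi-mapped means mapping quality below a threshold, default 1, because
  BWA assigns MAPQ 0 to ambiguous placements. The definition is a
  parameter, not a constant.
* Blacklist filtering removes a read when its aligned span overlaps any
  blacklist interval by ≥ 1 bp (span overlap, not 5′ containment —
  consistent with how reads are counted inside regions). Filter stages
  commute: dedup-then-blacklist equals blacklist-then-dedup, which the
  tests assert.
* The NRF guideline flag fires when the duplicate fraction is ≥ 20% *and*
  the library has ≥ 10 million reads; a small comparison guard (1e−12)
  keeps the boundary case exact in floating point.

## SSD

The SSD formula used here is: population standard deviation of the full
per-base depth vector (zero-depth bases included) per chromosome; mean
across chromosomes weighted by chromosome length; divided by
(total mapped reads / 10⁶). This is a literal reading of "weighted mean of
the standard deviation of depth of coverage, normalised to reads
sequenced", and it has the property the tests rely on: duplicating every
read exactly doubles both numerator and normaliser, so SSD is invariant —
whereas adding a concentrated stack raises it monotonically. Whether
historical implementations normalise identically cannot be settled from
their descriptions; this formula is this package's definition and is
stated as such. Depth uses raw aligned spans (no fragment extension);
extension is a deliberate non-default because it changes SSD's meaning.

The default chromosome set for SSD is every loaded chromosome; restricting
to a representative chromosome is supported (`chroms=["chr1"]`) and keeps
the normaliser (whole-library read count) unchanged so values stay
comparable across samples.

## Cross-correlation engine

`cc(δ)` is the Pearson correlation of `w[0:L−δ]` with `c[δ:L]` for every
integer shift 0…`max_shift` (default 400 — profiles must comfortably
contain both the read-length and fragment-length features; coarser grids
would make the argmax inexact). It is computed from the sparse 5′-count
representation: pairwise Watson/Crick position differences binned into
shifts give the cross-products, prefix sums give the window sums and sums
of squares, so the result is exact (the suite checks agreement with a
dense brute-force Pearson to 1e−12) at a cost proportional to reads rather
than genome length. Chromosomes contribute when they hold at least two
reads on each strand, and are combined by a read-count-weighted mean per
shift; degenerate windows yield NaN and drop out of the mean. Argmax ties
break to the smallest shift.

`estimate_fragment_length` takes the global argmax by default — thereby
reproducing, on purpose, the phantom failure mode on unfiltered data —
and with `exclude_read_length=True` masks fragment lengths within ±5 bp of
the read length first. NSC and RSC are reported as undefined (with an
explanatory note) when the profile minimum is not positive, rather than
returning a sign-flipped ratio. When a profile comes from a
blacklist-filtered set, RSC is accompanied by a caveat note: with the
artifact peak removed, cc(r) sits on the tail of the fragment-length peak
and RSC measures peak width rather than signal-to-artifact.

The paired strand-summit estimator slides a 300 bp window (mfold 10) over
per-strand 5′ counts, pairs each Watson summit with the nearest Crick
summit strictly downstream within 4 windows, and reports the median summit
distance — or `None` when no pair qualifies (e.g. featureless input).
These defaults are a documented simplification of the peak-caller
heuristic it imitates, not a reimplementation; the method inherits that
heuristic's sensitivity to artifact stacks tall enough to qualify as
summits, which the tests exercise.

## ChIP-exo

In exo libraries the exonuclease trims fragments to the protein footprint:
fragment- and read-length peaks co-occur near the read length, RSC is not
interpretable, and duplication at the protected borders is largely
legitimate signal. The pipeline therefore (in `mode="chipexo"`): retains
duplicates in its recommended stage, suppresses RSC, and reports
exo-NSC = max(cc)/min(cc), computed only on blacklist-filtered profiles
(enforced via provenance) since the ratio is meaningless while aberrant
stacks still dominate the maximum.

## The simulator

`simulate_chip` draws, per site, a negative-binomial number of fragments
(mean 50, dispersion 10 by default) of fixed length f₀ = 150 bp centred on
the site with Gaussian jitter (sd 10 bp), sequencing each from a uniformly
chosen end; `simulate_exo` instead stacks 5′ ends at site ± border
(default 10 bp, jitter clipped to ±2 bp), giving high legitimate
duplication; `simulate_input` emits background only. Artifact stacks emit
`depth` forward reads at a position and `depth` reverse reads one read
length downstream — precisely the geometry that produces the phantom peak
— and are placed clear of site windows so the emitted truth BEDs separate
artifact from signal cleanly. Reads are emitted directly as coordinate-
sorted SAM with placeholder bases (the metrics depend only on coordinates,
strand and MAPQ; MAPQ is 37, with a 2% MAPQ-0 "multi-mapped" fraction).
One integer seed drives independent sub-streams per component, so adding
sites does not perturb the background stream; identical seeds give
byte-identical output.

Background reads follow a two-level accessibility field: 10% of the genome
lies in 5 kb "open" islands holding 80% of the background mass. This is
deliberate, not a convenience: the Pearson correlation of two *independent*
uniform strands is mean-zero, so the profile minimum straddles zero and
every background-anchored ratio (NSC, exo-NSC) is undefined by
construction. In real data those ratios exist because regional coverage
biases are shared by the two strands, producing a flat positive baseline;
the island field is the minimal generator of that baseline. Setting the
island weight equal to the island fraction recovers iid-uniform
background. The default library (~2000 site reads, 20000 background reads)
keeps background the large majority, as in real libraries — this is also
what keeps the baseline positive when artifact stacks inflate the strand
variances.

What the simulator does **not** model: sequencing errors, GC and
mappability bias, broad histone-mark domains, paired-end reads, optical
duplicates. Tests passing on these fixtures show the metrics respond
correctly to the coordinate-level structure they are defined on; they do
not certify behaviour under alignment artifacts the simulator omits.

## Fixture sizes and statistical power

Problem sizes in the tests and in `scripts/acceptance.py` are chosen so
that each qualitative claim is decidable at the stated tolerance:

* Fragment-length recovery uses 21 libraries (7 seeds × f₀ ∈ {100, 150,
  200}) of ~2000 site + 2000 background reads; the median absolute error
  bound (≤ 5 bp) tolerates the jitter-broadened peak.
* Artifact-failure and filter-effect suites use 20 seeds each and require
  ≥ 18/20 agreement, leaving room for the occasional noisy seed.
* The class-profile decomposition and RSC/FSC stage comparisons use
  deeper sites (mean 100 reads/site): the duplicated-inside-peaks class is
  a small subset, and localising its argmax to ±5 bp needs that depth.
* The exo null fixture (exo-NSC ≈ 1) uses 200k background reads on a 2 Mb
  chromosome with 50 kb islands. A power computation fixes these sizes:
  the per-shift Pearson noise is ~1/√L, the max/min over ~400 shifts
  spans roughly ±3 noise sd around the baseline, and the field's
  autocovariance must be flat across the shift grid (correlation length ≫
  max_shift), otherwise the *expected* profile itself tilts. Smaller or
  rougher fixtures cannot resolve a ratio of 1 to within 0.1 regardless of
  implementation correctness.

## Known limitations

* Single-end only; paired-end duplicate logic and fragment inference are
  out of scope.
* Blacklists are consumed, never constructed; mappability is not modelled.
* The SSD normalisation is this package's fixed definition (above);
  absolute SSD values need not match other tools, though orderings and
  the invariances do.
* exo-NSC requires a positive profile minimum; very sparse libraries
  return "undefined" rather than a number.
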