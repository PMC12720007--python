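# Methods

## Coordinate model

All coordinates are 0-based half-open (the BED convention). An interval
`[start, end)` has length `end − start`; two intervals overlap by
`max(0, min(end_a, end_b) − max(start_a, start_b))` bp, so abutting
intervals (`[0,100)` vs `[100,200)`) do not overlap. The shared/unique
partition uses a minimum overlap of 1 bp by default: a peak of set A is
*shared* iff at least one peak of B overlaps it by ≥ `min_overlap` bp. A
peak overlapping several partners counts once in the shared set; the pair
list still enumerates every qualifying partner, so pair-based statistics
remain available.

Exclusion filtering (blacklist regions, subtelomeres) removes whole peaks
that touch a mask by ≥ 1 bp rather than trimming them, matching the
region-drop behaviour of coverage tooling. Subtelomeres are defined
operationally as the terminal 500 kb of each chromosome (margin
configurable); when twice the margin reaches the chromosome length the two
windows merge into one whole-chromosome interval. Exclusion is exposed as
an optional pre-filter: overlap statistics can be computed before or after
it, and both are reportable, since the choice is a genuine analysis degree
of freedom.

Duplicate peak records are kept (replicated summits can be real); a
warning is logged. Peak files without attached chromosome sizes accept any
chromosome name; with sizes attached, unknown names or out-of-bounds
coordinates fail fast.

## Telomeric repeat scanning and classification

The repeat unit is the exact hexamer TTAGGG, scanned together with its
reverse complement CCCTAA so the strand of the peak or of the underlying
array is irrelevant; counts for the two orientations are summed (and
reported separately). Matching is case-insensitive by default; `N` never
matches. A `respect_softmask` switch makes lowercase (soft-masked)
sequence unmatchable for genomes where that distinction matters.
Degenerate or variant units (TTAGG, TGAGGG, …) are not matched — exact
hexamers only.

A *tandem run* is a maximal series of occurrences of the *same* motif at
exactly 6-bp spacing. A single intervening base breaks a run, and a strand
change breaks a run: a biological telomeric array is strand-uniform, so a
TTAGGG occurrence directly followed by CCCTAA is a junction artifact, not
a 2-unit array. Every occurrence belongs to exactly one run (possibly of
length 1), which gives the conservation property `sum(run lengths) = total
occurrences` used throughout the tests.

Peaks are classified by repeat content:

| type | definition |
|------|------------|
| I    | no telomeric repeat |
| II   | exactly one repeat |
| III  | ≥ 2 repeats, no run reaching the tandem minimum |
| IV   | exactly one run of ≥ `min_tandem_units` |
| V    | two or more such runs |

The classes are exhaustive and mutually exclusive for every syntactically
valid profile. `min_tandem_units` defaults to 4, the threshold taken as
necessary for stable R-loop formation in cells; the in-vitro floor of 3 is
available by changing the filter. The tandem filter (types IV–V, i.e.
longest run ≥ minimum) is the predictor of RNA-dependent R-loop formation
that the downstream summaries quantify.

## Permutation test of overlap significance

Null model: every peak is re-placed independently and uniformly on its own
chromosome (`start ~ U[0, L − length]`), preserving the number, length and
chromosome distribution of each set. Both sets are re-randomized per
permutation by default (single-set modes are available for sensitivity
analysis). Randomized peaks may overlap each other, as under the plain
null. The "mappable genome" is approximated by full chromosome lengths; an
optional placement mask (e.g. blacklist + subtelomeres) removes regions by
rejection sampling with a bound of 1000 attempts per peak, after which an
infeasible mask raises rather than silently biasing placement.

The test statistic is the shared-A peak count (pair count available by
flag). With `r` of `n` null statistics ≥ the observed value, the primary
p-value is the raw empirical proportion `r/n`; because that estimator can
be exactly 0, the `(r+1)/(n+1)` pseudocount form is always reported
alongside, together with the null mean, SD and z-score. 1000 permutations
is the default. Determinism: the whole test is a pure function of the
seed.

Calibration note: the statistic is integer-valued, so empirical p-values
are discrete. The uniformity (calibration) test in the suite therefore
uses set sizes (300 peaks/set on a 2-Mb chromosome) at which the null
distribution spreads over enough support points for a Kolmogorov–Smirnov
uniformity check to be meaningful; with very sparse sets the p-value
distribution is dominated by a few atoms and a KS check against the
continuous uniform is not informative.

## Annotation

Gene models come from BED12 (exons reconstructed from the block fields;
TSS = `tx_start` on `+`, `tx_end` on `−`). A peak's category is decided by
its **midpoint** with precedence *promoter-TSS > TTS > exon > intron >
intergenic*; windows are explicit configuration, defaulting to 1000 bp
upstream / 100 bp downstream of the TSS (mirror image around the TTS),
oriented by strand. UTRs are folded into the exon category: BED12 does not
carry CDS-independent UTR structure reliably, so a separate 3′/5′-UTR
slice is deliberately not reported. The nearest-TSS search is
chromosome-local (ties broken by lexicographic gene id); peaks on
gene-free chromosomes get an empty association rather than a
cross-chromosome match. Gene-list overlap uses distinct nearest-gene
values, optionally restricted by a maximum |TSS distance|, and reports the
three Venn counts.

## Summary statistics

The repeat-content summary reports, for the shared and unique partitions
separately: peak counts, counts and percentages with ≥ 1 repeat, the
within-subpopulation split into single vs multiple repeats (the printed
denominators of the source analysis imply conditioning on the ≥ 1-repeat
subpopulation, and the medians are conditioned the same way), the share of
all repeat occurrences falling in each partition (occurrences, not tandem
units), and tandem-filter pass counts and percentages. Group comparisons
use Welch's unequal-variance two-sided t-test by default — the safer
choice for the very unequal group sizes these comparisons involve — with
the pooled-variance variant behind a flag. Degenerate input (a group of
< 2 values, or zero combined variance) raises.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not read-level data: it starts at the peak level, which is the pipeline's
input boundary.

- **Genome**: default five 2-Mb chromosomes (10 Mb total — large enough
  for stable permutation nulls, small enough that the full suite runs in
  minutes). Background bases are i.i.d. with configurable GC (default
  0.42, roughly mammalian), and the background is *verified* motif-free:
  any spontaneous TTAGGG/CCCTAA is locally re-rolled, keeping generation
  linear in genome length.
- **Arrays**: default 30 tandem arrays of 1–12 units, strand chosen with
  probability 0.5, planted by overwriting at recorded coordinates with
  ≥ 20 bp clearance between arrays; junction bases are re-rolled if
  planting spells out an extra motif, so scanner totals over each array
  equal the planted unit count exactly. Arrays avoid the 500-kb
  subtelomeric margins by construction, so exclusion filtering never
  silently changes planted-truth accounting (a flag places arrays inside
  the margins to exercise the exclusion path).
- **Peaks**: default 1000 per set, lengths uniform 150–1000 bp. A fraction
  of A peaks (default 3 %, the overlap scale of the motivating datasets)
  is forced to overlap a B peak; a quarter of those are centred on arrays
  of ≥ 4 units, with both partners fully containing the array, so repeat
  content concentrates in overlapping peaks. All other peaks avoid arrays.
  Chance overlaps between the sets are permitted by default and the
  realized shared count is recorded in `truth.json`; with
  `exact_bookkeeping=True` placement rejects chance cross-set overlaps so
  the designed pair list predicts the shared count exactly.
- **Genes**: non-overlapping 2–4-exon genes of 5–50 kb on both strands;
  TSS positions recorded. `truth.json` also records the annotation
  category counts of the designed-shared peaks computed at generation
  time, so re-running the pipeline from the written files must reproduce
  them exactly.

What the generator does *not* emulate: mappability structure, GC-driven
coverage bias, peak-width/signal correlation, replicate noise, or genuine
sequence context around arrays. Passing tests on these fixtures therefore
demonstrates algorithmic correctness (exact planted-truth recovery,
calibrated significance under the stated null) rather than robustness to
real-data artifacts.

## Numerical and design choices

- The full fixture, every permutation test and every report are pure
  functions of their seeds; reports are written with sorted keys so
  repeated runs are byte-identical.
- narrowPeak extra columns are preserved through read/write; write → read
  → write is byte-stable (numbers serialized in `%g`-style canonical
  form).
- Percentages are reported to one decimal. Note that 513/689 = 74.5 % and
  176/689 = 25.5 %: these are quoted as "~75 %" and "~25 %" (quarters) in
  the source analysis; the package reports the exact values.
- Rejection-sampling bounds (1000 attempts) guard every constrained
  placement; infeasible configurations raise instead of degrading.
- The library is the interface; the `telopeaks` CLI is a thin wrapper for
  shell use and adds no behaviour of its own.

## Limitations

- Annotation approximates HOMER-style midpoint assignment with fixed
  windows; it is not isoform-aware and does not sub-classify UTRs.
- Only exact hexamer matches are counted; diverged telomeric repeats are
  invisible to the scanner by design.
- The permutation null ignores mappability and chromatin accessibility
  structure unless a placement mask is supplied; p-values against the
  plain null are anti-conservative if real peaks are confined to a small
  mappable fraction.
- Peak calling, read processing, coverage heatmaps and motif discovery are
  out of scope: peaks are the input boundary.
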