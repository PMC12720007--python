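# telopeaks

Analysis toolkit for asking whether a chromatin-associated RNA's occupancy
peaks coincide with R-loop peaks, and whether that coincidence tracks
tandem telomeric repeat content — the computational core of studies of
TERRA (telomeric repeat-containing RNA) binding to non-telomeric DNA via
R-loop formation.

Given two peak sets in BED/narrowPeak format (e.g. TERRA CHIRT-seq and
R-loop DRIP-seq peaks), a genome FASTA, chromosome sizes and gene models in
BED12, the package:

- partitions peaks into **shared** (≥ 1 bp intersection with the other set)
  and **unique**, with per-chromosome count and length summaries;
- scans each peak for the telomeric hexamer **TTAGGG** and its reverse
  complement **CCCTAA**, finds maximal zero-gap **tandem runs**, and
  classifies each peak into types **I–V** (no repeat / single repeat /
  scattered repeats / one tandem stretch of ≥ 4 units / multiple such
  stretches);
- tests overlap significance with a constrained **permutation test**:
  peaks are re-placed uniformly on their own chromosomes, preserving
  number, length and chromosome distribution, and the empirical p-value is
  the fraction of 1000 randomized datasets whose overlap statistic reaches
  the observed one;
- filters peaks against exclusion regions (blacklist, 500-kb subtelomeric
  margins) by whole-peak removal;
- annotates peaks (promoter-TSS / exon / intron / TTS / intergenic, by peak
  midpoint with explicit window config), finds the nearest TSS, and
  intersects peak-associated genes with an external (e.g. differential
  expression) gene list;
- computes the headline repeat-content statistics of the shared/unique
  partition (fractions of peaks with ≥ 1 repeat, conditioned medians,
  repeat share, tandem-filter pass rates) and Welch t-tests between groups;
- generates **synthetic fixtures** — a genome with a motif-free background
  and planted tandem arrays at recorded loci, peak sets with designed
  overlap, toy gene models, and a `truth.json` — so the entire pipeline can
  be validated against planted ground truth.

## Worked example

```python
from telopeaks import (SynthConfig, write_fixture, read_bed, read_chrom_sizes,
                       intersect, profile_peaks, repeat_content_summary,
                       permutation_test, TandemFilter)
from telopeaks.permutation import PermutationConfig

cfg = SynthConfig(seed=42, n_peaks_a=200, n_peaks_b=200,
                  target_overlap_fraction=0.1, exact_bookkeeping=True)
fx = write_fixture(cfg, "demo_fixture")
sizes = read_chrom_sizes(fx.chrom_sizes)
a = read_bed(fx.peaks_a, "bed6", sizes, label="TERRA")
b = read_bed(fx.peaks_b, "bed6", sizes, label="RLOOP")

res = intersect(a, b)
print(f"shared A peaks: {len(res.shared_a)} / {len(a)}")

profiles = profile_peaks(a, fx.genome, TandemFilter(4))
s = repeat_content_summary(res, profiles)
print(f"peaks with >=1 repeat: shared {s.pct_shared_ge1:.1f}%, unique {s.pct_unique_ge1:.1f}%")
print(f"repeat share in shared peaks: {100*s.repeat_share_shared:.1f}%")
print(f"tandem-passing shared peaks: {s.n_shared_tandem} ({s.pct_shared_tandem:.1f}%)")

perm = permutation_test(a, b, sizes, PermutationConfig(n_permutations=1000, seed=1))
print(f"observed overlap {perm.observed}, null mean {perm.null_mean:.2f}, "
      f"p = {perm.p_empirical:.4g} (pseudocount {perm.p_pseudocount:.4g})")
```

Output:

```
shared A peaks: 20 / 200
peaks with >=1 repeat: shared 25.0%, unique 0.0%
repeat share in shared peaks: 100.0%
tandem-passing shared peaks: 5 (25.0%)
observed overlap 20, null mean 4.48, p = 0 (pseudocount 0.000999)
```

All 20 designed overlaps are recovered; the 5 peaks centred on planted
arrays of ≥ 4 tandem units carry 100 % of the genome's telomeric repeat
content and are the only tandem-filter passes; and the observed overlap
exceeds every one of 1000 randomized placements, so the raw empirical
p-value is 0 (reported alongside its (r+1)/(n+1) pseudocount form,
here 1/1001).

A `telopeaks` console command exposes the same steps
(`intersect`, `scan`, `permtest`, `annotate`, `summarize`, `simulate`);
run `telopeaks --help`.

## Layout

- `src/telopeaks/intervals.py` — interval model, BED I/O, intersection,
  exclusion, per-chromosome summaries
- `src/telopeaks/repeats.py` — motif scanning, tandem runs, type I–V
  classification, FASTA profiling
- `src/telopeaks/permutation.py` — constrained randomization test
- `src/telopeaks/annotation.py` — BED12 gene models, category assignment,
  nearest TSS, gene-list overlap
- `src/telopeaks/summary.py` — repeat-content summary, t-tests, JSON report
- `src/telopeaks/synthetic.py` — fixture generator with ground truth
- `docs/methods.md` — models, parameters, numerical choices, limitations
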