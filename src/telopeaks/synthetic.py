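"""Synthetic fixture generator: genome with planted telomeric arrays,
peak sets with controlled overlap, gene models, and a ground-truth record.

The generator emulates the statistical structure the analysis assumes: a
multi-chromosome genome whose background is verified free of the telomeric
hexamer, tandem TTAGGG/CCCTAA arrays planted at recorded loci, two peak
sets in which a configured fraction of A peaks is forced to overlap a B
peak (a subset of those centred on planted arrays, so repeat enrichment
concentrates in overlapping peaks), and non-overlapping multi-exon gene
models.  Every planted quantity is written to ``truth.json`` so pipeline
output can be checked against ground truth.

The whole fixture is a pure function of :class:`SynthConfig`; with
``exact_bookkeeping`` enabled, chance overlaps between the two peak sets
are rejected during placement so the designed pair list predicts the
shared-peak count exactly.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree

from telopeaks.annotation import GeneModel, write_gene_models
from telopeaks.intervals import ChromSizes, GenomicInterval, PeakSet, write_bed
from telopeaks.repeats import TELOMERIC

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MAX_TRIES = 1000
_ARRAY_GAP = 20  # bp kept clear around each planted array

TRUTH_SCHEMA = "telopeaks-truth-1"


@dataclass
class SynthConfig:
    """Study conditions for one synthetic fixture.

    Defaults: five 2-Mb chromosomes (10 Mb total), 30 planted arrays of
    1-12 units, 1000 peaks per set of 150-1000 bp, 3 % of A peaks forced
    onto B peaks with a quarter of those centred on tandem-qualifying
    arrays — the overlap and enrichment structure of the real datasets at
    desk scale.
    """

    chrom_lengths: tuple[int, ...] = (2_000_000,) * 5
    n_arrays: int = 30
    array_units_min: int = 1
    array_units_max: int = 12
    strand_mix: float = 0.5
    n_peaks_a: int = 1000
    n_peaks_b: int = 1000
    peak_length_min: int = 150
    peak_length_max: int = 1000
    target_overlap_fraction: float = 0.03
    fraction_shared_on_arrays: float = 0.25
    on_array_min_units: int = 4
    gc_background: float = 0.42
    n_genes: int = 50
    subtel_margin: int = 500_000
    arrays_in_margins: bool = False
    exact_bookkeeping: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.strand_mix, self.target_overlap_fraction,
                     self.fraction_shared_on_arrays, self.gc_background):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.peak_length_min < 1 or self.peak_length_min > self.peak_length_max:
            raise ValueError("invalid peak length range")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths))]

    def chromsizes(self) -> ChromSizes:
        return ChromSizes(dict(zip(self.chrom_names, self.chrom_lengths)))


@dataclass
class SynthTruth:
    """Ground truth for one fixture: planted arrays, designed overlaps,
    peak-to-array assignments and generated gene TSS positions."""

    arrays: list[dict] = field(default_factory=list)
    designed_pairs: list[tuple[str, str]] = field(default_factory=list)
    peak_on_array: dict[str, int] = field(default_factory=dict)
    gene_tss: dict[str, int] = field(default_factory=dict)
    realized_shared_a: int | None = None
    realized_overlap_fraction: float | None = None
    annotation_counts: dict[str, int] | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema"] = TRUTH_SCHEMA
        return d


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _random_background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _find_motifs(seq: bytes) -> list[tuple[int, str]]:
    hits = []
    for motif in (TELOMERIC.forward, TELOMERIC.reverse):
        m = motif.encode()
        pos = seq.find(m)
        while pos != -1:
            hits.append((pos, motif))
            pos = seq.find(m, pos + 1)
    return hits


def _scrub_region(
    seq: np.ndarray,
    rng: np.random.Generator,
    gc: float,
    protected: IntervalTree,
    lo: int = 0,
    hi: int | None = None,
) -> None:
    """Re-roll bases until [lo, hi) holds no motif occurrence outside the
    protected (planted-array) intervals.  Local re-rolls keep generation
    linear in genome length."""
    hi = len(seq) if hi is None else hi
    for _ in range(200):
        window = seq[lo:hi].tobytes()
        dirty = False
        for pos, _motif in _find_motifs(window):
            abs_start = lo + pos
            span = protected.overlap(abs_start, abs_start + 6)
            if span and any(o.begin <= abs_start and abs_start + 6 <= o.end for o in span):
                continue  # the planted array itself
            for i in range(abs_start, abs_start + 6):
                if not protected.overlap(i, i + 1):
                    seq[i] = _random_background(1, gc, rng)[0]
                    dirty = True
        if not dirty:
            return
    raise RuntimeError("could not scrub spurious motif occurrences")


def make_genome(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], SynthTruth]:
    """Generate chromosome sequences with planted arrays.

    The background is i.i.d. at the configured GC and verified motif-free;
    arrays are inserted by overwriting at recorded coordinates, and the
    flanking bases are re-rolled if the junction happens to spell out an
    extra motif, so scanner totals over each array equal the planted unit
    count exactly.
    """
    seqs: dict[str, np.ndarray] = {}
    truth = SynthTruth()
    names = config.chrom_names

    # assign arrays to chromosomes round-robin for an even spread
    arrays_per_chrom: dict[str, list[int]] = {n: [] for n in names}
    for i in range(config.n_arrays):
        arrays_per_chrom[names[i % len(names)]].append(i)

    array_records: list[dict | None] = [None] * config.n_arrays
    for ci, chrom in enumerate(names):
        length = config.chrom_lengths[ci]
        seq = _random_background(length, config.gc_background, rng)
        protected = IntervalTree()
        _scrub_region(seq, rng, config.gc_background, protected)

        placed = IntervalTree()
        for ai in arrays_per_chrom[chrom]:
            units = int(rng.integers(config.array_units_min, config.array_units_max + 1))
            motif = TELOMERIC.reverse if rng.random() < config.strand_mix else TELOMERIC.forward
            span = 6 * units
            if config.arrays_in_margins:
                lo, hi = 0, min(config.subtel_margin, length) - span
            else:
                lo = config.subtel_margin + _ARRAY_GAP
                hi = length - config.subtel_margin - span - _ARRAY_GAP
            if hi <= lo:
                raise RuntimeError(f"no room for array on {chrom}")
            for _ in range(_MAX_TRIES):
                start = int(rng.integers(lo, hi))
                if not placed.overlap(start - _ARRAY_GAP, start + span + _ARRAY_GAP):
                    break
            else:
                raise RuntimeError(f"cannot place array {ai} on {chrom} with required gaps")
            seq[start : start + span] = np.frombuffer((motif * units).encode(), dtype=np.uint8)
            placed.addi(start, start + span)
            protected.addi(start, start + span)
            array_records[ai] = {
                "chrom": chrom, "start": start, "end": start + span,
                "motif": motif, "n_units": units,
            }
            _scrub_region(seq, rng, config.gc_background, protected,
                          max(0, start - 7), min(length, start + span + 7))
        seqs[chrom] = seq
    truth.arrays = [r for r in array_records if r is not None]
    return seqs, truth


def write_fasta(seqs: dict[str, np.ndarray], path: str | Path, width: int = 80) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            raw = seq.tobytes().decode()
            for i in range(0, len(raw), width):
                fh.write(raw[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

def _draw_length(config: SynthConfig, rng: np.random.Generator, minimum: int = 0) -> int:
    lo = max(config.peak_length_min, minimum)
    hi = max(config.peak_length_max, lo)
    return int(rng.integers(lo, hi + 1))


class _Placer:
    """Rejection-sampling placement with per-chromosome avoid-trees."""

    def __init__(self, config: SynthConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        lengths = np.array(config.chrom_lengths, dtype=float)
        self.chrom_p = lengths / lengths.sum()
        self.names = config.chrom_names

    def draw(self, length: int, avoid: dict[str, IntervalTree]) -> tuple[str, int]:
        for _ in range(_MAX_TRIES):
            chrom = self.names[int(self.rng.choice(len(self.names), p=self.chrom_p))]
            L = self.config.chromsizes()[chrom]
            if length > L:
                continue
            start = int(self.rng.integers(0, L - length + 1))
            tree = avoid.get(chrom)
            if tree is None or not tree.overlap(start, start + length):
                return chrom, start
        raise RuntimeError("placement rejection bound exceeded (peak density infeasible)")


def make_peaks(
    config: SynthConfig, truth: SynthTruth, rng: np.random.Generator
) -> tuple[PeakSet, PeakSet, SynthTruth]:
    """Generate peak sets A and B with the designed overlap structure.

    ``round(target_overlap_fraction * n_peaks_a)`` A peaks are forced to
    overlap a B peak; of those, ``fraction_shared_on_arrays`` are centred
    on planted arrays of at least ``on_array_min_units`` units, with both
    partners fully containing the array.  All other peaks avoid planted
    arrays, so repeat content is confined to the designed on-array peaks.
    """
    chromsizes = config.chromsizes()
    array_tree: dict[str, IntervalTree] = {}
    for arr in truth.arrays:
        array_tree.setdefault(arr["chrom"], IntervalTree()).addi(
            arr["start"] - 1, arr["end"] + 1
        )

    placer = _Placer(config, rng)
    a_tree: dict[str, IntervalTree] = {}
    b_tree: dict[str, IntervalTree] = {}

    def _add(tree: dict[str, IntervalTree], chrom: str, s: int, e: int) -> None:
        tree.setdefault(chrom, IntervalTree()).addi(s, e)

    def _merge(*trees_list: dict[str, IntervalTree]) -> dict[str, IntervalTree]:
        out: dict[str, IntervalTree] = {}
        for trees in trees_list:
            for chrom, t in trees.items():
                out.setdefault(chrom, IntervalTree()).update(t)
        return out

    ivs_a: list[GenomicInterval] = []
    ivs_b: list[GenomicInterval] = []
    n_designed = round(config.target_overlap_fraction * config.n_peaks_a)
    n_on_array = round(config.fraction_shared_on_arrays * n_designed)

    qualifying = [
        i for i, arr in enumerate(truth.arrays)
        if arr["n_units"] >= config.on_array_min_units
    ]
    if len(qualifying) < n_on_array:
        raise RuntimeError(
            f"only {len(qualifying)} arrays with >= {config.on_array_min_units} "
            f"units available for {n_on_array} on-array peaks"
        )
    chosen_arrays = [qualifying[int(i)] for i in rng.choice(len(qualifying), size=n_on_array, replace=False)]

    pair_idx = 0
    for k in range(n_designed):
        a_name = f"A_{pair_idx:05d}"
        b_name = f"B_{pair_idx:05d}"
        if k < n_on_array:
            ai = chosen_arrays[k]
            arr = truth.arrays[ai]
            chrom = arr["chrom"]
            span = arr["end"] - arr["start"]
            len_a = _draw_length(config, rng, minimum=span + 2)
            len_b = _draw_length(config, rng, minimum=span + 2)
            # both partners fully contain the array
            sa = int(rng.integers(arr["end"] - len_a, arr["start"] + 1))
            sb = int(rng.integers(arr["end"] - len_b, arr["start"] + 1))
            truth.peak_on_array[a_name] = ai
            truth.peak_on_array[b_name] = ai
        else:
            len_a = _draw_length(config, rng)
            len_b = _draw_length(config, rng)
            avoid = _merge(array_tree, a_tree, b_tree) if config.exact_bookkeeping else array_tree
            for _ in range(_MAX_TRIES):
                chrom, sa = placer.draw(len_a, avoid)
                # partner B overlaps A by at least 1 bp, shifted randomly
                shift = int(rng.integers(-(len_b - 1), len_a))
                sb = sa + shift
                L = chromsizes[chrom]
                if sb < 0 or sb + len_b > L:
                    continue
                bt = _merge(array_tree, a_tree, b_tree) if config.exact_bookkeeping else array_tree
                t = bt.get(chrom)
                if t is None or not t.overlap(sb, sb + len_b):
                    break
            else:
                raise RuntimeError("cannot place designed overlap pair")
        ivs_a.append(GenomicInterval(chrom, sa, sa + len_a, a_name))
        ivs_b.append(GenomicInterval(chrom, sb, sb + len_b, b_name))
        _add(a_tree, chrom, sa, sa + len_a)
        _add(b_tree, chrom, sb, sb + len_b)
        truth.designed_pairs.append((a_name, b_name))
        pair_idx += 1

    # background peaks: avoid arrays always; in exact mode also avoid the
    # other set so chance collisions cannot blur the designed overlap count.
    # Background A is placed before background B, so avoiding the then-fixed
    # b_tree (and, for B, the completed a_tree) rules out all cross-set hits.
    avoid_a = _merge(array_tree, b_tree) if config.exact_bookkeeping else array_tree
    for i in range(config.n_peaks_a - n_designed):
        length = _draw_length(config, rng)
        chrom, s = placer.draw(length, avoid_a)
        name = f"A_bg_{i:05d}"
        ivs_a.append(GenomicInterval(chrom, s, s + length, name))
        _add(a_tree, chrom, s, s + length)
    avoid_b = _merge(array_tree, a_tree) if config.exact_bookkeeping else array_tree
    for i in range(config.n_peaks_b - n_designed):
        length = _draw_length(config, rng)
        chrom, s = placer.draw(length, avoid_b)
        name = f"B_bg_{i:05d}"
        ivs_b.append(GenomicInterval(chrom, s, s + length, name))
        _add(b_tree, chrom, s, s + length)

    a = PeakSet("A", sorted(ivs_a, key=GenomicInterval.sort_key), chromsizes)
    b = PeakSet("B", sorted(ivs_b, key=GenomicInterval.sort_key), chromsizes)
    return a, b, truth


# ---------------------------------------------------------------------------
# Genes
# ---------------------------------------------------------------------------

def make_genes(
    config: SynthConfig, truth: SynthTruth, rng: np.random.Generator
) -> list[GeneModel]:
    """Non-overlapping multi-exon genes on both strands; TSS recorded in truth."""
    chromsizes = config.chromsizes()
    placer = _Placer(config, rng)
    occupied: dict[str, IntervalTree] = {}
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        length = int(rng.integers(5_000, 50_001))
        chrom, start = placer.draw(length, occupied)
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 5))
        # cut the transcript into 2*n_exons-1 alternating exon/intron pieces
        cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False))
        bounds = np.concatenate([[0], cuts, [length]])
        blocks = tuple(
            (start + int(bounds[j]), start + int(bounds[j + 1]))
            for j in range(0, 2 * n_exons - 1, 2)
        )
        gene = GeneModel(f"gene_{i:04d}", chrom, strand, start, end, blocks)
        genes.append(gene)
        occupied.setdefault(chrom, IntervalTree()).addi(start - 1000, end + 1000)
        truth.gene_tss[gene.gene_id] = gene.tss
    return genes


# ---------------------------------------------------------------------------
# Fixture assembly
# ---------------------------------------------------------------------------

@dataclass
class FixturePaths:
    root: Path
    genome: Path
    peaks_a: Path
    peaks_b: Path
    genes: Path
    chrom_sizes: Path
    truth: Path


def write_fixture(config: SynthConfig, out_dir: str | Path) -> FixturePaths:
    """Generate the complete fixture directory.

    Writes genome.fa, a.bed, b.bed, genes.bed12, chrom.sizes and
    truth.json; on any failure the partially written directory is removed.
    The realized shared-A count and the annotation category counts of the
    designed-shared peaks are computed at generation time and recorded in
    truth.json.
    """
    from telopeaks.annotation import annotate_peaks
    from telopeaks.intervals import intersect

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        rng = np.random.default_rng(config.seed)
        seqs, truth = make_genome(config, rng)
        a, b, truth = make_peaks(config, truth, rng)
        genes = make_genes(config, truth, rng)

        result = intersect(a, b)
        truth.realized_shared_a = len(result.shared_a)
        truth.realized_overlap_fraction = len(result.shared_a) / len(a)
        records = annotate_peaks(result.shared_a, genes)
        from collections import Counter

        truth.annotation_counts = dict(Counter(r.category for r in records))

        paths = FixturePaths(
            root=out_dir,
            genome=write_fasta(seqs, out_dir / "genome.fa"),
            peaks_a=write_bed(a, out_dir / "a.bed"),
            peaks_b=write_bed(b, out_dir / "b.bed"),
            genes=write_gene_models(genes, out_dir / "genes.bed12"),
            chrom_sizes=config.chromsizes().to_file(out_dir / "chrom.sizes"),
            truth=out_dir / "truth.json",
        )
        doc = truth.to_dict()
        doc["config"] = asdict(config)
        with open(paths.truth, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths
    except Exception:
        shutil.rmtree(out_dir, ignore_errors=True)
        raise


def load_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
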