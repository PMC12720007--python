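"""Genomic-interval data model, BED-family I/O, and interval set operations.

Coordinates are 0-based half-open throughout (the BED convention): an
interval ``[start, end)`` covers ``end - start`` bases, and two intervals
that merely abut (``[0, 100)`` vs ``[100, 200)``) do not overlap.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_DIALECT_COLUMNS = {"bed3": 3, "bed6": 6, "narrowpeak": 10}


class BedFormatError(ValueError):
    """Raised when a BED-family file cannot be parsed."""


@dataclass(frozen=True)
class ChromSizes:
    """Chromosome name -> length (bp) mapping with stable iteration order."""

    entries: Mapping[str, int]

    def __post_init__(self) -> None:
        entries = dict(self.entries)
        for name, length in entries.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "entries", entries)

    def __getitem__(self, chrom: str) -> int:
        return self.entries[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.entries

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def items(self):
        return self.entries.items()

    @classmethod
    def from_file(cls, path: str | Path) -> "ChromSizes":
        entries: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise BedFormatError(f"{path}:{lineno}: expected 'name<TAB>length'")
                name, length = fields[0], fields[1]
                if name in entries:
                    raise BedFormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
                entries[name] = int(length)
        return cls(entries)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for name, length in self.entries.items():
                fh.write(f"{name}\t{length}\n")
        return path


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column ``name<TAB>length`` chrom.sizes file."""
    return ChromSizes.from_file(path)


@dataclass(frozen=True)
class GenomicInterval:
    """One peak: half-open genomic coordinates plus optional metadata.

    ``metadata`` carries narrowPeak extras (signalValue, pValue, qValue,
    summit) when present.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float | None = None
    strand: str = "."
    metadata: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} for {self.name}")
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.name}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if isinstance(self.metadata, dict):
            object.__setattr__(self, "metadata", tuple(self.metadata.items()))

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def meta(self) -> dict[str, object]:
        return dict(self.metadata)

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Half-open overlap in bp; 0 when disjoint or on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def sort_key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.name)


@dataclass
class PeakSet:
    """A labelled, ordered collection of peaks, optionally bound to ChromSizes."""

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    chromsizes: ChromSizes | None = None

    def __post_init__(self) -> None:
        self.intervals = list(self.intervals)
        self.validate()

    def validate(self) -> None:
        if self.chromsizes is not None:
            for iv in self.intervals:
                if iv.chrom not in self.chromsizes:
                    raise ValueError(
                        f"interval {iv.name}: chromosome {iv.chrom!r} absent from chrom sizes"
                    )
                if iv.end > self.chromsizes[iv.chrom]:
                    raise ValueError(
                        f"interval {iv.name}: end {iv.end} exceeds length of {iv.chrom}"
                    )
        dup = [n for n, c in Counter(iv.name for iv in self.intervals).items() if c > 1]
        if dup:
            logger.warning("peak set %r has duplicate names: %s", self.label, dup[:5])

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, idx: int) -> GenomicInterval:
        return self.intervals[idx]

    @property
    def names(self) -> list[str]:
        return [iv.name for iv in self.intervals]

    def sorted(self) -> "PeakSet":
        """Canonical (chrom, start, end, name) order."""
        ivs = sorted(self.intervals, key=GenomicInterval.sort_key)
        return PeakSet(self.label, ivs, self.chromsizes)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = defaultdict(list)
        for iv in self.intervals:
            out[iv.chrom].append(iv)
        return dict(out)

    def subset(self, names: Iterable[str], label: str | None = None) -> "PeakSet":
        wanted = set(names)
        ivs = [iv for iv in self.intervals if iv.name in wanted]
        return PeakSet(label or self.label, ivs, self.chromsizes)


@dataclass
class OverlapResult:
    """Shared/unique partition of two peak sets under a >= min_overlap criterion.

    A peak of A is *shared* iff it overlaps at least one peak of B by at
    least ``min_overlap`` bp (and vice versa); ``pairs`` enumerates every
    qualifying (A-name, B-name, overlap-bp) combination.
    """

    shared_a: PeakSet
    unique_a: PeakSet
    shared_b: PeakSet
    unique_b: PeakSet
    pairs: list[tuple[str, str, int]]
    min_overlap: int = 1

    def __post_init__(self) -> None:
        for p in self.pairs:
            if p[2] < self.min_overlap:
                raise ValueError(f"pair {p} below min_overlap={self.min_overlap}")

    @property
    def n_shared_a(self) -> int:
        return len(self.shared_a)

    @property
    def n_unique_a(self) -> int:
        return len(self.unique_a)


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def _format_number(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return format(x, "g")


def _parse_line(fields: list[str], dialect: str, lineno: int, path) -> GenomicInterval:
    try:
        chrom = fields[0]
        start = int(fields[1])
        end = int(fields[2])
    except (ValueError, IndexError) as exc:
        raise BedFormatError(f"{path}:{lineno}: malformed coordinates: {exc}") from None
    if start < 0:
        raise BedFormatError(f"{path}:{lineno}: negative start {start}")
    if start >= end:
        raise BedFormatError(f"{path}:{lineno}: start {start} >= end {end}")

    name = "."
    score: float | None = None
    strand = "."
    meta: dict[str, object] = {}
    if dialect in ("bed6", "narrowpeak"):
        name = fields[3]
        score = float(fields[4])
        strand = fields[5]
    if dialect == "narrowpeak":
        meta = {
            "signalValue": float(fields[6]),
            "pValue": float(fields[7]),
            "qValue": float(fields[8]),
            "summit": int(fields[9]),
        }
    if name == ".":
        name = f"peak_{lineno}"
    return GenomicInterval(chrom, start, end, name, score, strand, tuple(meta.items()))


def read_bed(
    path: str | Path,
    dialect: str = "bed6",
    chromsizes: ChromSizes | None = None,
    label: str | None = None,
) -> PeakSet:
    """Parse a BED3/BED6/narrowPeak file into a PeakSet, in file order.

    Unnamed records receive generated names ``peak_<line#>``.  With
    ``chromsizes`` given, unknown chromosomes are an error; without, any
    chromosome name is accepted.
    """
    dialect = dialect.lower()
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}; use bed3, bed6 or narrowpeak")
    ncol = _DIALECT_COLUMNS[dialect]
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < ncol:
                raise BedFormatError(
                    f"{path}:{lineno}: expected >= {ncol} columns for {dialect}, got {len(fields)}"
                )
            iv = _parse_line(fields, dialect, lineno, path)
            if chromsizes is not None and iv.chrom not in chromsizes:
                raise BedFormatError(
                    f"{path}:{lineno}: chromosome {iv.chrom!r} absent from chrom sizes"
                )
            intervals.append(iv)
    return PeakSet(label or path.stem, intervals, chromsizes)


def write_bed(peaks: PeakSet, path: str | Path, dialect: str = "bed6") -> Path:
    """Write a PeakSet in canonical sort order; inverse of :func:`read_bed`.

    Output is tab-separated with no trailing whitespace, so writing,
    re-reading and writing again is byte-stable.
    """
    dialect = dialect.lower()
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with open(path, "w") as fh:
        for iv in peaks.sorted():
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if dialect in ("bed6", "narrowpeak"):
                score = iv.score if iv.score is not None else 0
                cols += [iv.name, _format_number(score), iv.strand]
            if dialect == "narrowpeak":
                m = iv.meta
                cols += [
                    _format_number(float(m.get("signalValue", 0))),
                    _format_number(float(m.get("pValue", -1))),
                    _format_number(float(m.get("qValue", -1))),
                    str(int(m.get("summit", -1))),
                ]
            fh.write("\t".join(cols) + "\n")
    return path


# ---------------------------------------------------------------------------
# Set operations
# ---------------------------------------------------------------------------

def _build_trees(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, ivs in peaks.by_chrom().items():
        trees[chrom] = IntervalTree.from_tuples((iv.start, iv.end, iv) for iv in ivs)
    return trees


def intersect(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> OverlapResult:
    """Partition A and B into shared/unique by >= ``min_overlap`` bp intersection.

    A peak overlapping several partners is counted once in the shared set;
    the pair list still records every qualifying partner.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees_b = _build_trees(b)
    pairs: list[tuple[str, str, int]] = []
    shared_a_names: set[str] = set()
    shared_b_names: set[str] = set()
    for iv in a:
        tree = trees_b.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            partner: GenomicInterval = hit.data
            ovl = min(iv.end, partner.end) - max(iv.start, partner.start)
            if ovl >= min_overlap:
                pairs.append((iv.name, partner.name, ovl))
                shared_a_names.add(iv.name)
                shared_b_names.add(partner.name)
    pairs.sort()
    shared_a = [iv for iv in a if iv.name in shared_a_names]
    unique_a = [iv for iv in a if iv.name not in shared_a_names]
    shared_b = [iv for iv in b if iv.name in shared_b_names]
    unique_b = [iv for iv in b if iv.name not in shared_b_names]
    mk = lambda label, ivs, src: PeakSet(label, sorted(ivs, key=GenomicInterval.sort_key), src.chromsizes)
    return OverlapResult(
        shared_a=mk(f"{a.label}_shared", shared_a, a),
        unique_a=mk(f"{a.label}_unique", unique_a, a),
        shared_b=mk(f"{b.label}_shared", shared_b, b),
        unique_b=mk(f"{b.label}_unique", unique_b, b),
        pairs=pairs,
        min_overlap=min_overlap,
    )


def count_shared(a: PeakSet, b: PeakSet, min_overlap: int = 1, statistic: str = "shared") -> int:
    """Fast overlap statistic used inside the permutation loop.

    ``shared`` counts A peaks with >= 1 qualifying partner; ``pairs`` counts
    every qualifying (A, B) pair.  Equivalent to the corresponding fields of
    :func:`intersect` but avoids building the full partition.
    """
    by_chrom_b = b.by_chrom()
    total = 0
    for chrom, ivs_a in a.by_chrom().items():
        ivs_b = by_chrom_b.get(chrom)
        if not ivs_b:
            continue
        starts = np.array([iv.start for iv in ivs_b])
        ends = np.array([iv.end for iv in ivs_b])
        order = np.argsort(starts, kind="stable")
        starts = starts[order]
        ends = ends[order]
        # prefix max of ends over B sorted by start: a qualifying partner for
        # A=[s,e) is any B with start <= e - m and end >= s + m
        prefix_max_end = np.maximum.accumulate(ends)
        for iv in ivs_a:
            hi = int(np.searchsorted(starts, iv.end - min_overlap, side="right"))
            if hi == 0:
                continue
            if statistic == "shared":
                if prefix_max_end[hi - 1] >= iv.start + min_overlap:
                    total += 1
            else:
                ovls = np.minimum(ends[:hi], iv.end) - np.maximum(starts[:hi], iv.start)
                total += int(np.count_nonzero(ovls >= min_overlap))
    return total


def subtelomere_regions(chromsizes: ChromSizes, margin: int = 500_000) -> PeakSet:
    """Terminal ``margin`` bp at each chromosome end (default 500 kb).

    When twice the margin reaches the chromosome length, the two terminal
    windows merge into a single whole-chromosome interval.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    intervals: list[GenomicInterval] = []
    if margin == 0:
        return PeakSet("subtelomeres", [], chromsizes)
    for chrom, length in chromsizes.items():
        if 2 * margin >= length:
            intervals.append(GenomicInterval(chrom, 0, length, f"{chrom}_subtel"))
        else:
            intervals.append(GenomicInterval(chrom, 0, margin, f"{chrom}_subtel_p"))
            intervals.append(
                GenomicInterval(chrom, length - margin, length, f"{chrom}_subtel_q")
            )
    return PeakSet("subtelomeres", intervals, chromsizes)


def exclude_regions(peaks: PeakSet, masks: Sequence[PeakSet]) -> PeakSet:
    """Drop every peak overlapping any mask region by >= 1 bp (whole-peak
    removal, no trimming); output in canonical order."""
    mask_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for mask in masks:
        for iv in mask:
            mask_trees[iv.chrom].addi(iv.start, iv.end)
    kept = [
        iv
        for iv in peaks
        if not (iv.chrom in mask_trees and mask_trees[iv.chrom].overlap(iv.start, iv.end))
    ]
    return PeakSet(peaks.label, sorted(kept, key=GenomicInterval.sort_key), peaks.chromsizes)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def per_chromosome_counts(result: OverlapResult) -> pd.DataFrame:
    """Per-chromosome shared/unique peak counts for both sets (wide table)."""
    rows: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for col, ps in [
        ("shared_a", result.shared_a),
        ("unique_a", result.unique_a),
        ("shared_b", result.shared_b),
        ("unique_b", result.unique_b),
    ]:
        for iv in ps:
            rows[iv.chrom][col] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    for col in ("shared_a", "unique_a", "shared_b", "unique_b"):
        if col not in df.columns:
            df[col] = 0
    df = df[["shared_a", "unique_a", "shared_b", "unique_b"]]
    df.index.name = "chrom"
    return df.sort_index()


def length_summary(result: OverlapResult) -> pd.DataFrame:
    """Length distribution (mean/median/quartiles) of shared peaks, per
    chromosome and source set; rows only for chromosomes with shared peaks."""
    records = []
    for source, ps in [("a", result.shared_a), ("b", result.shared_b)]:
        for chrom, ivs in ps.by_chrom().items():
            lengths = np.array([iv.length for iv in ivs], dtype=float)
            records.append(
                {
                    "chrom": chrom,
                    "source": source,
                    "n": len(lengths),
                    "mean": float(np.mean(lengths)),
                    "median": float(np.median(lengths)),
                    "q25": float(np.percentile(lengths, 25)),
                    "q75": float(np.percentile(lengths, 75)),
                }
            )
    df = pd.DataFrame.from_records(
        records, columns=["chrom", "source", "n", "mean", "median", "q25", "q75"]
    )
    return df.sort_values(["chrom", "source"]).reset_index(drop=True)
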