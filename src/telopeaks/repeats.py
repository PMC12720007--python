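"""Telomeric hexamer scanning, tandem-run detection and peak classification.

The telomeric unit is the exact hexamer TTAGGG (or its reverse complement
CCCTAA, the motif seen when the array lies on the opposite strand).  A
*tandem run* is a maximal series of occurrences of the same motif at exactly
unit-length spacing; one intervening base breaks a run, and runs never mix
the two motifs, since a biological telomeric array is strand-uniform.

Peaks are classified by repeat content into five types:

    I    no telomeric repeat
    II   a single repeat
    III  multiple but scattered repeats (no run reaching the tandem minimum)
    IV   exactly one run of >= min_tandem_units consecutive units
    V    two or more such runs

The default tandem minimum is 4 units, the threshold taken as necessary for
stable R-loop formation in cells (in vitro data put the floor at 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyfaidx import Fasta

PEAK_TYPES = ("I", "II", "III", "IV", "V")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    """The repeat unit scanned on both orientations."""

    forward: str = "TTAGGG"
    reverse: str = "CCCTAA"

    def __post_init__(self) -> None:
        if reverse_complement(self.forward).upper() != self.reverse.upper():
            raise ValueError("reverse must be the reverse complement of forward")

    @property
    def unit_length(self) -> int:
        return len(self.forward)


TELOMERIC = MotifSpec()


@dataclass(frozen=True)
class TandemFilter:
    """Minimum number of consecutive units for a run to count as tandem."""

    min_tandem_units: int = 4

    def __post_init__(self) -> None:
        if self.min_tandem_units < 1:
            raise ValueError("min_tandem_units must be >= 1")


@dataclass
class RepeatProfile:
    """Per-peak repeat content: occurrence counts, tandem runs, and type."""

    peak_name: str
    count_forward: int
    count_reverse: int
    run_lengths: list[int] = field(default_factory=list)
    peak_type: str | None = None
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    @property
    def total(self) -> int:
        return self.count_forward + self.count_reverse

    @property
    def longest_tandem(self) -> int:
        return max(self.run_lengths) if self.run_lengths else 0

    def n_runs_ge(self, min_units: int) -> int:
        return sum(1 for r in self.run_lengths if r >= min_units)

    def check(self) -> None:
        if any(r < 1 for r in self.run_lengths):
            raise ValueError(f"{self.peak_name}: run lengths must be positive")
        if sum(self.run_lengths) != self.total:
            raise ValueError(
                f"{self.peak_name}: run lengths sum to {sum(self.run_lengths)} "
                f"but total occurrences are {self.total}"
            )


def scan_motif(seq: str, motif: str, respect_softmask: bool = False) -> list[int]:
    """All start offsets where ``motif`` matches ``seq`` exactly.

    Matching is case-insensitive unless ``respect_softmask`` is set, in which
    case soft-masked (lowercase) sequence never matches.  ``N`` never matches.
    Overlapping occurrences are reported (irrelevant for TTAGGG, which has no
    nontrivial self-overlap).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if not respect_softmask:
        seq = seq.upper()
    motif = motif.upper()
    hits: list[int] = []
    pos = seq.find(motif)
    while pos != -1:
        hits.append(pos)
        pos = seq.find(motif, pos + 1)
    return hits


def count_repeats(seq: str, motifs: MotifSpec = TELOMERIC, **kw) -> tuple[int, int]:
    """(forward, reverse) occurrence counts; the peak total is their sum."""
    return (
        len(scan_motif(seq, motifs.forward, **kw)),
        len(scan_motif(seq, motifs.reverse, **kw)),
    )


def tandem_runs(
    seq: str, motifs: MotifSpec = TELOMERIC, **kw
) -> list[tuple[str, int, int]]:
    """Maximal zero-gap runs of each motif as (motif, start, units) tuples.

    Every occurrence belongs to exactly one run (possibly of length 1); a
    strand change or any intervening base terminates a run.
    """
    unit = motifs.unit_length
    runs: list[tuple[str, int, int]] = []
    for motif in (motifs.forward, motifs.reverse):
        offsets = scan_motif(seq, motif, **kw)
        i = 0
        while i < len(offsets):
            j = i
            while j + 1 < len(offsets) and offsets[j + 1] == offsets[j] + unit:
                j += 1
            runs.append((motif.upper(), offsets[i], j - i + 1))
            i = j + 1
    runs.sort(key=lambda r: r[1])
    return runs


def classify_peak(profile: RepeatProfile, filt: TandemFilter = TandemFilter()) -> str:
    """Assign one of the five repeat-content types; exhaustive and exclusive."""
    profile.check()
    total = profile.total
    if total == 0:
        return "I"
    if total == 1:
        return "II"
    n_tandem = profile.n_runs_ge(filt.min_tandem_units)
    if n_tandem == 0:
        return "III"
    if n_tandem == 1:
        return "IV"
    return "V"


def profile_sequence(
    name: str,
    seq: str,
    filt: TandemFilter = TandemFilter(),
    motifs: MotifSpec = TELOMERIC,
    **kw,
) -> RepeatProfile:
    cf, cr = count_repeats(seq, motifs, **kw)
    runs = [units for _, _, units in tandem_runs(seq, motifs, **kw)]
    prof = RepeatProfile(name, cf, cr, runs)
    prof.peak_type = classify_peak(prof, filt)
    return prof


def profile_peaks(
    peaks,
    genome: str | Path | Fasta,
    filt: TandemFilter = TandemFilter(),
    motifs: MotifSpec = TELOMERIC,
    respect_softmask: bool = False,
) -> list[RepeatProfile]:
    """Profile every peak against the reference sequence.

    The peak sequence is taken as ``[start, end)`` on the plus strand; both
    motif orientations are scanned, so the peak's own strand is irrelevant.
    """
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    profiles: list[RepeatProfile] = []
    for iv in peaks:
        if iv.chrom not in fasta:
            raise KeyError(f"chromosome {iv.chrom!r} missing from FASTA")
        chrom_len = len(fasta[iv.chrom])
        if iv.end > chrom_len:
            raise ValueError(
                f"peak {iv.name} ([{iv.start}, {iv.end})) out of bounds for "
                f"{iv.chrom} (length {chrom_len})"
            )
        seq = str(fasta[iv.chrom][iv.start : iv.end])
        prof = profile_sequence(
            iv.name, seq, filt, motifs, respect_softmask=respect_softmask
        )
        prof.chrom, prof.start, prof.end = iv.chrom, iv.start, iv.end
        profiles.append(prof)
    return profiles


def filter_min_tandem(
    profiles: Iterable[RepeatProfile], filt: TandemFilter = TandemFilter()
) -> tuple[list[RepeatProfile], list[RepeatProfile]]:
    """Split profiles into (passing, failing) by longest run >= the tandem
    minimum — equivalently, types {IV, V} vs {I, II, III}."""
    passing, failing = [], []
    for p in profiles:
        (passing if p.longest_tandem >= filt.min_tandem_units else failing).append(p)
    return passing, failing


def profiles_to_frame(
    profiles: Sequence[RepeatProfile], filt: TandemFilter = TandemFilter()
) -> pd.DataFrame:
    """Tabular view of profiles (one row per peak) for TSV export."""
    return pd.DataFrame(
        {
            "peak_name": [p.peak_name for p in profiles],
            "chrom": [p.chrom for p in profiles],
            "start": [p.start for p in profiles],
            "end": [p.end for p in profiles],
            "count_fwd": [p.count_forward for p in profiles],
            "count_rev": [p.count_reverse for p in profiles],
            "total": [p.total for p in profiles],
            "longest_tandem": [p.longest_tandem for p in profiles],
            "n_runs_ge_min": [p.n_runs_ge(filt.min_tandem_units) for p in profiles],
            "peak_type": [p.peak_type for p in profiles],
        }
    )
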