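"""Genomic annotation of peaks relative to gene models.

Each peak is assigned to exactly one category by the position of its
midpoint, with precedence promoter_tss > tts > exon > intron > intergenic.
Promoter and transcription-termination windows are explicit configuration
(defaults 1000 bp upstream / 100 bp downstream of the TSS, and the mirror
image around the TTS).  The nearest gene is the one whose TSS minimizes the
midpoint distance on the same chromosome, ties broken lexicographically.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

CATEGORIES = ("promoter_tss", "exon", "intron", "tts", "intergenic")


@dataclass(frozen=True)
class GeneModel:
    """One gene: transcript span, strand and exon blocks (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_blocks: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start must be < tx_end")
        if not self.exon_blocks:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        prev_end = None
        for s, e in self.exon_blocks:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside transcript")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exon blocks overlap or unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start: tx_start on +, tx_end on -."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tts(self) -> int:
        """Transcription termination: tx_end on +, tx_start on -."""
        return self.tx_end if self.strand == "+" else self.tx_start


@dataclass(frozen=True)
class AnnotationRecord:
    peak_name: str
    category: str
    nearest_gene: str = ""
    tss_distance: float | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"invalid category {self.category!r}")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse gene models from BED12; exons reconstructed from block fields."""
    genes: list[GeneModel] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns, got {len(f)}")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(
                    f"{path}:{lineno}: blockCount={n_blocks} inconsistent with "
                    f"{len(sizes)} sizes / {len(starts)} starts"
                )
            blocks = tuple(
                (start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)
            )
            try:
                genes.append(GeneModel(name, chrom, strand, start, end, blocks))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> Path:
    """Write gene models as BED12 (inverse of :func:`read_gene_models`)."""
    path = Path(path)
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start, g.gene_id)):
            sizes = ",".join(str(e - s) for s, e in g.exon_blocks)
            starts = ",".join(str(s - g.tx_start) for s, _ in g.exon_blocks)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.tx_start),
                        str(g.tx_end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.tx_start),
                        str(g.tx_end),
                        "0",
                        str(len(g.exon_blocks)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )
    return path


def _promoter_window(g: GeneModel, upstream: int, downstream: int) -> tuple[int, int]:
    if g.strand == "+":
        return (g.tss - upstream, g.tss + downstream)
    return (g.tss - downstream, g.tss + upstream)


def _tts_window(g: GeneModel, upstream: int, downstream: int) -> tuple[int, int]:
    if g.strand == "+":
        return (g.tts - upstream, g.tts + downstream)
    return (g.tts - downstream, g.tts + upstream)


def annotate_peak(
    peak,
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = (1000, 100),
    tts_window: tuple[int, int] = (100, 1000),
) -> AnnotationRecord:
    """Categorize one peak by its midpoint and attach the nearest TSS.

    Windows are (upstream, downstream) in the gene's transcription
    direction.  The nearest-TSS search is chromosome-local; peaks on
    gene-free chromosomes get an empty ``nearest_gene``.
    """
    mid = peak.midpoint
    local = [g for g in genes if g.chrom == peak.chrom]

    category = "intergenic"
    if any(w[0] <= mid < w[1] for g in local for w in [_promoter_window(g, *promoter_window)]):
        category = "promoter_tss"
    elif any(w[0] <= mid < w[1] for g in local for w in [_tts_window(g, *tts_window)]):
        category = "tts"
    else:
        inside = [g for g in local if g.tx_start <= mid < g.tx_end]
        if inside:
            in_exon = any(
                s <= mid < e for g in inside for s, e in g.exon_blocks
            )
            category = "exon" if in_exon else "intron"

    nearest_gene = ""
    tss_distance: float | None = None
    if local:
        best = min(local, key=lambda g: (abs(mid - g.tss), g.gene_id))
        nearest_gene = best.gene_id
        # strand-oriented sign: positive = downstream of the TSS
        tss_distance = float(mid - best.tss if best.strand == "+" else best.tss - mid)
    return AnnotationRecord(peak.name, category, nearest_gene, tss_distance)


def annotate_peaks(
    peaks,
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = (1000, 100),
    tts_window: tuple[int, int] = (100, 1000),
) -> list[AnnotationRecord]:
    return [annotate_peak(p, genes, promoter_window, tts_window) for p in peaks]


def annotation_breakdown(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    """Category counts and percentages (percentages sum to 100)."""
    if not records:
        raise ValueError("no annotation records")
    counts = Counter(r.category for r in records)
    rows = [
        {
            "category": cat,
            "count": counts.get(cat, 0),
            "percentage": 100.0 * counts.get(cat, 0) / len(records),
        }
        for cat in CATEGORIES
    ]
    return pd.DataFrame(rows)


def gene_list_overlap(
    records: Sequence[AnnotationRecord],
    de_genes: Iterable[str],
    max_tss_distance: float | None = None,
) -> tuple[set[str], dict[str, int]]:
    """Intersect peak-associated genes with an external gene list.

    Peak-associated genes are the distinct nearest-gene values, optionally
    restricted to peaks within ``max_tss_distance`` of the TSS.  Returns the
    intersection and the three Venn counts.
    """
    associated = {
        r.nearest_gene
        for r in records
        if r.nearest_gene
        and (
            max_tss_distance is None
            or (r.tss_distance is not None and abs(r.tss_distance) <= max_tss_distance)
        )
    }
    de = set(de_genes)
    inter = associated & de
    counts = {
        "associated_only": len(associated - de),
        "de_only": len(de - associated),
        "both": len(inter),
    }
    return inter, counts


def read_gene_list(path: str | Path) -> set[str]:
    """One gene identifier per line; blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
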