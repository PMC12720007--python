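"""Interval model, BED I/O, intersection partitioning and exclusion filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from telopeaks.intervals import (
    BedFormatError,
    ChromSizes,
    GenomicInterval,
    PeakSet,
    count_shared,
    exclude_regions,
    intersect,
    length_summary,
    per_chromosome_counts,
    read_bed,
    read_chrom_sizes,
    subtelomere_regions,
    write_bed,
)
from conftest import random_peak_set


def brute_force_partition(a, b, min_overlap=1):
    """All-pairs oracle for the shared/unique partition."""
    pairs = []
    for x in a:
        for y in b:
            ovl = x.overlap_length(y)
            if ovl >= min_overlap:
                pairs.append((x.name, y.name, ovl))
    shared_a = {p[0] for p in pairs}
    shared_b = {p[1] for p in pairs}
    return shared_a, shared_b, sorted(pairs)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

def test_interval_invariants():
    iv = GenomicInterval("chr1", 10, 20, "p")
    assert iv.length == 10
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 20, 20, "empty")
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 5, "neg")
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 0, 5, "badstrand", strand="x")


def test_chromsizes_validation_and_io(tmp_path):
    with pytest.raises(ValueError):
        ChromSizes({"chr1": 0})
    sizes = ChromSizes({"chr2": 50, "chr1": 100})
    assert list(sizes) == ["chr2", "chr1"]  # insertion order is stable
    path = sizes.to_file(tmp_path / "g.sizes")
    assert read_chrom_sizes(path).entries == sizes.entries


def test_peakset_rejects_out_of_bounds():
    sizes = ChromSizes({"chr1": 100})
    with pytest.raises(ValueError, match="absent"):
        PeakSet("x", [GenomicInterval("chrX", 0, 10, "p")], sizes)
    with pytest.raises(ValueError, match="exceeds"):
        PeakSet("x", [GenomicInterval("chr1", 90, 110, "p")], sizes)


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def test_read_bed3_basic(tmp_path):
    path = tmp_path / "x.bed"
    path.write_text("chr1\t0\t100\nchr1\t50\t60\nchr2\t10\t20\n")
    ps = read_bed(path, "bed3")
    assert [iv.length for iv in ps] == [100, 10, 10]
    assert ps.names == ["peak_1", "peak_2", "peak_3"]


def test_read_bed_empty_file(tmp_path):
    path = tmp_path / "empty.bed"
    path.write_text("")
    assert len(read_bed(path, "bed3")) == 0


@pytest.mark.parametrize(
    "content,err",
    [
        ("chr1\t50\t40\n", "start 50 >= end 40"),
        ("chr1\tfoo\t40\n", "malformed"),
        ("chr1\t10\n", "expected"),
    ],
)
def test_read_bed_errors_name_line(tmp_path, content, err):
    path = tmp_path / "bad.bed"
    path.write_text(content)
    with pytest.raises(BedFormatError, match=err):
        read_bed(path, "bed3")
    with pytest.raises(BedFormatError, match=":1:"):
        read_bed(path, "bed3")


def test_read_bed_unknown_chrom_with_sizes(tmp_path):
    path = tmp_path / "x.bed"
    path.write_text("chrZ\t0\t10\n")
    assert len(read_bed(path, "bed3")) == 1  # accepted without sizes
    with pytest.raises(BedFormatError, match="chrZ"):
        read_bed(path, "bed3", ChromSizes({"chr1": 100}))


def test_write_bed_fixed_formatting(tmp_path):
    ps = PeakSet("x", [GenomicInterval("chr1", 5, 15, "p1", 0.0)])
    path = write_bed(ps, tmp_path / "o.bed")
    assert path.read_text() == "chr1\t5\t15\tp1\t0\t.\n"


def test_write_bed_empty(tmp_path):
    path = write_bed(PeakSet("x", []), tmp_path / "o.bed", "bed3")
    assert path.read_text() == ""


def test_narrowpeak_roundtrip_bytestable(tmp_path):
    """write -> read -> write is byte-identical on a generated 50-row file."""
    rng = np.random.default_rng(7)
    ivs = []
    for i in range(50):
        s = int(rng.integers(0, 10_000))
        ln = int(rng.integers(1, 500))
        ivs.append(
            GenomicInterval(
                f"chr{rng.integers(1, 4)}",
                s,
                s + ln,
                f"np_{i}",
                float(np.round(rng.uniform(0, 1000), 2)),
                "+-."[int(rng.integers(3))],
                {
                    "signalValue": float(np.round(rng.uniform(0, 50), 3)),
                    "pValue": float(np.round(rng.uniform(0, 300), 4)),
                    "qValue": float(np.round(rng.uniform(0, 300), 4)),
                    "summit": int(rng.integers(0, ln)),
                },
            )
        )
    ps = PeakSet("np", ivs)
    p1 = write_bed(ps, tmp_path / "a.narrowPeak", "narrowpeak")
    reread = read_bed(p1, "narrowpeak")
    assert all(len(iv.meta) == 4 for iv in reread)
    p2 = write_bed(reread, tmp_path / "b.narrowPeak", "narrowpeak")
    assert p1.read_bytes() == p2.read_bytes()


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_bed6_roundtrip_property(tmp_path_factory, seed):
    """Re-parsing a written set equals the canonical sort of the input."""
    rng = np.random.default_rng(seed)
    sizes = ChromSizes({"chr1": 10_000, "chr2": 5_000})
    ps = random_peak_set("p", int(rng.integers(0, 30)), sizes, rng, (1, 400))
    path = tmp_path_factory.mktemp("rt") / "x.bed"
    write_bed(ps, path)
    reread = read_bed(path, "bed6")
    expect = [(i.chrom, i.start, i.end, i.name) for i in ps.sorted()]
    got = [(i.chrom, i.start, i.end, i.name) for i in reread]
    assert got == expect


# ---------------------------------------------------------------------------
# intersect
# ---------------------------------------------------------------------------

def test_intersect_boundary_one_bp():
    a = PeakSet("A", [GenomicInterval("chr1", 0, 100, "a1")])
    b = PeakSet("B", [GenomicInterval("chr1", 99, 200, "b1")])
    res = intersect(a, b)
    assert len(res.shared_a) == 1 and res.pairs == [("a1", "b1", 1)]
    # half-open adjacency does not overlap
    b2 = PeakSet("B", [GenomicInterval("chr1", 100, 200, "b1")])
    res2 = intersect(a, b2)
    assert len(res2.shared_a) == 0 and len(res2.unique_a) == 1


def test_intersect_different_chromosomes():
    a = PeakSet("A", [GenomicInterval("chr1", 0, 100, "a1")])
    b = PeakSet("B", [GenomicInterval("chr2", 0, 100, "b1")])
    res = intersect(a, b)
    assert len(res.shared_a) == 0 and len(res.unique_a) == 1


def test_intersect_matches_brute_force(small_sizes):
    rng = np.random.default_rng(1234)
    a = random_peak_set("A", 200, small_sizes, rng)
    b = random_peak_set("B", 200, small_sizes, rng)
    res = intersect(a, b)
    sh_a, sh_b, pairs = brute_force_partition(a, b)
    assert set(res.shared_a.names) == sh_a
    assert set(res.shared_b.names) == sh_b
    assert res.pairs == pairs


@pytest.mark.parametrize("seed", range(10))
def test_partition_conservation_and_symmetry(small_sizes, seed):
    rng = np.random.default_rng(seed)
    a = random_peak_set("A", int(rng.integers(0, 80)), small_sizes, rng)
    b = random_peak_set("B", int(rng.integers(1, 80)), small_sizes, rng)
    res = intersect(a, b)
    assert len(res.shared_a) + len(res.unique_a) == len(a)
    assert len(res.shared_b) + len(res.unique_b) == len(b)
    swapped = intersect(b, a)
    assert sorted((y, x, o) for x, y, o in res.pairs) == sorted(swapped.pairs)
    # no unique peak appears in any pair, every shared one does
    in_pairs = {p[0] for p in res.pairs}
    assert in_pairs == set(res.shared_a.names)
    assert not in_pairs & set(res.unique_a.names)


def test_min_overlap_monotonicity(small_sizes):
    rng = np.random.default_rng(9)
    a = random_peak_set("A", 100, small_sizes, rng)
    b = random_peak_set("B", 100, small_sizes, rng)
    counts = [len(intersect(a, b, m).shared_a) for m in (1, 10, 50, 200)]
    assert counts == sorted(counts, reverse=True)


def test_count_shared_agrees_with_intersect(small_sizes):
    rng = np.random.default_rng(77)
    a = random_peak_set("A", 150, small_sizes, rng)
    b = random_peak_set("B", 120, small_sizes, rng)
    for m in (1, 25):
        res = intersect(a, b, m)
        assert count_shared(a, b, m, "shared") == len(res.shared_a)
        assert count_shared(a, b, m, "pairs") == len(res.pairs)


# ---------------------------------------------------------------------------
# subtelomeres & exclusion
# ---------------------------------------------------------------------------

def test_subtelomere_windows():
    sizes = ChromSizes({"chrA": 10_000_000, "chrB": 800_000})
    regs = subtelomere_regions(sizes, 500_000)
    spans = {(iv.chrom, iv.start, iv.end) for iv in regs}
    assert ("chrA", 0, 500_000) in spans
    assert ("chrA", 9_500_000, 10_000_000) in spans
    assert ("chrB", 0, 800_000) in spans  # margins merge into one interval
    assert len(subtelomere_regions(sizes, 0)) == 0


def test_exclude_whole_peak_removal():
    peaks = PeakSet("p", [GenomicInterval("chr1", 100, 200, "p1")])
    removed = exclude_regions(peaks, [PeakSet("m", [GenomicInterval("chr1", 150, 160, "m1")])])
    assert len(removed) == 0
    kept = exclude_regions(peaks, [PeakSet("m", [GenomicInterval("chr1", 200, 300, "m1")])])
    assert kept.names == ["p1"]


def test_exclude_matches_brute_force_and_idempotent(small_sizes):
    rng = np.random.default_rng(5)
    peaks = random_peak_set("p", 500, small_sizes, rng)
    masks = [random_peak_set("m", 10, small_sizes, rng, (100, 2000)) for _ in range(2)]
    kept = exclude_regions(peaks, masks)
    expect = {
        iv.name
        for iv in peaks
        if all(iv.overlap_length(m) == 0 for mask in masks for m in mask)
    }
    assert set(kept.names) == expect
    again = exclude_regions(kept, masks)
    assert again.names == kept.names


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def test_per_chromosome_counts_sum_to_totals(small_sizes):
    rng = np.random.default_rng(3)
    a = random_peak_set("A", 120, small_sizes, rng)
    b = random_peak_set("B", 90, small_sizes, rng)
    res = intersect(a, b)
    table = per_chromosome_counts(res)
    assert table["shared_a"].sum() + table["unique_a"].sum() == len(a)
    assert table["shared_b"].sum() + table["unique_b"].sum() == len(b)


def test_per_chromosome_counts_empty():
    res = intersect(PeakSet("A", [GenomicInterval("chr9", 0, 10, "a")]),
                    PeakSet("B", [GenomicInterval("chr9", 50, 60, "b")]))
    table = per_chromosome_counts(res)
    assert table.loc["chr9", "unique_a"] == 1 and table.loc["chr9", "shared_a"] == 0


def test_length_summary_recompute(small_sizes):
    a = PeakSet("A", [GenomicInterval("chr1", 0, 150, "a1"),
                      GenomicInterval("chr1", 300, 500, "a2"),
                      GenomicInterval("chr2", 0, 300, "a3")])
    b = PeakSet("B", [GenomicInterval("chr1", 100, 160, "b1"),
                      GenomicInterval("chr1", 400, 450, "b2")])
    table = length_summary(intersect(a, b))
    row = table[(table.chrom == "chr1") & (table.source == "a")].iloc[0]
    assert row["mean"] == np.mean([150, 200]) and row["median"] == np.median([150, 200])
    # chromosomes without shared peaks produce no rows
    assert "chr2" not in set(table.chrom)
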