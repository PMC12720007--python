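"""Shared fixtures: synthetic genomes/peak sets generated at session scope."""

import numpy as np
import pytest

from telopeaks.intervals import ChromSizes, GenomicInterval, PeakSet
from telopeaks.synthetic import SynthConfig, write_fixture


def random_peak_set(
    label: str,
    n: int,
    chromsizes: ChromSizes,
    rng: np.random.Generator,
    length_range: tuple[int, int] = (50, 500),
) -> PeakSet:
    """Uniformly placed peaks, chromosome chosen in proportion to length."""
    names = list(chromsizes)
    lengths = np.array([chromsizes[c] for c in names], dtype=float)
    p = lengths / lengths.sum()
    ivs = []
    for i in range(n):
        chrom = names[int(rng.choice(len(names), p=p))]
        ln = int(rng.integers(length_range[0], length_range[1] + 1))
        start = int(rng.integers(0, chromsizes[chrom] - ln + 1))
        ivs.append(GenomicInterval(chrom, start, start + ln, f"{label}_{i}"))
    return PeakSet(label, ivs, chromsizes)


@pytest.fixture(scope="session")
def small_sizes() -> ChromSizes:
    return ChromSizes({"chr1": 100_000, "chr2": 80_000, "chr3": 50_000})


@pytest.fixture(scope="session")
def exact_fixture(tmp_path_factory):
    """Default-scale fixture with exact bookkeeping (truth predicts counts)."""
    out = tmp_path_factory.mktemp("fixture_exact")
    config = SynthConfig(seed=11, exact_bookkeeping=True)
    return config, write_fixture(config, out / "fix")


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """Default fixture (chance collisions permitted and recorded)."""
    out = tmp_path_factory.mktemp("fixture_default")
    config = SynthConfig(seed=5)
    return config, write_fixture(config, out / "fix")
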