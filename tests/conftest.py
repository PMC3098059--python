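import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from peakannot import GenomicRegion, RegionSet


@pytest.fixture
def myexp() -> RegionSet:
    """Three experimental binding sites on chromosomes 1-3 (worked example)."""
    return RegionSet("myexp", [
        GenomicRegion("1", 967654, 967754, "Site1"),
        GenomicRegion("2", 2010897, 2010997, "Site2"),
        GenomicRegion("3", 2496704, 2496804, "Site3"),
    ])


@pytest.fixture
def literature() -> RegionSet:
    """Five stranded literature sites used as the annotation feature set."""
    return RegionSet("literature", [
        GenomicRegion("1", 967659, 967869, "t1", "+"),
        GenomicRegion("2", 2010898, 2011108, "t2", "+"),
        GenomicRegion("3", 2496700, 2496920, "t3", "-"),
        GenomicRegion("1", 3075866, 3076166, "t4", "-"),
        GenomicRegion("2", 3123260, 3123470, "t5", "+"),
    ])


def random_region_set(rng, label, n, max_coord=2000, max_width=120,
                      chroms=("chrA", "chrB"), stranded=False):
    """Small random RegionSet for oracle-equivalence sweeps."""
    regions = []
    for i in range(n):
        start = int(rng.integers(1, max_coord))
        width = int(rng.integers(1, max_width + 1))
        strand = ("+", "-")[int(rng.integers(0, 2))] if stranded else "*"
        regions.append(GenomicRegion(
            chroms[int(rng.integers(0, len(chroms)))],
            start, start + width - 1, f"{label}_{i}", strand,
        ))
    return RegionSet(label, regions)
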