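import numpy as np
import pandas as pd
import pytest

from madzyd.intervals import GenomicInterval, TSSRecord
from madzyd.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=7)


@pytest.fixture
def small_tss():
    return [
        TSSRecord("gA", "scaffold_1", 500_000, "+"),
        TSSRecord("gB", "scaffold_1", 520_000, "-"),
        TSSRecord("gC", "scaffold_2", 100_000, "+"),
    ]


def random_intervals(rng, n, scaffolds=("s1", "s2"), span=10_000, max_len=500):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(str(rng.choice(scaffolds)), start, start + length))
    return out


def brute_force_union(intervals):
    """Per-base boolean coverage union: the independent merge oracle."""
    by_scaffold = {}
    for iv in intervals:
        by_scaffold.setdefault(iv.scaffold, []).append(iv)
    merged = []
    for scaffold in sorted(by_scaffold):
        ivs = by_scaffold[scaffold]
        hi = max(iv.end for iv in ivs)
        covered = np.zeros(hi + 1, dtype=bool)
        for iv in ivs:
            covered[iv.start:iv.end] = True
        start = None
        for pos in range(hi + 1):
            if covered[pos] and start is None:
                start = pos
            elif not covered[pos] and start is not None:
                merged.append(GenomicInterval(scaffold, start, pos))
                start = None
    return merged


@pytest.fixture
def peaks_frame():
    return pd.DataFrame({
        "scaffold": ["s1", "s1", "s2"],
        "start": [100, 5000, 300],
        "end": [600, 5600, 900],
        "signal": [2.0, 3.0, 1.0],
    })
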