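import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from teprofile.catalog import GenomeLayout, RepeatCatalog


@pytest.fixture
def toy_genome():
    return GenomeLayout({"chr1": 10_000, "chr2": 8_000})


def make_catalog(rows, genome):
    """Catalog from (chrom, start, end, strand, name, family, class) tuples."""
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "repeat_name", "family", "class_name"]
    )
    df["copy_id"] = (
        df["chrom"] + ":" + df["start"].astype(str) + "-" + df["end"].astype(str)
        + ":" + df["repeat_name"]
    )
    return RepeatCatalog(df, genome)


@pytest.fixture
def toy_catalog(toy_genome):
    return make_catalog(
        [
            ("chr1", 100, 400, "+", "AluY", "Alu", "SINE"),
            ("chr1", 600, 700, "-", "AluY", "Alu", "SINE"),
            ("chr1", 1000, 2500, "+", "L1HS", "L1", "LINE"),
            ("chr1", 3000, 3300, "+", "SVA_F", "SVA", "Other"),
            ("chr2", 500, 900, "-", "L1ME", "L1", "LINE"),
            ("chr2", 2000, 2350, "+", "AluJb", "Alu", "SINE"),
        ],
        toy_genome,
    )


def random_intervals(rng, length, n, min_len=10, max_len=500):
    """n random (start, end) intervals within [0, length)."""
    out = []
    for _ in range(n):
        size = int(rng.integers(min_len, max_len + 1))
        size = min(size, length - 1)
        start = int(rng.integers(0, length - size))
        out.append((start, start + size))
    return out


def random_track(rng, genome, chrom, n_runs=20, lo=-2.0, hi=5.0):
    """Random piecewise-constant track on one chromosome."""
    from teprofile.coverage import CoverageTrack

    length = genome[chrom]
    cuts = np.sort(rng.choice(np.arange(1, length), size=min(n_runs, length - 1), replace=False))
    bounds = np.concatenate([[0], cuts, [length]]).astype(float)
    values = rng.uniform(lo, hi, size=len(bounds) - 1)
    return CoverageTrack.from_bounds(genome, {chrom: (bounds, values)})
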