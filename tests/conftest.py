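import numpy as np
import pandas as pd
import pytest

from chiprx.layout import GenomeLayout, Organism


@pytest.fixture
def layout() -> GenomeLayout:
    """Small combined mouse+fly layout used across unit tests."""
    return GenomeLayout(
        [
            Organism("mouse", "primary", "mm_", {"chr1": 100_000, "chr2": 50_000}),
            Organism("fly", "spikein", "dm_", {"chr2L": 20_000}),
        ]
    )


def frame(rows, columns=("chrom", "start", "end", "name", "score", "strand")):
    """Build an interval frame from (chrom, start, end, ...) tuples."""
    cols = list(columns[: len(rows[0])]) if rows else list(columns)
    return pd.DataFrame(rows, columns=cols)


def random_intervals(rng, n, chroms=("mm_chr1", "mm_chr2"), max_pos=90_000, max_len=500, prefix="iv"):
    starts = rng.integers(0, max_pos, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, size=n),
            "start": starts,
            "end": starts + lengths,
            "name": [f"{prefix}_{i}" for i in range(n)],
        }
    )


def brute_force_overlap_matrix(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """O(n*m) pairwise >=1 bp overlap oracle, independent of the package."""
    out = np.zeros((len(a), len(b)), dtype=bool)
    for i, (ca, sa, ea) in enumerate(zip(a["chrom"], a["start"], a["end"])):
        for j, (cb, sb, eb) in enumerate(zip(b["chrom"], b["start"], b["end"])):
            out[i, j] = ca == cb and sa < eb and sb < ea
    return out


def brute_force_any(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    return brute_force_overlap_matrix(a, b).any(axis=1)
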