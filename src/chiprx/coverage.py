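"""Genome-wide fragment coverage and the RPK10M density unit.

Coverage at base ``b`` is the number of fragments whose half-open interval
contains ``b``.  Densities are expressed as Reads Per Kilobase per 10
Million mapped fragments:

    rpk10m(count, width, total) = count / ((width / 1e3) * (total / 1e7))

which makes windows of different width and samples of different depth
directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import as_interval_frame
from .layout import GenomeLayout


@dataclass
class CoverageTrack:
    """Per-chromosome per-base fragment coverage.

    Attributes
    ----------
    data
        chromosome -> int32 array of per-base coverage.
    start_positions
        chromosome -> sorted array of fragment start coordinates (used by
        the window-based enrichment caller, where counts of independent
        fragment starts — not correlated per-base pileup — are the Poisson
        observable).
    total_mapped
        number of fragments the track was built from.
    """

    data: dict[str, np.ndarray]
    start_positions: dict[str, np.ndarray]
    total_mapped: int
    _cumsum: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def coverage_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base coverage over [start, end), clipped to the chromosome."""
        arr = self.data.get(chrom)
        if arr is None:
            return 0.0
        cs = self._cumsum.get(chrom)
        if cs is None:
            cs = np.concatenate(([0], np.cumsum(arr, dtype=np.int64)))
            self._cumsum[chrom] = cs
        lo = min(max(start, 0), len(arr))
        hi = min(max(end, 0), len(arr))
        if hi <= lo:
            return 0.0
        return float(cs[hi] - cs[lo])

    def window_start_counts(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Number of fragment starts falling in each [start, end) window."""
        pos = self.start_positions.get(chrom)
        if pos is None:
            return np.zeros(len(starts), dtype=np.int64)
        return np.searchsorted(pos, ends, side="left") - np.searchsorted(pos, starts, side="left")

    def scale(self, factor: float) -> "CoverageTrack":
        """Return a copy with per-base coverage multiplied by ``factor``."""
        return CoverageTrack(
            data={c: a * factor for c, a in self.data.items()},
            start_positions=self.start_positions,
            total_mapped=self.total_mapped,
        )


def compute_coverage(fragments: pd.DataFrame, layout: GenomeLayout) -> CoverageTrack:
    """Build a CoverageTrack over the primary organism's chromosomes.

    Fragments must be deduplicated primary-organism fragments; a fragment
    extending beyond its chromosome raises ``ValueError``.
    """
    chrom_lengths = layout.primary_chromosomes()
    data = {c: np.zeros(l, dtype=np.int32) for c, l in chrom_lengths.items()}
    start_positions: dict[str, np.ndarray] = {}
    if len(fragments):
        as_interval_frame(fragments)
    total = 0
    chrom_arr = fragments["chrom"].to_numpy() if len(fragments) else np.array([], dtype=object)
    for chrom in pd.unique(chrom_arr):
        if chrom not in data:
            raise KeyError(f"fragment chromosome {chrom!r} is not a primary-organism chromosome")
        sub = fragments.loc[chrom_arr == chrom]
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        L = chrom_lengths[chrom]
        if (ends > L).any() or (starts < 0).any():
            bad = sub.loc[(ends > L) | (starts < 0)].iloc[0]
            raise ValueError(
                f"fragment {chrom}:{bad['start']}-{bad['end']} outside chromosome bounds [0, {L})"
            )
        delta = np.zeros(L + 1, dtype=np.int32)
        np.add.at(delta, starts, 1)
        np.add.at(delta, ends, -1)
        data[chrom] = np.cumsum(delta[:-1], dtype=np.int32)
        start_positions[chrom] = np.sort(starts, kind="stable")
        total += len(sub)
    for chrom in chrom_lengths:
        start_positions.setdefault(chrom, np.array([], dtype=np.int64))
    return CoverageTrack(data=data, start_positions=start_positions, total_mapped=total)


def rpk10m(count: float, width_bp: float, total_mapped: float) -> float:
    """Reads Per Kilobase per 10 Million mapped fragments."""
    if width_bp <= 0:
        raise ValueError(f"width must be positive, got {width_bp}")
    if total_mapped <= 0:
        raise ValueError(f"total mapped fragment count must be positive, got {total_mapped}")
    return count / ((width_bp / 1e3) * (total_mapped / 1e7))


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Export coverage as a run-length-encoded bedGraph file."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            bounds = np.concatenate(([0], change, [len(arr)]))
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                val = int(arr[lo])
                if val != 0:
                    fh.write(f"{chrom}\t{lo}\t{hi}\t{val}\n")
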