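"""Half-open interval overlap primitives.

Every genomic interval in this package is 0-based half-open ``[start, end)``
and two intervals overlap iff they share at least one base.  The counting
trick used throughout: with per-chromosome fragment starts and ends each
sorted independently, the number of intervals overlapping a query
``[qs, qe)`` equals

    #{start < qe} - #{end <= qs}

because an interval fails to overlap the query exactly when it lies wholly
left (``end <= qs``) or wholly right (``start >= qe``), and the wholly-left
set is contained in ``{start < qe}``.  Both counts are binary searches, so
overlap counting over n intervals and m queries is O((n+m) log n) and exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def as_interval_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the minimal interval contract (chrom/start/end, start < end)."""
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"interval frame missing required column {col!r}")
    bad = df.index[df["start"].to_numpy() >= df["end"].to_numpy()]
    if len(bad):
        row = df.loc[bad[0]]
        raise ValueError(f"interval with start >= end: {row['chrom']}:{row['start']}-{row['end']}")
    if (df["start"].to_numpy() < 0).any():
        raise ValueError("negative interval coordinates")
    return df


class _ChromIndex:
    __slots__ = ("starts", "ends")

    def __init__(self, starts: np.ndarray, ends: np.ndarray):
        self.starts = np.sort(starts, kind="stable")
        self.ends = np.sort(ends, kind="stable")


class IntervalIndex:
    """Per-chromosome sorted-array index for overlap counting."""

    def __init__(self, df: pd.DataFrame):
        as_interval_frame(df)
        self._chroms: dict[str, _ChromIndex] = {}
        for chrom, sub in df.groupby("chrom", sort=False, observed=True):
            self._chroms[str(chrom)] = _ChromIndex(
                sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
            )

    def count_overlaps(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Number of indexed intervals overlapping each query by >= 1 bp."""
        idx = self._chroms.get(chrom)
        if idx is None:
            return np.zeros(len(starts), dtype=np.int64)
        n_left_of_end = np.searchsorted(idx.starts, ends, side="left")
        n_fully_left = np.searchsorted(idx.ends, starts, side="right")
        return n_left_of_end - n_fully_left


def count_overlaps(queries: pd.DataFrame, subjects: pd.DataFrame) -> np.ndarray:
    """Per query interval, the number of subject intervals overlapping it."""
    as_interval_frame(queries)
    index = IntervalIndex(subjects)
    out = np.zeros(len(queries), dtype=np.int64)
    chrom_arr = queries["chrom"].to_numpy()
    starts = queries["start"].to_numpy(np.int64)
    ends = queries["end"].to_numpy(np.int64)
    for chrom in pd.unique(chrom_arr):
        mask = chrom_arr == chrom
        out[mask] = index.count_overlaps(str(chrom), starts[mask], ends[mask])
    return out


def overlaps_any(queries: pd.DataFrame, subjects: pd.DataFrame) -> np.ndarray:
    """Boolean array: does each query overlap at least one subject interval?"""
    return count_overlaps(queries, subjects) > 0


def merge_intervals(starts: np.ndarray, ends: np.ndarray, gap: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted-by-start intervals whose gap is <= ``gap`` bp.

    Returns merged (starts, ends).  ``gap=0`` merges touching/overlapping
    intervals only.
    """
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = np.asarray(starts)[order], np.asarray(ends)[order]
    out_s = [starts[0]]
    out_e = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1] + gap:
            if e > out_e[-1]:
                out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)
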