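"""Dual-genome read partitioning and spike-in normalization factors.

After alignment to the combined primary+spike-in reference, properly paired
fragments are split by organism using the layout's chromosome-name prefixes.
The spike-in fragment count of each sample determines its normalization
factor

    alpha = C / n_spike        (C = 1e6 by default, i.e. reads-per-million
                                spike-in fragments)

so that the scaled signal of a genomic region is comparable across samples
that received the same proportion of exogenous chromatin: a global loss of
the immunoprecipitated mark inflates the spike-in share of a fixed
sequencing depth, which alpha corrects for.  Per-peak normalized signal is
``(# fragments overlapping the peak) * alpha``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import IntervalIndex, as_interval_frame
from .layout import GenomeLayout

log = logging.getLogger(__name__)

#: Default scale constant C in alpha = C / n_spike.
DEFAULT_SCALE_CONSTANT = 1e6

FRAGMENT_COLUMNS = ["chrom", "start", "end", "strand"]


@dataclass(frozen=True)
class SpikeInFactors:
    """Per-sample spike-in bookkeeping and the normalization factor."""

    sample_id: str
    n_primary: int
    n_spike: int
    scale_constant: float = DEFAULT_SCALE_CONSTANT

    @property
    def alpha(self) -> float:
        return compute_normalization_factor(self.n_spike, self.scale_constant)

    @property
    def spike_fraction(self) -> float:
        total = self.n_primary + self.n_spike
        return self.n_spike / total if total else float("nan")

    def to_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "n_primary": self.n_primary,
            "n_spike": self.n_spike,
            "alpha": self.alpha,
        }


def split_by_organism(fragments: pd.DataFrame, layout: GenomeLayout) -> dict[str, pd.DataFrame]:
    """Partition fragments into one bucket per organism.

    Every fragment is assigned to exactly one organism by resolving its
    chromosome name through the layout; input order is preserved within
    buckets.  An unresolvable chromosome raises ``KeyError`` naming it.
    """
    if len(fragments):
        as_interval_frame(fragments)
    chrom_arr = fragments["chrom"].to_numpy() if len(fragments) else np.array([], dtype=object)
    # resolve each distinct chromosome once
    org_of = {c: layout.organism_of(c) for c in pd.unique(chrom_arr)}
    assignment = np.array([org_of[c] for c in chrom_arr], dtype=object)
    out: dict[str, pd.DataFrame] = {}
    for org in layout.organisms:
        out[org.name] = fragments.loc[assignment == org.name] if len(fragments) else fragments.iloc[0:0]
    return out


def deduplicate(fragments: pd.DataFrame) -> pd.DataFrame:
    """Drop coordinate-identical fragments (PCR-duplicate removal).

    Two fragments are duplicates iff they agree on (chrom, start, end,
    strand); the first occurrence is kept.  Strand is part of the key, so
    sense/antisense fragments over the same span both survive.
    """
    if len(fragments) == 0:
        return fragments
    return fragments.drop_duplicates(subset=["chrom", "start", "end", "strand"], keep="first")


def compute_normalization_factor(n_spike: int, scale_constant: float = DEFAULT_SCALE_CONSTANT) -> float:
    """alpha = C / n_spike; strictly decreasing in the spike-in count."""
    if scale_constant <= 0:
        raise ValueError(f"scale constant must be positive, got {scale_constant}")
    if n_spike <= 0:
        raise ValueError("no spike-in reads: cannot compute a normalization factor")
    return scale_constant / n_spike


def spike_in_factors(
    fragments: pd.DataFrame,
    layout: GenomeLayout,
    sample_id: str,
    scale_constant: float = DEFAULT_SCALE_CONSTANT,
    already_deduplicated: bool = False,
) -> SpikeInFactors:
    """Split + dedup a sample's fragments and derive its SpikeInFactors.

    Emits a WARN when the observed spike fraction falls outside the
    plausible experimental range [0.005, 0.10].
    """
    if not already_deduplicated:
        fragments = deduplicate(fragments)
    buckets = split_by_organism(fragments, layout)
    n_primary = len(buckets[layout.primary.name])
    n_spike = len(buckets[layout.spikein.name])
    factors = SpikeInFactors(sample_id, n_primary, n_spike, scale_constant)
    frac = factors.spike_fraction
    if not (0.005 <= frac <= 0.10):
        log.warning(
            "sample %s: spike-in fraction %.4f outside expected range [0.005, 0.10]",
            sample_id,
            frac,
        )
    return factors


def count_fragments_in_peaks(peaks: pd.DataFrame, fragments: pd.DataFrame) -> np.ndarray:
    """Per peak, the number of fragments overlapping it by >= 1 bp."""
    as_interval_frame(peaks)
    index = IntervalIndex(fragments) if len(fragments) else None
    counts = np.zeros(len(peaks), dtype=np.int64)
    if index is None:
        return counts
    chrom_arr = peaks["chrom"].to_numpy()
    starts = peaks["start"].to_numpy(np.int64)
    ends = peaks["end"].to_numpy(np.int64)
    for chrom in pd.unique(chrom_arr):
        mask = chrom_arr == chrom
        counts[mask] = index.count_overlaps(str(chrom), starts[mask], ends[mask])
    return counts


def normalize_peak_counts(
    peaks: pd.DataFrame,
    fragments: pd.DataFrame,
    alpha: float,
    layout: GenomeLayout | None = None,
) -> pd.Series:
    """Spike-in-normalized per-peak signal: overlap count x alpha.

    ``fragments`` must be primary-organism, deduplicated fragments of one
    sample.  When a layout is given, peak chromosomes are validated against
    the primary organism.
    """
    if alpha <= 0:
        raise ValueError(f"normalization factor must be positive, got {alpha}")
    if layout is not None:
        primary_chroms = set(layout.primary_chromosomes())
        for chrom in pd.unique(peaks["chrom"].to_numpy()):
            if chrom not in primary_chroms:
                raise KeyError(f"peak chromosome {chrom!r} is not a primary-organism chromosome")
    counts = count_fragments_in_peaks(peaks, fragments)
    names = (
        peaks["name"].astype(str)
        if "name" in peaks.columns
        else pd.Index([f"peak_{i}" for i in range(len(peaks))])
    )
    return pd.Series(counts * float(alpha), index=pd.Index(names, name="peak"), name="signal")
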