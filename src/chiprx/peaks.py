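"""Peak-set operations: enrichment-domain calling, cross-condition
classification, promoter assignment, Venn counts, and the
tumor-initiating-set construction.

All intervals are 0-based half-open; two intervals overlap iff they share
at least one base.  Peak classification across a control sample and two
condition clones follows the replicate-overlap rule: a condition peak
counts only if it is present (overlaps a peak) in *both* clones; replicated
condition peaks overlapping a control peak are "common", the rest
"unique_condition"; control peaks overlapping neither clone are
"unique_control"; clone peaks without a mate in the sibling clone are
"unreplicated" and excluded downstream.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack
from .intervals import as_interval_frame, merge_intervals, overlaps_any
from .metagene import tss_positions, validate_genes

log = logging.getLogger(__name__)

LABELS = ("common", "unique_condition", "unique_control", "unreplicated")


# ---------------------------------------------------------------------------
# plumbing enrichment-domain caller
# ---------------------------------------------------------------------------

def call_enrichment_domains(
    sample_cov: CoverageTrack,
    control_cov: CoverageTrack,
    window_bp: int = 200,
    step_bp: int = 100,
    p_cutoff: float = 1e-5,
    merge_gap: int = 500,
    pseudocount: float = 0.25,
    control_scaling: str = "depth",
) -> pd.DataFrame:
    """Sliding-window Poisson enrichment caller (broad-mark flavoured).

    Windows whose fragment-start count exceeds the Poisson upper-tail
    threshold at ``p_cutoff``, given the control-derived expected count,
    are retained and merged into domains when closer than ``merge_gap`` bp.
    This is deliberately simple plumbing for synthetic end-to-end runs, not
    a re-implementation of a production peak caller.

    ``control_scaling``:
      * ``"depth"`` (default): control window counts scaled by the ratio of
        total mapped fragments (sample / control).
      * ``"background"``: scaled so the median window count of the control
        matches the sample's — more robust when most sample fragments sit
        inside enriched domains.
    """
    if control_scaling not in ("depth", "background"):
        raise ValueError(f"unknown control_scaling {control_scaling!r}")
    if sample_cov.total_mapped == 0:
        log.warning("zero-depth sample: no domains called")
        return _empty_peaks()
    rows = []
    n_domain = 0
    genome_bp = sum(len(a) for a in sample_cov.data.values())
    # genome-wide control rate per window: the floor under the local
    # estimate, so a locally empty control cannot deflate lambda to zero
    ctrl_global = control_cov.total_mapped * window_bp / max(genome_bp, 1)
    for chrom in sorted(sample_cov.data):
        L = len(sample_cov.data[chrom])
        if L < window_bp:
            continue
        starts = np.arange(0, L - window_bp + 1, step_bp, dtype=np.int64)
        ends = starts + window_bp
        counts = sample_cov.window_start_counts(chrom, starts, ends)
        ctrl = control_cov.window_start_counts(chrom, starts, ends).astype(float)
        if control_scaling == "depth":
            scale = sample_cov.total_mapped / max(control_cov.total_mapped, 1)
        else:
            med_s = np.median(counts)
            med_c = max(np.median(ctrl), ctrl_global)
            scale = med_s / med_c if med_c > 0 else sample_cov.total_mapped / max(control_cov.total_mapped, 1)
        lam = np.maximum(ctrl, ctrl_global) * scale + pseudocount
        pvals = stats.poisson.sf(counts - 1, lam)
        keep = (pvals <= p_cutoff) & (counts > 0)
        if keep.any():
            ms, me = merge_intervals(starts[keep], ends[keep], gap=merge_gap)
            for s, e in zip(ms, me):
                n_domain += 1
                rows.append((chrom, int(s), int(e), f"domain_{n_domain}"))
    if not rows:
        return _empty_peaks()
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _empty_peaks() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=object), "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64), "name": pd.Series(dtype=object)})


# ---------------------------------------------------------------------------
# classification across control + two condition clones
# ---------------------------------------------------------------------------

def classify_peaks(
    control: pd.DataFrame, clone1: pd.DataFrame, clone2: pd.DataFrame
) -> pd.DataFrame:
    """Label peaks as common / unique_condition / unique_control / unreplicated.

    The classified universe is: clone1 peaks that overlap clone2 (the
    replicated condition peaks, reported with clone1 coordinates), all
    control peaks, and — labelled ``unreplicated`` — clone peaks with no
    mate in the sibling clone.  A control peak overlapping either clone is
    part of a common region and is labelled ``common``.

    Returns a BED-like frame with columns chrom/start/end/name/label/origin.
    """
    for df in (control, clone1, clone2):
        if len(df):
            as_interval_frame(df)

    def _lab(df, mask_true, true_label, false_label, origin):
        out = df.loc[:, ["chrom", "start", "end"]].copy()
        out["name"] = df["name"].astype(str) if "name" in df.columns else [
            f"{origin}_{i}" for i in range(len(df))
        ]
        out["label"] = np.where(mask_true, true_label, false_label)
        out["origin"] = origin
        return out

    rep1 = overlaps_any(clone1, clone2) if len(clone1) and len(clone2) else np.zeros(len(clone1), bool)
    rep2 = overlaps_any(clone2, clone1) if len(clone1) and len(clone2) else np.zeros(len(clone2), bool)

    replicated = clone1.loc[rep1]
    rep_common = (
        overlaps_any(replicated, control) if len(replicated) and len(control) else np.zeros(len(replicated), bool)
    )
    parts = [_lab(replicated, rep_common, "common", "unique_condition", "clone1")]

    if len(control):
        c1 = overlaps_any(control, clone1) if len(clone1) else np.zeros(len(control), bool)
        c2 = overlaps_any(control, clone2) if len(clone2) else np.zeros(len(control), bool)
        parts.append(_lab(control, c1 | c2, "common", "unique_control", "control"))

    unrep1 = clone1.loc[~rep1]
    unrep2 = clone2.loc[~rep2]
    if len(unrep1):
        parts.append(_lab(unrep1, np.ones(len(unrep1), bool), "unreplicated", "unreplicated", "clone1"))
    if len(unrep2):
        parts.append(_lab(unrep2, np.ones(len(unrep2), bool), "unreplicated", "unreplicated", "clone2"))

    out = pd.concat(parts, ignore_index=True) if parts else _empty_peaks()
    return out


def classification_summary(classified: pd.DataFrame) -> pd.Series:
    """Peak counts per label (all four labels always present)."""
    counts = classified["label"].value_counts()
    return pd.Series({lab: int(counts.get(lab, 0)) for lab in LABELS}, name="n_peaks")


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def make_promoters(
    genes: pd.DataFrame, upstream_bp: int = 2000, downstream_bp: int = 500
) -> pd.DataFrame:
    """Strand-aware promoter windows around each TSS.

    On '+' the window is [TSS - upstream, TSS + downstream); on '-' it is
    mirrored, [TSS - downstream + 1, TSS + upstream + 1).  Both defaults
    follow the -2000/+500 convention; the Fig-2E-style -2000/+1000 window
    is a parameter change.  Windows are clipped at position 0.
    """
    if upstream_bp <= 0 or downstream_bp <= 0:
        raise ValueError("promoter window widths must be positive")
    validate_genes(genes)
    tss = tss_positions(genes).to_numpy()
    plus = genes["strand"].to_numpy() == "+"
    starts = np.where(plus, tss - upstream_bp, tss - downstream_bp + 1)
    ends = np.where(plus, tss + downstream_bp, tss + upstream_bp + 1)
    starts = np.maximum(starts, 0)
    return pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy(),
            "start": starts.astype(np.int64),
            "end": ends.astype(np.int64),
            "gene_id": genes["gene_id"].astype(str).to_numpy(),
        }
    )


def assign_promoters(peaks: pd.DataFrame, promoters: pd.DataFrame) -> set[str]:
    """gene_ids whose promoter window overlaps >= 1 peak by >= 1 bp."""
    if len(peaks) == 0 or len(promoters) == 0:
        return set()
    hit = overlaps_any(promoters, peaks)
    return set(promoters.loc[hit, "gene_id"].astype(str))


# ---------------------------------------------------------------------------
# set algebra
# ---------------------------------------------------------------------------

def venn_counts(named_sets: dict[str, set] | list[tuple[str, set]]) -> dict[frozenset, int]:
    """Exclusive-region counts of the inclusion-exclusion partition.

    Returns {frozenset of member names -> count of elements belonging to
    exactly those sets}; counts sum to the union size.
    """
    if isinstance(named_sets, dict):
        items = list(named_sets.items())
    else:
        items = list(named_sets)
        names = [n for n, _ in items]
        if len(names) != len(set(names)):
            raise ValueError("duplicate set names in venn_counts input")
    if len(items) < 2:
        raise ValueError("venn_counts requires at least two named sets")
    out: dict[frozenset, int] = {}
    for r in range(1, len(items) + 1):
        for combo in combinations(items, r):
            region = frozenset(n for n, _ in combo)
            inside = set.intersection(*(s for _, s in combo))
            outside = set.union(set(), *(s for n, s in items if n not in region))
            out[region] = len(inside - outside)
    return out


def build_initiating_set(ref_a: set[str], ref_b: set[str], sample: set[str]) -> set[str]:
    """Presumed baseline occupancy: (refA & refB) | (sample - (refA | refB)).

    Mirrors the construction of a pre-transformation peak universe from two
    reference samples plus the peaks unique to the tumour sample.
    """
    return (set(ref_a) & set(ref_b)) | (set(sample) - (set(ref_a) | set(ref_b)))
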