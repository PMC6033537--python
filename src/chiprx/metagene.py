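"""Expression-stratified metagene (TSS->TES) profiles.

Genes are ranked by expression and split into near-equal tiers (default
tertiles: high / medium / low).  For each gene the profile covers a fixed
10-kb upstream flank, the gene body rescaled to 100 equal-fraction bins,
and a 10-kb downstream flank, each flank likewise in 100 fixed-width bins.
Per-bin mean density is expressed in RPK10M; minus-strand genes are
reversed so bin 0 is always the 5'-most position.  The tier profile is the
unweighted mean of its genes' per-bin densities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, rpk10m

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
DEFAULT_TIER_LABELS = ("high", "medium", "low")


def validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    for col in GENE_COLUMNS:
        if col not in genes.columns:
            raise ValueError(f"gene table missing required column {col!r}")
    if (genes["start"].to_numpy() >= genes["end"].to_numpy()).any():
        raise ValueError("gene with span_start >= span_end")
    if not genes["strand"].isin(["+", "-"]).all():
        raise ValueError("gene strand must be '+' or '-'")
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r}")
    return genes


def tss_positions(genes: pd.DataFrame) -> pd.Series:
    """0-based TSS base per gene: span_start on '+', span_end - 1 on '-'."""
    validate_genes(genes)
    plus = genes["strand"].to_numpy() == "+"
    tss = np.where(plus, genes["start"].to_numpy(), genes["end"].to_numpy() - 1)
    return pd.Series(tss, index=genes["gene_id"].to_numpy(), name="tss")


def stratify_genes(
    genes: pd.DataFrame,
    expression: pd.Series,
    k: int = 3,
    labels: tuple[str, ...] | None = None,
) -> pd.Series:
    """Assign genes to k contiguous expression-rank tiers.

    Genes are ranked by expression descending (ties broken by gene_id,
    lexicographic) and split into k groups whose sizes differ by at most
    one, larger groups at higher tiers.  Returns gene_id -> tier label.
    """
    validate_genes(genes)
    ids = genes["gene_id"].astype(str).to_numpy()
    missing = [g for g in ids if g not in expression.index]
    if missing:
        raise KeyError(f"genes missing expression values: {missing[:10]}" + (" ..." if len(missing) > 10 else ""))
    values = expression.loc[ids].to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression values must be nonnegative")
    if labels is None:
        labels = DEFAULT_TIER_LABELS if k == 3 else tuple(f"tier_{i + 1}" for i in range(k))
    if len(labels) != k:
        raise ValueError(f"need {k} tier labels, got {len(labels)}")
    # sort by (-expression, gene_id): descending expression, ties by id
    order = np.lexsort((ids, -values))
    n = len(ids)
    base, extra = divmod(n, k)
    sizes = [base + (1 if i < extra else 0) for i in range(k)]
    tier_arr = np.empty(n, dtype=object)
    pos = 0
    for label, size in zip(labels, sizes):
        tier_arr[order[pos : pos + size]] = label
        pos += size
    return pd.Series(tier_arr, index=pd.Index(ids, name="gene_id"), name="tier")


@dataclass
class MetageneProfile:
    """tier x (3B) matrix of mean RPK10M density over flank-body-flank."""

    values: pd.DataFrame  # index: tier labels, columns: 0..3B-1
    n_bins: int
    flank_bp: int
    genes_per_tier: dict[str, int]

    @property
    def segments(self) -> dict[str, slice]:
        B = self.n_bins
        return {"upstream": slice(0, B), "body": slice(B, 2 * B), "downstream": slice(2 * B, 3 * B)}

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "tier"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, flank_bp: int = 10_000) -> "MetageneProfile":
        values = pd.read_csv(path, sep="\t", index_col=0)
        values.columns = values.columns.astype(int)
        B = values.shape[1] // 3
        return cls(values=values, n_bins=B, flank_bp=flank_bp, genes_per_tier={})


def _body_boundaries(length: int, n_bins: int) -> np.ndarray:
    """Half-open body bin boundaries: boundary_i = round(L*i/B)."""
    i = np.arange(n_bins + 1, dtype=np.float64)
    return np.floor(length * i / n_bins + 0.5).astype(np.int64)


def gene_profile(
    track: CoverageTrack,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    n_bins: int = 100,
    flank_bp: int = 10_000,
) -> np.ndarray:
    """Per-gene 3B-vector of RPK10M densities, 5'->3'.

    Body bins use fractional boundaries round(L*i/B); flank bins are fixed
    ``flank_bp / B``-wide.  Flank bins truncated by a chromosome edge are
    measured over their covered width only; fully-off-chromosome bins are 0.
    """
    B = n_bins
    L = end - start
    if L < B:
        raise ValueError(f"gene of length {L} is shorter than {B} bins")
    if flank_bp % B:
        raise ValueError(f"flank ({flank_bp}) must be divisible by the bin count ({B})")
    flank_w = flank_bp // B
    total = track.total_mapped
    chrom_len = len(track.data[chrom]) if chrom in track.data else 0

    def bin_value(lo: int, hi: int) -> float:
        c_lo, c_hi = max(lo, 0), min(hi, chrom_len)
        width = c_hi - c_lo
        if width <= 0:
            return 0.0
        return rpk10m(track.coverage_sum(chrom, c_lo, c_hi), width, total)

    bounds = _body_boundaries(L, B)
    body = [bin_value(start + bounds[i], start + bounds[i + 1]) for i in range(B)]

    if strand == "+":
        upstream = [bin_value(start - flank_bp + j * flank_w, start - flank_bp + (j + 1) * flank_w) for j in range(B)]
        downstream = [bin_value(end + j * flank_w, end + (j + 1) * flank_w) for j in range(B)]
        return np.array(upstream + body + downstream)
    elif strand == "-":
        # 5'-most flank bin is the genomically-rightmost one
        upstream = [bin_value(end + (B - 1 - j) * flank_w, end + (B - j) * flank_w) for j in range(B)]
        downstream = [bin_value(start - (j + 1) * flank_w, start - j * flank_w) for j in range(B)]
        return np.array(upstream + body[::-1] + downstream)
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def metagene_profile(
    track: CoverageTrack,
    genes: pd.DataFrame,
    tiers: pd.Series,
    n_bins: int = 100,
    flank_bp: int = 10_000,
) -> MetageneProfile:
    """Tier-averaged metagene profile.

    Genes shorter than ``n_bins`` bp are excluded up front (their body bins
    would be zero-width).  Each tier present in ``tiers`` must retain at
    least one gene after that exclusion.
    """
    validate_genes(genes)
    lengths = genes["end"].to_numpy() - genes["start"].to_numpy()
    usable = genes.loc[lengths >= n_bins]
    tier_labels = list(dict.fromkeys(tiers.to_numpy()))
    profiles: dict[str, list[np.ndarray]] = {t: [] for t in tier_labels}
    for row in usable.itertuples(index=False):
        tier = tiers.get(row.gene_id)
        if tier is None:
            continue
        vec = gene_profile(track, row.chrom, int(row.start), int(row.end), row.strand, n_bins, flank_bp)
        profiles[tier].append(vec)
    empty = [t for t, vecs in profiles.items() if not vecs]
    if empty:
        raise ValueError(f"tier(s) with no usable genes: {empty}")
    values = pd.DataFrame(
        {t: np.mean(np.vstack(vecs), axis=0) for t, vecs in profiles.items()}
    ).T
    values.columns = range(3 * n_bins)
    values = values.loc[tier_labels]
    return MetageneProfile(
        values=values,
        n_bins=n_bins,
        flank_bp=flank_bp,
        genes_per_tier={t: len(v) for t, v in profiles.items()},
    )
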