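"""Seeded synthetic ChIP-Rx study generator.

Generates a complete toy two-organism dataset carrying the statistical
structure the pipeline assumes:

* a combined primary + spike-in genome with prefixed chromosome names;
* non-overlapping genes in fixed-width slots, with planted expression
  tiers (log-normal within tier);
* per-mark planted enrichment domains —

  - ``H3K27me3``: broad domains centred on the promoters of low-expression
    genes.  In the mutant condition most are reduced to a global factor
    ``f`` (the genome-wide H3K27me3 loss caused by the K27M oncohistone)
    while a ``retained_fraction`` keeps full signal ("strong PRC2 sites");
  - ``Ezh2``: sharp domains at the same PRC2 sites; in the mutant the
    enzyme leaves the reduced sites and reappears at planted poised
    enhancers (redistribution);
  - ``H3.3K27M``: mutant-only occupancy over highly expressed gene bodies,
    over the reduced PRC2 sites, and at poised enhancers;
  - ``H3K4me1``: enhancer domains shared by both conditions, a planted
    subset of which are the poised enhancers;
  - ``input``: uniform background;

* fragments sampled from a Poisson-intensity mixture: per-base weight 1 in
  background and ``max(fold * factor, 1)`` inside a domain, with a fixed
  sequencing depth per sample.  Spike-in chromatin contributes a constant
  weight calibrated so the control sample's expected spike read share
  equals ``spike_fraction``; a condition that loses primary signal
  therefore yields proportionally more spike reads — exactly the handle
  spike-in normalization uses, and exactly what fixed-depth resampling
  hides from plain depth normalization.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .layout import GenomeLayout, Organism

MARKS = ("H3K27me3", "Ezh2", "H3.3K27M", "H3K4me1", "input")

# fixed slot geometry (bp offsets within a gene slot); chosen so that the
# broad promoter domain of one slot can never reach the enhancer or the
# domain of a neighbouring slot, whatever the strand
_ENHANCER_OFFSET = 500
_GENE_OFFSET = 7_000
_EDGE_MARGIN = 10_000


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic ChIP-Rx experiment.

    Defaults are the conditions the pipeline is validated under: a 10-Mb
    two-chromosome primary genome with a 1-Mb spike-in genome, 600 genes in
    three expression tiers, 200 broad H3K27me3 domains, a 30% residual
    H3K27me3 level (f = 0.3) in the mutant with a quarter of domains fully
    retained, 2% spike-in chromatin, and 100,000 fragments per sample.
    """

    seed: int = 0
    # genomes
    primary_organism: str = "human"
    primary_prefix: str = "hs_"
    primary_chromosomes: tuple[tuple[str, int], ...] = (("chr1", 5_000_000), ("chr2", 5_000_000))
    spike_organism: str = "fly"
    spike_prefix: str = "dm_"
    spike_chromosomes: tuple[tuple[str, int], ...] = (("chr1", 1_000_000),)
    # genes & expression
    n_genes: int = 600
    slot_bp: int = 16_000
    gene_length_min: int = 600
    gene_length_max: int = 4_000
    gene_length_log_mean: float = math.log(1_500)
    gene_length_log_sigma: float = 0.5
    expression_tier_medians: tuple[float, float, float] = (50.0, 5.0, 0.5)
    expression_log_sigma: float = 0.5
    # planted domains
    n_domains: int = 200          # H3K27me3 / PRC2 sites
    domain_width: int = 10_000
    k27me3_fold: float = 50.0
    ezh2_width: int = 2_000
    ezh2_fold: float = 20.0
    global_reduction: float = 0.3  # f: residual H3K27me3/Ezh2 level in the mutant
    retained_fraction: float = 0.25
    n_enhancers: int = 200
    enhancer_width: int = 1_000
    enhancer_fold: float = 20.0
    poised_fraction: float = 0.5
    k27m_body_fold: float = 8.0
    k27m_overlay_fold: float = 6.0
    # sequencing
    depth: int = 100_000
    spike_fraction: float = 0.02
    fragment_length: int = 150

    def __post_init__(self) -> None:
        if not (0.0 < self.spike_fraction < 1.0):
            raise ValueError("spike_fraction must lie in (0, 1)")
        if not (0.0 < self.global_reduction <= 1.0):
            raise ValueError("global_reduction f must lie in (0, 1]")
        if not (0.0 <= self.retained_fraction < 1.0):
            raise ValueError("retained_fraction must lie in [0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_genes and self.n_domains > self.n_genes // 3:
            raise ValueError("n_domains cannot exceed the low-expression tier size (n_genes // 3)")
        if self.n_enhancers > self.n_genes and self.n_genes > 0:
            raise ValueError("n_enhancers cannot exceed n_genes (one enhancer per gene slot)")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class TruthSet:
    """Planted ground truth of a synthetic study."""

    domains: dict[str, pd.DataFrame]  # mark -> chrom,start,end,name,fold,factor_control,factor_condition,kind
    enhancers: pd.DataFrame
    poised_enhancers: pd.DataFrame
    retained_domains: list[str]  # H3K27me3 domain names with full mutant signal
    reduced_domains: list[str]

    def peaks(self, mark: str, condition: str) -> pd.DataFrame:
        """Truth peak intervals of a mark present in the given condition."""
        dom = self.domains[mark]
        col = f"factor_{condition}"
        present = dom.loc[dom[col].to_numpy() > 0.0]
        return present.loc[:, ["chrom", "start", "end", "name"]].reset_index(drop=True)


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    layout: GenomeLayout
    genes: pd.DataFrame
    expression: pd.Series
    tiers: pd.Series          # planted tier per gene
    truth: TruthSet
    slots: pd.DataFrame = field(repr=False, default=None)
    samples: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)
    sample_table: pd.DataFrame = field(default=None, repr=False)


DEFAULT_SAMPLES: tuple[tuple[str, str, int], ...] = (
    ("H3K27me3", "control", 1),
    ("H3K27me3", "control", 2),
    ("H3K27me3", "k27m", 1),
    ("H3K27me3", "k27m", 2),
    ("Ezh2", "control", 1),
    ("Ezh2", "k27m", 1),
    ("Ezh2", "k27m", 2),
    ("H3.3K27M", "k27m", 1),
    ("H3K4me1", "k27m", 1),
    ("input", "control", 1),
    ("input", "k27m", 1),
)


def sample_id(mark: str, condition: str, rep: int) -> str:
    return f"{mark}_{condition}_rep{rep}"


# ---------------------------------------------------------------------------
# genome / genes
# ---------------------------------------------------------------------------

def make_layout(config: SimulationConfig) -> GenomeLayout:
    return GenomeLayout(
        [
            Organism(config.primary_organism, "primary", config.primary_prefix,
                     dict(config.primary_chromosomes)),
            Organism(config.spike_organism, "spikein", config.spike_prefix,
                     dict(config.spike_chromosomes)),
        ]
    )


def make_genome(config: SimulationConfig) -> tuple[GenomeLayout, pd.DataFrame, pd.Series, pd.Series, pd.DataFrame]:
    """Deterministically build layout, genes, expression, planted tiers, slots.

    Genes occupy fixed non-overlapping slots laid left to right across the
    primary chromosomes (with a margin at each chromosome edge); raises if
    the requested gene count does not fit.
    """
    rng = np.random.default_rng([config.seed, 1])
    layout = make_layout(config)
    slots = []
    for chrom, length in layout.primary_chromosomes().items():
        capacity = max(0, (length - 2 * _EDGE_MARGIN) // config.slot_bp)
        for i in range(capacity):
            slots.append((chrom, _EDGE_MARGIN + i * config.slot_bp))
    if config.n_genes > len(slots):
        raise ValueError(
            f"cannot place {config.n_genes} non-overlapping genes in {len(slots)} slots; "
            "use longer chromosomes or fewer genes"
        )
    slots = slots[: config.n_genes]
    n = config.n_genes
    if n == 0:
        genes = pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand"])
        empty = pd.Series(dtype=float)
        return layout, genes, empty, pd.Series(dtype=object), pd.DataFrame(columns=["chrom", "slot_start"])
    lengths = np.exp(rng.normal(config.gene_length_log_mean, config.gene_length_log_sigma, n))
    lengths = np.clip(lengths, config.gene_length_min, config.gene_length_max).astype(np.int64)
    strands = rng.choice(["+", "-"], size=n)
    gene_ids = [f"g{i:04d}" for i in range(n)]
    starts = np.array([s + _GENE_OFFSET for _, s in slots], dtype=np.int64)
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": [c for c, _ in slots],
            "start": starts,
            "end": starts + lengths,
            "strand": strands,
        }
    )
    # planted tiers: random thirds (high gets the remainder, as ranks do)
    perm = rng.permutation(n)
    base, extra = divmod(n, 3)
    sizes = [base + (1 if i < extra else 0) for i in range(3)]
    tier_arr = np.empty(n, dtype=object)
    pos = 0
    for label, size in zip(("high", "medium", "low"), sizes):
        tier_arr[perm[pos : pos + size]] = label
        pos += size
    tiers = pd.Series(tier_arr, index=pd.Index(gene_ids, name="gene_id"), name="tier")
    medians = dict(zip(("high", "medium", "low"), config.expression_tier_medians))
    mu = np.array([math.log(medians[t]) for t in tier_arr])
    expression = pd.Series(
        np.exp(rng.normal(mu, config.expression_log_sigma)),
        index=pd.Index(gene_ids, name="gene_id"),
        name="expression",
    )
    slot_df = pd.DataFrame({"gene_id": gene_ids, "chrom": [c for c, _ in slots],
                            "slot_start": [s for _, s in slots]})
    return layout, genes, expression, tiers, slot_df


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def _tss(genes: pd.DataFrame) -> np.ndarray:
    plus = genes["strand"].to_numpy() == "+"
    return np.where(plus, genes["start"].to_numpy(), genes["end"].to_numpy() - 1)


def make_truth(
    config: SimulationConfig,
    genes: pd.DataFrame,
    tiers: pd.Series,
    slots: pd.DataFrame,
) -> TruthSet:
    rng = np.random.default_rng([config.seed, 2])
    f = config.global_reduction

    def dom_frame(rows, columns=("chrom", "start", "end", "name", "fold",
                                 "factor_control", "factor_condition", "kind")):
        return pd.DataFrame(rows, columns=list(columns))

    domains: dict[str, pd.DataFrame] = {}

    # --- H3K27me3 / PRC2 sites at low-tier promoters -----------------------
    low_ids = list(tiers.index[tiers.to_numpy() == "low"])
    site_ids = (
        [str(g) for g in sorted(rng.choice(low_ids, size=config.n_domains, replace=False))]
        if config.n_domains and low_ids
        else []
    )
    n_ret = int(round(config.retained_fraction * len(site_ids)))
    retained = {str(g) for g in rng.choice(site_ids, size=n_ret, replace=False)} if n_ret else set()
    gene_ix = genes.set_index("gene_id")
    half = config.domain_width // 2
    e_half = config.ezh2_width // 2
    k27me3_rows, ezh2_rows = [], []
    for gid in site_ids:
        row = gene_ix.loc[gid]
        tss = int(row["start"] if row["strand"] == "+" else row["end"] - 1)
        kind = "retained" if gid in retained else "reduced"
        fac_cond = 1.0 if kind == "retained" else f
        k27me3_rows.append((row["chrom"], tss - half, tss + half, gid,
                            config.k27me3_fold, 1.0, fac_cond, kind))
        # Ezh2 leaves the reduced sites in the mutant (redistribution)
        ez_cond = 1.0 if kind == "retained" else 0.0
        ezh2_rows.append((row["chrom"], tss - e_half, tss + e_half, f"ez_{gid}",
                          config.ezh2_fold, 1.0, ez_cond, f"prc2_site_{kind}"))
    domains["H3K27me3"] = dom_frame(k27me3_rows)

    # --- enhancers / poised enhancers --------------------------------------
    enh_slots = slots.iloc[
        sorted(rng.choice(len(slots), size=min(config.n_enhancers, len(slots)), replace=False))
    ] if len(slots) else slots
    enh_rows = []
    for j, s in enumerate(enh_slots.itertuples(index=False)):
        e0 = s.slot_start + _ENHANCER_OFFSET
        enh_rows.append((s.chrom, e0, e0 + config.enhancer_width, f"enh_{j:04d}"))
    enhancers = pd.DataFrame(enh_rows, columns=["chrom", "start", "end", "name"])
    n_poised = int(round(config.poised_fraction * len(enhancers)))
    poised_ix = sorted(rng.choice(len(enhancers), size=n_poised, replace=False)) if n_poised else []
    poised = enhancers.iloc[poised_ix].reset_index(drop=True)

    domains["H3K4me1"] = dom_frame(
        [(r.chrom, r.start, r.end, r.name, config.enhancer_fold, 1.0, 1.0, "enhancer")
         for r in enhancers.itertuples(index=False)]
    )

    # Ezh2 appears at poised enhancers in the mutant only
    for r in poised.itertuples(index=False):
        ezh2_rows.append((r.chrom, r.start, r.end, f"ez_{r.name}",
                          config.ezh2_fold, 0.0, 1.0, "poised_enhancer"))
    domains["Ezh2"] = dom_frame(ezh2_rows)

    # --- H3.3K27M: mutant-only occupancy -----------------------------------
    k27m_rows = []
    high_ids = tiers.index[tiers.to_numpy() == "high"]
    for gid in high_ids:
        row = gene_ix.loc[gid]
        k27m_rows.append((row["chrom"], int(row["start"]), int(row["end"]), f"km_{gid}",
                          config.k27m_body_fold, 0.0, 1.0, "gene_body"))
    for r in domains["H3K27me3"].itertuples(index=False):
        if r.kind == "reduced":
            k27m_rows.append((r.chrom, r.start, r.end, f"km_{r.name}",
                              config.k27m_overlay_fold, 0.0, 1.0, "k27me3_overlay"))
    for r in poised.itertuples(index=False):
        k27m_rows.append((r.chrom, r.start, r.end, f"km_{r.name}",
                          config.k27m_overlay_fold, 0.0, 1.0, "poised_enhancer"))
    domains["H3.3K27M"] = dom_frame(k27m_rows)

    domains["input"] = dom_frame([])

    return TruthSet(
        domains=domains,
        enhancers=enhancers,
        poised_enhancers=poised,
        retained_domains=sorted(retained),
        reduced_domains=[g for g in site_ids if g not in retained],
    )


# ---------------------------------------------------------------------------
# fragment sampling
# ---------------------------------------------------------------------------

def _segments_for(
    layout: GenomeLayout, domains: pd.DataFrame, factor_col: str
) -> tuple[list[tuple[str, int, int, float]], float]:
    """Piecewise-constant per-base weights over the primary genome.

    Returns (segments, total_weight); each segment is (chrom, start,
    length, multiplier) with multiplier = max(fold * factor, 1) inside a
    domain and 1 in background.  Domains of one mark are disjoint by
    construction.
    """
    segs: list[tuple[str, int, int, float]] = []
    total = 0.0
    for chrom, length in layout.primary_chromosomes().items():
        sub = domains.loc[domains["chrom"] == chrom].sort_values("start") if len(domains) else domains
        pos = 0
        if len(domains):
            for r in sub.itertuples(index=False):
                if r.start > pos:
                    segs.append((chrom, pos, r.start - pos, 1.0))
                mult = max(r.fold * getattr(r, factor_col), 1.0)
                segs.append((chrom, int(r.start), int(r.end - r.start), mult))
                pos = int(r.end)
        if pos < length:
            segs.append((chrom, pos, length - pos, 1.0))
    for _, _, seg_len, mult in segs:
        total += seg_len * mult
    return segs, total


def simulate_sample(
    layout: GenomeLayout,
    truth: TruthSet,
    mark: str,
    condition: str,
    config: SimulationConfig,
    rep: int = 1,
) -> pd.DataFrame:
    """Sample one library of exactly ``config.depth`` aligned fragments.

    Fragment start positions follow the piecewise-constant intensity of the
    mark in the given condition; spike-in fragments are uniform over the
    spike genome with a constant expected chromatin share calibrated on the
    control composition of the mark.
    """
    if mark not in truth.domains:
        raise KeyError(f"mark {mark!r} not present in the truth set")
    if condition not in ("control", "k27m"):
        raise ValueError(f"condition must be 'control' or 'k27m', got {condition!r}")
    rng = np.random.default_rng([config.seed, 3, MARKS.index(mark), {"control": 0, "k27m": 1}[condition], rep])
    factor_col = "factor_control" if condition == "control" else "factor_condition"
    domains = truth.domains[mark]
    segs, w_primary = _segments_for(layout, domains, factor_col)
    _, w_primary_ref = _segments_for(layout, domains, "factor_control")
    sf = config.spike_fraction
    w_spike = sf / (1.0 - sf) * w_primary_ref

    depth = config.depth
    p_spike = w_spike / (w_spike + w_primary)
    n_spike = int(rng.binomial(depth, p_spike))
    n_primary = depth - n_spike
    frag_len = config.fragment_length

    # primary fragments: inverse-CDF over the piecewise weights
    seg_chrom = np.array([s[0] for s in segs], dtype=object)
    seg_start = np.array([s[1] for s in segs], dtype=np.int64)
    seg_len = np.array([s[2] for s in segs], dtype=np.int64)
    seg_w = seg_len * np.array([s[3] for s in segs])
    cum = np.cumsum(seg_w)
    u = rng.random(n_primary) * cum[-1]
    pick = np.searchsorted(cum, u, side="right")
    within = (u - (cum[pick] - seg_w[pick])) / seg_w[pick] * seg_len[pick]
    starts = seg_start[pick] + within.astype(np.int64)
    chroms = seg_chrom[pick]
    # clamp so fragments stay within chromosome bounds
    chrom_len = layout.primary_chromosomes()
    max_start = np.array([chrom_len[c] - frag_len for c in chroms], dtype=np.int64)
    starts = np.minimum(starts, max_start)

    # spike fragments: uniform over the spike genome
    spike_chroms = layout.spikein_chromosomes()
    sc_names = list(spike_chroms)
    sc_len = np.array([spike_chroms[c] for c in sc_names], dtype=np.int64)
    sc_cum = np.cumsum(sc_len)
    us = rng.integers(0, sc_cum[-1], size=n_spike)
    s_pick = np.searchsorted(sc_cum, us, side="right")
    s_start = us - (sc_cum[s_pick] - sc_len[s_pick])
    s_start = np.minimum(s_start, sc_len[s_pick] - frag_len)
    s_chrom = np.array(sc_names, dtype=object)[s_pick]

    all_chrom = np.concatenate([chroms, s_chrom])
    all_start = np.concatenate([starts, s_start]).astype(np.int64)
    strand = rng.choice(["+", "-"], size=depth)
    sid = sample_id(mark, condition, rep)
    return pd.DataFrame(
        {
            "chrom": all_chrom,
            "start": all_start,
            "end": all_start + frag_len,
            "name": [f"frag_{i}" for i in range(depth)],
            "score": np.zeros(depth, dtype=np.int64),
            "strand": strand,
            "sample_id": sid,
        }
    )


def simulate_study(
    config: SimulationConfig,
    samples: tuple[tuple[str, str, int], ...] = DEFAULT_SAMPLES,
) -> SyntheticStudy:
    """Build genome, truth, and all requested sample libraries."""
    layout, genes, expression, tiers, slots = make_genome(config)
    truth = make_truth(config, genes, tiers, slots)
    frames: dict[str, pd.DataFrame] = {}
    rows = []
    for mark, condition, rep in samples:
        sid = sample_id(mark, condition, rep)
        frames[sid] = simulate_sample(layout, truth, mark, condition, config, rep)
        rows.append({"sample_id": sid, "mark": mark, "condition": condition, "rep": rep,
                     "n_fragments": len(frames[sid])})
    table = pd.DataFrame(rows)
    return SyntheticStudy(
        config=config, layout=layout, genes=genes, expression=expression,
        tiers=tiers, truth=truth, slots=slots, samples=frames, sample_table=table,
    )
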