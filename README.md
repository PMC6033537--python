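# chiprx

Spike-in-normalized (ChIP-Rx) comparative ChIP-seq analysis, built around
the question the H3.3K27M oncohistone poses: when a mutation causes a
*global* loss of a chromatin mark (H3K27me3), per-sample depth
normalization silently hides the loss — every library is resequenced to
the same depth, so the remaining signal is rescaled back up.  Adding a
fixed proportion of exogenous chromatin (fly or moth) before the
immunoprecipitation gives every sample an internal ruler: when the primary
mark collapses, spike-in reads claim a larger share of the fixed depth,
and the per-sample factor

&nbsp;&nbsp;&nbsp;&nbsp; α = C / N_spike  (C = 10⁶ by default)

applied to per-peak read counts restores cross-sample comparability.

The package implements the full comparative analysis around that idea:

* **Dual-genome partitioning** — aligned fragments on a combined
  primary + spike-in chromosome namespace are split by organism,
  deduplicated, and turned into per-sample `SpikeInFactors`.
* **Coverage & metagene profiles** — per-base fragment coverage, the
  RPK10M density unit (reads per kilobase per 10 million mapped), and
  expression-stratified TSS→TES profiles (10-kb flanks, 100 bins per
  segment, tertile expression tiers).
* **Peak-set algebra** — classification of peaks across a control and two
  condition clones (common / unique-to-condition / unique-to-control /
  unreplicated, replicate-overlap rule), strand-aware promoter windows,
  Venn region counts, and the baseline-occupancy ("tumor-initiating")
  set construction `(refA ∩ refB) ∪ (sample − refA ∪ refB)`.
* **Co-localization clustering** — binary peak × feature occupancy
  matrices and agglomerative clustering (Jaccard distance, average
  linkage) into co-localization classes such as poised-enhancer-like
  peaks (H3K4me1⁺, promoter⁻).
* **Differential retention statistics** — per-peak condition/control
  ratios of spike-normalized signal, most/least-reduced median splits,
  pooled-variance two-tailed Student's *t* tests between groups, and the
  fraction of peaks with increased signal.
* **A seeded synthetic-data generator** — a complete toy two-organism
  study (genes, expression tiers, planted enrichment domains, fixed-depth
  fragment libraries with spike-in) carrying the statistical structure the
  pipeline assumes, including the redistribution of the PRC2 writer to
  poised enhancers and locus-specific mark retention at promoters the
  mutant protein avoids.

## Worked example

Simulate the default study (10-Mb primary genome, 600 genes, 200 broad
H3K27me3 domains, 30% residual mark level in the mutant with a quarter of
domains retained, 2% spike-in, 100,000 fragments per sample) and run the
retention workflow:

```python
from chiprx import SimulationConfig, simulate_study, RunConfig, run_pipeline
from chiprx.io import write_dataset

study = simulate_study(SimulationConfig(seed=1))
write_dataset(study, "demo/ds")
report = run_pipeline(RunConfig("demo/ds", "demo/out"), "retention")
r = report["results"]
print(f"spike-in normalized median ratio : {r['median_spikein_ratio']:.3f}")
print(f"depth-normalized median ratio    : {r['median_depth_ratio']:.3f}")
print(f"peaks with increased H3K27me3    : {r['fraction_increased_pct']:.1f}%")
comp = r["comparisons"]["k27m_density_by_reduction_group"]
print(f"H3.3K27M density, most reduced   : {comp['groups']['most_reduced']['mean']:.0f}")
print(f"H3.3K27M density, least reduced  : {comp['groups']['least_reduced']['mean']:.0f}")
print(f"two-tailed Student's t p-value   : {comp['ttest']['p']:.2e}")
```

```
spike-in normalized median ratio : 0.304
depth-normalized median ratio    : 0.603
peaks with increased H3K27me3    : 9.5%
H3.3K27M density, most reduced   : 27770
H3.3K27M density, least reduced  : 16464
two-tailed Student's t p-value   : 5.40e-18
```

The spike-normalized median ratio recovers the planted 0.3 residual level
almost exactly, while depth normalization reports 0.60 — the global loss
is half-masked because most domains keep full signal only relative to a
shrunken library.  Peaks that retain H3K27me3 fall in the least-reduced
group, and the mutant histone's density there is significantly lower than
at the most-reduced peaks: the inverse relationship between H3.3K27M
occupancy and mark retention, reproduced on synthetic truth.

The same objects drive a command-line interface (`chiprx simulate`,
`split`, `normalize`, `coverage`, `metagene`, `callpeaks`, `classify`,
`annotate`, `cluster`, `differential`, `venn`, `initiating`, `run`); see
`chiprx --help`.

## Layout

```
src/chiprx/
  layout.py          combined two-organism genome namespace
  intervals.py       half-open interval overlap primitives
  partition.py       organism split, dedup, spike-in factors, peak counts
  coverage.py        coverage tracks, RPK10M, bedGraph export
  metagene.py        expression tiers and TSS->TES profiles
  peaks.py           enrichment caller, classification, promoters, Venn
  colocalization.py  binary annotation + Jaccard clustering + heatmap
  differential.py    ratios, splits, Student's t, fraction increased
  simulate.py        seeded synthetic two-organism study generator
  io.py              BED/TSV/YAML readers and writers, dataset directory
  pipeline.py        the retention and redistribution workflows
  cli.py             click command-line interface
docs/methods.md      model, assumptions, parameter choices, limitations
```
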