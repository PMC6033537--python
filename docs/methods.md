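# Methods

## The quantification problem

ChIP-seq read counts are compositional: a library sequenced to a fixed
depth reports only the *relative* distribution of immunoprecipitated
fragments.  A perturbation that reduces a histone mark everywhere — the
H3.3K27M oncohistone's dominant inhibition of PRC2 and the resulting
genome-wide H3K27me3 loss is the motivating case — leaves relative
profiles almost unchanged, so per-sample depth normalization reports
ratios near 1 where the true change is several-fold.  Adding exogenous
("spike-in") chromatin from a second organism at a fixed proportion of
the chromatin input breaks the degeneracy: the exogenous material
competes for the same antibody and the same sequencing depth, so its
read share grows exactly when the primary mark shrinks.

## Normalization model

Reads are aligned to a combined reference whose chromosome names carry an
organism prefix (`hs_chr1`, `dm_chr2L`).  After splitting fragments by
organism and removing coordinate-identical duplicates (key: chromosome,
start, end, strand — strand kept so opposite-strand fragments over one
span survive), each sample's factor is

    alpha = C / N_spike,  C = 1e6 (configurable)

i.e. reads-per-million-spike-in.  The normalized signal of a peak is
`(# primary fragments overlapping the peak by >= 1 bp) * alpha`.  All
coordinates are 0-based half-open and overlap means sharing at least one
base, everywhere in the package.  Doubling the spike-in count halves
alpha exactly; uniformly duplicating a library and deduplicating leaves
all signals unchanged.

Why this is correct in expectation: if a sample's fragments are drawn
from chromatin with primary IP-able weight `W_p` and constant spike
weight `W_s`, a fixed depth `D` yields `N_spike ≈ D·W_s/(W_s+W_p)` and a
peak count `≈ D·w_peak/(W_s+W_p)`, so `count · C/N_spike ≈ C·w_peak/W_s`
— the depth and the composition cancel, leaving a quantity proportional
to the peak's absolute chromatin weight.  Depth normalization
(`C/N_primary`) leaves a residual factor `W_p(condition)/W_p(control)`,
which is precisely the masking the spike-in removes.

## Density unit and metagene profiles

Densities are RPK10M: `count / ((width/1e3)·(total_mapped/1e7))` (reads
per kilobase per 10 million mapped fragments).  Metagene profiles cover a
10-kb upstream flank, the TSS→TES body, and a 10-kb downstream flank,
each in B = 100 bins.  Body bin boundaries are `round(L·i/B)` (half-open;
genes shorter than B bp are excluded, avoiding zero-width bins); flank
bins are fixed 100 bp and, when truncated by a chromosome edge,
contribute only their covered width (fully off-chromosome bins report 0).
Minus-strand genes are reversed so bin 0 is always 5′-most.  Expression
tiers are tertiles of the expression ranking (descending, ties broken by
gene id; group sizes differ by at most one with the extra gene in the
higher tier), and the tier profile is the unweighted per-gene mean.
Profiles use per-sample RPK10M by default; spike-in scaling can be
applied upstream by the caller.  No correction is attempted for the
TSS/TES enrichment that MNase digestion can impose on real data.

## Enrichment-domain caller (plumbing)

A deliberately simple sliding-window caller stands in for a production
broad-peak caller in synthetic end-to-end runs: 200-bp windows at 100-bp
steps, fragment-*start* counts (independent Poisson observables, unlike
correlated per-base pileup) tested against a Poisson upper tail at
p ≤ 1e-5, significant windows merged across gaps ≤ 500 bp.  The expected
count is the depth-scaled control window count with a genome-wide
control-rate floor — without the floor, windows where the sparse control
happens to be empty degenerate to the pseudocount (0.25) and background
windows with a handful of fragments become "significant".  An alternative
`background` scaling mode matches the control to the sample's *median*
window count instead of its total depth; it is the right choice for marks
whose fragments concentrate almost entirely inside domains (there total
depth scaling overstates the background several-fold and costs power).
The caller reproduces planted domains on synthetic data; it does not
model local lambda estimation, duplicate handling or q-values.

## Peak classification and set constructions

Across a control sample and two condition clones: condition peaks count
only when present in both clones (a clone-1 peak overlapping any clone-2
peak; reported with clone-1 coordinates).  Replicated peaks overlapping a
control peak are `common`, otherwise `unique_condition`; control peaks
overlapping neither clone are `unique_control`; clone peaks without a
replicate mate are `unreplicated` and excluded downstream.  The labels
must partition the universe, and the rule for a control peak that
overlaps a clone peak is not forced by the definitions above; here such a
peak is `common` (it belongs to a region occupied in both conditions).

Promoter windows are strand-aware around the TSS, default
−2000/+500 bp; a −2000/+1000 variant is a parameter change.  A gene is
peak-positive when any peak overlaps its window by ≥ 1 bp.  Venn counts
enumerate the exclusive regions of the inclusion–exclusion partition.
The baseline-occupancy ("tumor-initiating") construction is
`(refA ∩ refB) ∪ (sample − (refA ∪ refB))`: promoters marked in both
reference samples, plus those unique to the tumour sample relative to
both references.

## Co-localization clustering

Peak × feature occupancy is binary (≥ 1 bp overlap with any feature
interval).  Rows are clustered agglomeratively with Jaccard distance and
average linkage (all-zero row pairs have distance 0, so unannotated peaks
form their own natural cluster).  Two robustness measures are layered on
the plain "cut the tree at k" rule, both deterministic:

* **Canonical row order.**  Linkage tie-breaking depends on input order;
  rows are therefore clustered in pattern-lexicographic order and mapped
  back, making the assignment invariant (up to relabelling) under row
  permutation — identical patterns always share a cluster because their
  distance is 0.
* **Minimum cluster size.**  A plain `maxclust` cut lets a rare outlier
  row (several simultaneous bit flips) capture a whole cluster slot and
  force two real blocks to merge.  The cut is deepened until k clusters
  reach ≥ 1% of rows (at least 2); rows left in sub-threshold clusters
  are attached to the core cluster with the smallest mean Jaccard
  distance.

k defaults to 5; the workflow clips k to the number of distinct rows.
Heatmap rows are grouped by cluster (blocks ordered by size, then
smallest row id) and ordered within a cluster by row sum descending, ties
by row id, so the rendered black/white matrix is permutation-invariant.

## Differential statistics

Per-peak ratio: mean over condition samples of `signal/control`
(mean-of-ratios, not ratio-of-means; peaks with zero control signal are
excluded and reported).  The most/least-reduced split is a deterministic
median split (ascending by value then id; odd n puts the extra element in
the upper group).  Group comparisons use the pooled-variance two-tailed
Student's *t* (Welch optional); zero pooled variance with equal means
yields t = 0, p = 1, with unequal means the p = 0 underflow sentinel.  The
fraction-increased summary counts peaks strictly above threshold × 
reference (default 1.0) on spike-normalized signal.  No multiple-testing
correction is applied: the workflows perform single grouped tests, not
per-peak testing.

## Synthetic study design

The generator emits complete fixed-depth fragment libraries, so every
downstream stage runs exactly as it would on real post-alignment data.
Default conditions (all configurable through `SimulationConfig`):

| parameter | default | rationale |
|---|---|---|
| primary genome | 2 × 5 Mb | smallest size that holds 600 gene slots with clean geometry |
| spike genome | 1 × 1 Mb | spike reads need positions, not structure |
| genes | 600 in 16-kb slots, lengths log-normal (median 1.5 kb, clipped 0.6–4 kb) | three tiers of 200; slots keep genes, domains and enhancers disjoint by construction |
| expression | log-normal per tier, medians 50 / 5 / 0.5, σ = 0.5 | tier recovery by ranking is essentially noiseless |
| H3K27me3 domains | 200 × 10 kb at low-tier promoters, fold 50 | broad repressive domains; the fold puts ~90% of fragments in-domain, matching the read concentration of MNase ChIP for this mark and making depth-normalization masking visible |
| global reduction f | 0.3 | the mutant's residual mark level |
| retained fraction | 0.25 | the locus-specific retention phenomenon: retained ("strong PRC2") domains keep factor 1 and carry no mutant histone |
| Ezh2 | 2-kb domains (fold 20) at the PRC2 sites; in the mutant the reduced sites empty and poised enhancers gain Ezh2 | redistribution of the writer |
| H3K4me1 | 200 × 1-kb enhancers (fold 20), half flagged poised | poised enhancers carry Ezh2 + H3.3K27M in the mutant |
| H3.3K27M | mutant-only: high-tier gene bodies (fold 8), reduced PRC2 sites and poised enhancers (fold 6) | ties occupancy to transcription and creates the inverse relation with retention |
| depth / spike / fragment | 100,000 fragments, 2% spike, 150 bp | 2% sits in the 1–5% experimental range; 150 bp ≈ mononucleosome |

Per-base sampling weight is 1 in background and `max(fold·factor, 1)`
inside a domain, with the condition factor carrying the planted
reduction.  The spike chromatin weight is constant across conditions
(calibrated so the control sample's expected spike share equals the
configured fraction); a mutant sample with less primary signal therefore
yields more spike reads at the same fixed depth — the handle the
normalization uses, and exactly what fixed-depth resampling hides from
depth scaling.  Fragment starts are drawn by inverse-CDF over the
piecewise weights, so every statistic is exactly reproducible from the
seed, and child seeds are derived per sample (mark, condition,
replicate), making each library independent of which others are
simulated.

Uniform-reduction analyses (the spike-recovery and masking measurements)
set `retained_fraction = 0`, planting the same f in all 200 domains; the
default configuration with retention feeds the end-to-end workflows.

What the generator does **not** model: sequencing errors, mappability
and GC bias, copy-number variation, fragment-length variation, antibody
efficiency differences between samples, or any spatial correlation of
background reads.  Passing tests therefore demonstrate the correctness
and calibration of the analysis chain under its own model assumptions,
not robustness to those real-data artifacts.

## Numerical and degenerate-input choices

* Body-bin boundary rounding is `floor(x + 0.5)` (not banker's rounding)
  for platform-stable bins.
* Division-by-zero guards: zero spike reads, zero-width bins, empty
  tiers, empty peak universes and sub-2 groups raise; zero-depth samples
  in the caller warn and return an empty set.
* All reports are JSON with sorted keys and no timestamps or absolute
  paths in the results block, so reruns are byte-comparable.
* The workflow clips the cluster count to the number of distinct
  annotation rows rather than failing an otherwise-valid run.

## Problem sizes

Unit tests run on kilobase-scale toy genomes; the integration and
acceptance checks use the default study above (10-Mb genome, eleven
100k-fragment libraries) and a 1000 × 8 clustering problem, sizes at
which every statistical contrast of interest is already decisive.

## Known limitations

* The caller is plumbing: single-pass Poisson windows with one control
  scaling factor per chromosome set; no local lambda, no q-values.
* Replicated condition peaks are anchored on clone-1 coordinates; the
  anchor choice is arbitrary and recorded in the output.
* `fraction_increased` on ratios near 1 is sensitive to sampling noise
  around the threshold; it is a descriptive summary, not a test.
* The Jaccard/average-linkage choice and k = 5 are conventions; other
  distances or k values are parameter changes, not code changes.
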