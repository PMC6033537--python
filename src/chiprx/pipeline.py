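"""The two headline workflows over a dataset directory.

``retention``: spike-in normalization chain — split fragments by organism,
deduplicate, derive per-sample normalization factors, quantify the
H3K27me3 peak universe, form per-peak mutant/control ratios (spike-in and,
as the negative control, plain depth normalization), median-split into
most/least reduced, compare H3.3K27M density between the groups, compute
the fraction of increased peaks, and build promoter Venn counts plus the
presumed baseline ("tumor-initiating") promoter set from called peaks.

``redistribution``: enrichment-domain calling on Ezh2 in control and two
mutant clones, cross-condition peak classification, binary co-localization
annotation + clustering, and the poised-enhancer enrichment contrast
between mutant-unique and common peaks.

Both write TSV intermediates and a machine-readable ``report.json`` that
is byte-identical across reruns with the same dataset and config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import colocalization, differential, peaks as peak_ops
from .coverage import compute_coverage
from .io import Dataset, write_bed, write_factors_tsv
from .partition import (
    DEFAULT_SCALE_CONSTANT,
    compute_normalization_factor,
    deduplicate,
    normalize_peak_counts,
    spike_in_factors,
    split_by_organism,
)

log = logging.getLogger(__name__)

WORKFLOWS = ("retention", "redistribution")


@dataclass
class RunConfig:
    """Parameters of a pipeline run over a dataset directory."""

    dataset_dir: str
    output_dir: str
    scale_constant: float = DEFAULT_SCALE_CONSTANT
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    increase_threshold: float = 1.0
    # enrichment caller
    window_bp: int = 200
    step_bp: int = 100
    p_cutoff: float = 1e-5
    merge_gap: int = 500
    k27me3_control_scaling: str = "background"
    ezh2_control_scaling: str = "depth"
    # clustering
    k_clusters: int = 5
    make_figures: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class _Prepared:
    """Deduplicated primary fragments + spike factors for one sample."""

    sample_id: str
    primary: pd.DataFrame
    factors: object


def _prepare(ds: Dataset, sid: str, scale_constant: float) -> _Prepared:
    frags = deduplicate(ds.fragments(sid))
    factors = spike_in_factors(frags, ds.layout, sid, scale_constant, already_deduplicated=True)
    primary = split_by_organism(frags, ds.layout)[ds.layout.primary.name]
    return _Prepared(sid, primary, factors)


def _signal(prep: _Prepared, universe: pd.DataFrame, alpha: float) -> pd.Series:
    return normalize_peak_counts(universe, prep.primary, alpha)


def run_pipeline(config: RunConfig, workflow: str) -> dict:
    """Execute one workflow; returns the report dict (also written to disk)."""
    if workflow not in WORKFLOWS:
        raise ValueError(f"unknown workflow {workflow!r}; choose from {WORKFLOWS}")
    ds = Dataset(config.dataset_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if workflow == "retention":
        results = _retention(ds, config, out)
    else:
        results = _redistribution(ds, config, out)
    report = {
        "workflow": workflow,
        "dataset_seed": ds.manifest["seed"],
        "dataset_config_hash": ds.manifest["config_hash"],
        "run_config": config.to_dict(),
        "results": results,
    }
    with open(out / f"report_{workflow}.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# retention
# ---------------------------------------------------------------------------

def _retention(ds: Dataset, config: RunConfig, out: Path) -> dict:
    controls = ds.sample_ids(mark="H3K27me3", condition="control")
    clones = ds.sample_ids(mark="H3K27me3", condition="k27m")
    if not controls or not clones:
        raise ValueError("retention workflow requires H3K27me3 control and k27m samples")
    preps = {sid: _prepare(ds, sid, config.scale_constant) for sid in controls + clones}
    write_factors_tsv([p.factors for p in preps.values()], out / "spikein_factors.tsv")

    universe = ds.truth_peaks("H3K27me3", "control")
    ref = preps[controls[0]]

    spike_sig = {sid: _signal(preps[sid], universe, preps[sid].factors.alpha) for sid in preps}
    depth_sig = {
        sid: _signal(
            preps[sid], universe,
            compute_normalization_factor(preps[sid].factors.n_primary, config.scale_constant),
        )
        for sid in preps
    }

    cond_spike = pd.DataFrame({sid: spike_sig[sid] for sid in clones})
    cond_depth = pd.DataFrame({sid: depth_sig[sid] for sid in clones})
    ratios, excluded = differential.per_peak_ratio(cond_spike, spike_sig[ref.sample_id])
    ratios_depth, _ = differential.per_peak_ratio(cond_depth, depth_sig[ref.sample_id])

    groups = differential.median_split(ratios)
    width_kb = (universe.set_index("name")["end"] - universe.set_index("name")["start"]) / 1e3

    # H3.3K27M density at the peak universe (mutant-only mark)
    k27m_ids = ds.sample_ids(mark="H3.3K27M", condition="k27m")
    comparisons = {}
    if k27m_ids:
        k27m_prep = _prepare(ds, k27m_ids[0], config.scale_constant)
        k27m_density = _signal(k27m_prep, universe, k27m_prep.factors.alpha) / width_kb
        comparisons["k27m_density_by_reduction_group"] = differential.group_density_compare(
            groups, k27m_density
        )
    # control H3K27me3 density between the groups
    wt_density = spike_sig[ref.sample_id] / width_kb
    comparisons["wt_k27me3_density_by_reduction_group"] = differential.group_density_compare(
        groups, wt_density
    )

    frac_inc = differential.fraction_increased(
        cond_spike.mean(axis=1), spike_sig[ref.sample_id], config.increase_threshold
    )

    # per-peak table
    table = pd.DataFrame({"ratio_spikein": ratios, "ratio_depth": ratios_depth})
    for sid in preps:
        table[f"signal_{sid}"] = spike_sig[sid]
    table["group"] = "least_reduced"
    table.loc[table.index.isin(groups["most_reduced"]), "group"] = "most_reduced"
    table.rename_axis("peak").to_csv(out / "retention_peaks.tsv", sep="\t")

    # promoter-level sets from called peaks (control replicates act as the
    # two reference samples of the baseline-set construction)
    promoters = peak_ops.make_promoters(ds.genes, config.promoter_upstream, config.promoter_downstream)
    called: dict[str, pd.DataFrame] = {}
    inputs = {c: ds.sample_ids(mark="input", condition=c) for c in ("control", "k27m")}
    prom_sets: dict[str, set] = {}
    input_cov_cache: dict[str, object] = {}

    def input_cov_for(cond: str):
        ids = inputs[cond] or inputs["control"]
        if not ids:
            return None
        sid0 = ids[0]
        if sid0 not in input_cov_cache:
            prep = _prepare(ds, sid0, config.scale_constant)
            input_cov_cache[sid0] = compute_coverage(prep.primary, ds.layout)
        return input_cov_cache[sid0]

    for sid in controls + clones:
        cond = "control" if sid in controls else "k27m"
        input_cov = input_cov_for(cond)
        if input_cov is None:
            continue
        sample_cov = compute_coverage(preps[sid].primary, ds.layout)
        called[sid] = peak_ops.call_enrichment_domains(
            sample_cov, input_cov, config.window_bp, config.step_bp, config.p_cutoff,
            config.merge_gap, control_scaling=config.k27me3_control_scaling,
        )
        write_bed(called[sid], out / f"called_{sid}.bed")
        prom_sets[sid] = peak_ops.assign_promoters(called[sid], promoters)

    results: dict = {
        "n_peaks_universe": int(len(universe)),
        "n_excluded_zero_control": len(excluded),
        "median_spikein_ratio": float(ratios.median()),
        "median_depth_ratio": float(ratios_depth.median()),
        "fraction_increased_pct": float(frac_inc),
        "group_sizes": {k: len(v) for k, v in groups.items()},
        "comparisons": comparisons,
        "spikein_factors": {sid: preps[sid].factors.to_row() for sid in preps},
    }
    if len(prom_sets) >= 2:
        venn_input = {sid: prom_sets[sid] for sid in list(prom_sets)[:3]}
        venn = peak_ops.venn_counts(venn_input)
        results["venn_promoters"] = {"+".join(sorted(k)): v for k, v in venn.items()}
        if len(controls) >= 2 and clones and all(s in prom_sets for s in controls[:2] + clones[:1]):
            initiating = peak_ops.build_initiating_set(
                prom_sets[controls[0]], prom_sets[controls[1]], prom_sets[clones[0]]
            )
            results["initiating_set_size"] = len(initiating)
            with open(out / "initiating_promoters.txt", "w") as fh:
                fh.write("\n".join(sorted(initiating)) + "\n")
    return results


# ---------------------------------------------------------------------------
# redistribution
# ---------------------------------------------------------------------------

def _redistribution(ds: Dataset, config: RunConfig, out: Path) -> dict:
    ezh2_ctrl = ds.sample_ids(mark="Ezh2", condition="control")
    ezh2_k27m = ds.sample_ids(mark="Ezh2", condition="k27m")
    if not ezh2_ctrl or len(ezh2_k27m) < 2:
        raise ValueError("redistribution workflow requires one control and two k27m Ezh2 samples")
    inputs = {c: ds.sample_ids(mark="input", condition=c) for c in ("control", "k27m")}
    input_cov_cache: dict[str, object] = {}

    def call(sid: str, condition: str) -> pd.DataFrame:
        prep = _prepare(ds, sid, config.scale_constant)
        input_ids = inputs[condition] or inputs["control"]
        if not input_ids:
            raise ValueError("redistribution workflow requires input samples for calling")
        if input_ids[0] not in input_cov_cache:
            input_prep = _prepare(ds, input_ids[0], config.scale_constant)
            input_cov_cache[input_ids[0]] = compute_coverage(input_prep.primary, ds.layout)
        domains = peak_ops.call_enrichment_domains(
            compute_coverage(prep.primary, ds.layout),
            input_cov_cache[input_ids[0]],
            config.window_bp, config.step_bp, config.p_cutoff, config.merge_gap,
            control_scaling=config.ezh2_control_scaling,
        )
        domains["name"] = [f"{sid}_{n}" for n in domains["name"]]
        write_bed(domains, out / f"called_{sid}.bed")
        return domains

    control_peaks = call(ezh2_ctrl[0], "control")
    clone1_peaks = call(ezh2_k27m[0], "k27m")
    clone2_peaks = call(ezh2_k27m[1], "k27m")

    classified = peak_ops.classify_peaks(control_peaks, clone1_peaks, clone2_peaks)
    write_bed(classified.assign(name=classified["name"] + "|" + classified["label"]),
              out / "classified_peaks.bed")
    summary = peak_ops.classification_summary(classified)

    universe = classified.loc[classified["label"] != "unreplicated"].reset_index(drop=True)
    features = {
        "promoter": peak_ops.make_promoters(ds.genes, config.promoter_upstream, config.promoter_downstream),
        "H3K4me1": ds.truth_bed("enhancers"),
        "H3K27me3": ds.truth_peaks("H3K27me3", "control"),
        "H3.3K27M": ds.truth_peaks("H3.3K27M", "k27m"),
        "poised_enhancer": ds.truth_bed("poised_enhancers"),
    }
    matrix = colocalization.annotate_peaks(universe, features)
    k = min(config.k_clusters, len(np.unique(matrix.to_numpy(bool), axis=0)))
    assignment = colocalization.cluster_binary(matrix, k)
    matrix.assign(cluster=assignment, label=universe["label"].to_numpy()).to_csv(
        out / "annotation_matrix.tsv", sep="\t"
    )
    if config.make_figures:
        colocalization.render_heatmap(matrix, assignment, out / "colocalization_heatmap.png")

    # poised-enhancer enrichment: mutant-unique vs common peaks
    poised_hit = matrix["poised_enhancer"].astype(float)
    labels = pd.Series(universe["label"].to_numpy(), index=matrix.index)
    uniq = poised_hit[labels == "unique_condition"]
    comm = poised_hit[labels == "common"]
    results: dict = {
        "classification": {k_: int(v) for k_, v in summary.items()},
        "cluster_sizes": {int(k_): int(v) for k_, v in colocalization.cluster_sizes(assignment).items()},
        "n_clusters": int(k),
    }
    if len(uniq) >= 2 and len(comm) >= 2:
        test = differential.students_t(uniq.to_numpy(), comm.to_numpy())
        results["poised_enrichment"] = {
            "unique_condition_overlap_rate": float(uniq.mean()),
            "common_overlap_rate": float(comm.mean()),
            "ttest": test.to_dict(),
        }
    # H3.3K27M density contrast at common vs mutant-unique Ezh2 peaks
    k27m_ids = ds.sample_ids(mark="H3.3K27M", condition="k27m")
    if k27m_ids and len(uniq) >= 2 and len(comm) >= 2:
        k27m_prep = _prepare(ds, k27m_ids[0], config.scale_constant)
        named = universe.copy()
        named["name"] = matrix.index
        density = normalize_peak_counts(named, k27m_prep.primary, k27m_prep.factors.alpha)
        density = density / ((named.set_index("name")["end"] - named.set_index("name")["start"]) / 1e3)
        results["k27m_density_by_class"] = differential.group_density_compare(
            {"common": list(comm.index), "unique_condition": list(uniq.index)}, density
        )
    return results
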