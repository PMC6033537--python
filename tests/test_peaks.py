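"""Peak classification, promoter assignment, Venn algebra, and the caller."""

import numpy as np
import pandas as pd
import pytest

from chiprx.coverage import compute_coverage
from chiprx.layout import GenomeLayout, Organism
from chiprx.peaks import (
    assign_promoters,
    build_initiating_set,
    call_enrichment_domains,
    classification_summary,
    classify_peaks,
    make_promoters,
    venn_counts,
)

from conftest import brute_force_any, frame, random_intervals


def brute_force_classify(control, clone1, clone2):
    """Exhaustive pairwise-overlap re-derivation of the label rule."""

    def any_overlap(row, df):
        return any(
            row["chrom"] == c and row["start"] < e and s < row["end"]
            for c, s, e in zip(df["chrom"], df["start"], df["end"])
        )

    labels = []
    for _, r in clone1.iterrows():
        if any_overlap(r, clone2):
            labels.append(("clone1", r["name"], "common" if any_overlap(r, control) else "unique_condition"))
        else:
            labels.append(("clone1", r["name"], "unreplicated"))
    for _, r in clone2.iterrows():
        if not any_overlap(r, clone1):
            labels.append(("clone2", r["name"], "unreplicated"))
    for _, r in control.iterrows():
        hit = any_overlap(r, clone1) or any_overlap(r, clone2)
        labels.append(("control", r["name"], "common" if hit else "unique_control"))
    return {(o, n): l for o, n, l in labels}


class TestClassifyPeaks:
    def test_textbook_examples(self):
        control = frame([("c", 100, 200, "ctrl1"), ("c", 900, 950, "ctrl2")],
                        columns=("chrom", "start", "end", "name"))
        clone1 = frame([("c", 150, 250, "a1"), ("c", 500, 600, "a2"), ("c", 2000, 2100, "a3")],
                       columns=("chrom", "start", "end", "name"))
        clone2 = frame([("c", 180, 300, "b1"), ("c", 550, 650, "b2")],
                       columns=("chrom", "start", "end", "name"))
        out = classify_peaks(control, clone1, clone2)
        by = out.set_index(["origin", "name"])["label"]
        assert by[("clone1", "a1")] == "common"
        assert by[("clone1", "a2")] == "unique_condition"
        assert by[("control", "ctrl2")] == "unique_control"
        assert by[("clone1", "a3")] == "unreplicated"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        control = random_intervals(rng, 120, chroms=("c1", "c2"), prefix="ctrl")
        clone1 = random_intervals(rng, 120, chroms=("c1", "c2"), prefix="a")
        clone2 = random_intervals(rng, 120, chroms=("c1", "c2"), prefix="b")
        got = classify_peaks(control, clone1, clone2)
        want = brute_force_classify(control, clone1, clone2)
        got_map = {(o, n): l for o, n, l in zip(got["origin"], got["name"], got["label"])}
        assert got_map == want

    def test_partition_is_exhaustive_and_order_invariant(self):
        rng = np.random.default_rng(22)
        control = random_intervals(rng, 80, chroms=("c1",), prefix="ctrl")
        clone1 = random_intervals(rng, 80, chroms=("c1",), prefix="a")
        clone2 = random_intervals(rng, 80, chroms=("c1",), prefix="b")
        out = classify_peaks(control, clone1, clone2)
        assert out["label"].isin(["common", "unique_condition", "unique_control", "unreplicated"]).all()
        shuffled = classify_peaks(
            control.sample(frac=1, random_state=1),
            clone1.sample(frac=1, random_state=2),
            clone2.sample(frac=1, random_state=3),
        )
        assert classification_summary(out).equals(classification_summary(shuffled))

    def test_clone_swap_symmetry_on_matched_sets(self):
        # peaks on a coarse grid so cross-set overlaps are one-to-one
        rng = np.random.default_rng(23)
        def grid_peaks(prefix):
            anchors = rng.choice(np.arange(0, 100_000, 500), size=60, replace=False)
            return pd.DataFrame({"chrom": "c", "start": anchors, "end": anchors + 150,
                                 "name": [f"{prefix}{i}" for i in range(60)]})
        control, clone1, clone2 = grid_peaks("x"), grid_peaks("y"), grid_peaks("z")
        s12 = classification_summary(classify_peaks(control, clone1, clone2))
        s21 = classification_summary(classify_peaks(control, clone2, clone1))
        assert s12["common"] == s21["common"]
        assert s12["unique_condition"] == s21["unique_condition"]
        assert s12["unique_control"] == s21["unique_control"]


class TestPromoters:
    def test_window_geometry(self):
        genes = pd.DataFrame(
            {"gene_id": ["p", "m"], "chrom": "c", "start": [10_000, 10_000],
             "end": [12_000, 12_000], "strand": ["+", "-"]}
        )
        prom = make_promoters(genes, 2000, 500).set_index("gene_id")
        assert (prom.loc["p", "start"], prom.loc["p", "end"]) == (8000, 10_500)
        # '-' TSS at 11,999: mirrored window
        assert (prom.loc["m", "start"], prom.loc["m", "end"]) == (11_500, 14_000)
        assert (prom["end"] - prom["start"] == 2500).all()

    def test_assignment_in_and_bookended(self):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": "c", "start": [10_000],
                              "end": [12_000], "strand": ["+"]})
        prom = make_promoters(genes, 2000, 500)
        inside = frame([("c", 9000, 9100, "pk")], columns=("chrom", "start", "end", "name"))
        bookended = frame([("c", 10_500, 10_600, "pk")], columns=("chrom", "start", "end", "name"))
        assert assign_promoters(inside, prom) == {"g"}
        assert assign_promoters(bookended, prom) == set()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(31)
        genes = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(50)], "chrom": rng.choice(["c1", "c2"], 50),
             "start": rng.integers(5_000, 80_000, 50)}
        )
        genes["end"] = genes["start"] + rng.integers(500, 5_000, 50)
        genes["strand"] = rng.choice(["+", "-"], 50)
        prom = make_promoters(genes)
        peaks = random_intervals(rng, 200, chroms=("c1", "c2"), prefix="pk")
        want = set(prom.loc[brute_force_any(prom, peaks), "gene_id"])
        assert assign_promoters(peaks, prom) == want


class TestVennAndInitiatingSet:
    def test_three_set_example(self):
        counts = venn_counts({"A": {"a", "b"}, "B": {"b", "c"}, "C": {"b"}})
        assert counts[frozenset({"A", "B", "C"})] == 1
        assert counts[frozenset({"A"})] == 1
        assert counts[frozenset({"B"})] == 1
        assert sum(counts.values()) == 3

    def test_disjoint_sets(self):
        counts = venn_counts({"A": {1}, "B": {2}})
        assert counts[frozenset({"A", "B"})] == 0

    def test_inclusion_exclusion_identity_random(self):
        rng = np.random.default_rng(41)
        sets = {n: set(rng.integers(0, 300, size=100).tolist()) for n in "ABC"}
        counts = venn_counts(sets)
        assert sum(counts.values()) == len(sets["A"] | sets["B"] | sets["C"])
        # every region count agrees with direct set algebra
        for region, c in counts.items():
            inside = set.intersection(*(sets[n] for n in region))
            outside = set.union(*(sets[n] for n in sets if n not in region), set())
            assert c == len(inside - outside)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            venn_counts([("A", {1}), ("A", {2})])

    def test_initiating_set_examples(self):
        assert build_initiating_set({"P1", "P2", "P3"}, {"P2", "P3", "P4"}, {"P3", "P5"}) == {"P2", "P3", "P5"}
        assert build_initiating_set({"a", "b"}, {"b"}, {"b"}) == {"b"}
        assert build_initiating_set(set(), set(), {"x", "y"}) == {"x", "y"}


@pytest.fixture
def small_layout():
    return GenomeLayout(
        [Organism("m", "primary", "p_", {"chr1": 1_000_000}),
         Organism("f", "spikein", "s_", {"chrX": 10_000})]
    )


def _uniform_frags(rng, n, chrom="p_chr1", L=1_000_000, frag=150):
    starts = rng.integers(0, L - frag, size=n)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + frag, "strand": "+"})


class TestEnrichmentCaller:
    def test_null_sample_identical_to_control(self, small_layout):
        rng = np.random.default_rng(51)
        frags = _uniform_frags(rng, 20_000)
        cov = compute_coverage(frags, small_layout)
        domains = call_enrichment_domains(cov, cov)
        assert len(domains) == 0

    def test_empty_sample_warns_and_returns_empty(self, small_layout):
        empty = compute_coverage(_uniform_frags(np.random.default_rng(0), 0), small_layout)
        ctrl = compute_coverage(_uniform_frags(np.random.default_rng(1), 1000), small_layout)
        assert len(call_enrichment_domains(empty, ctrl)) == 0

    def test_null_simulations_rarely_call_anything(self, small_layout):
        n_called = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            sample = compute_coverage(_uniform_frags(rng, 20_000), small_layout)
            ctrl = compute_coverage(_uniform_frags(rng, 20_000), small_layout)
            n_called += len(call_enrichment_domains(sample, ctrl)) > 0
        assert n_called <= 2

    def test_planted_domain_recovered(self, small_layout):
        rng = np.random.default_rng(61)
        dom_start, dom_end = 400_000, 402_000
        n_bg = 20_000
        bg = _uniform_frags(rng, n_bg)
        # 10x background inside the planted 2-kb domain
        lam_bg_per_bp = n_bg / 1_000_000
        n_dom = int(10 * lam_bg_per_bp * (dom_end - dom_start))
        ds = rng.integers(dom_start, dom_end - 150, size=n_dom)
        dom = pd.DataFrame({"chrom": "p_chr1", "start": ds, "end": ds + 150, "strand": "+"})
        sample = compute_coverage(pd.concat([bg, dom], ignore_index=True), small_layout)
        ctrl = compute_coverage(_uniform_frags(rng, n_bg), small_layout)
        domains = call_enrichment_domains(sample, ctrl)
        assert len(domains) == 1
        got = domains.iloc[0]
        covered = min(got["end"], dom_end) - max(got["start"], dom_start)
        assert covered >= 0.9 * (dom_end - dom_start)
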