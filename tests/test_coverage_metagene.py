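"""Coverage tracks, RPK10M and metagene profiles against per-base oracles."""

import numpy as np
import pandas as pd
import pytest

from chiprx.coverage import CoverageTrack, compute_coverage, rpk10m
from chiprx.metagene import gene_profile, metagene_profile, stratify_genes, tss_positions

from conftest import frame


def brute_force_gene_profile(cov, chrom_len, start, end, strand, total, B=10, flank=1000):
    """Independent per-base re-binning of a per-base coverage array."""
    w = flank // B
    L = end - start

    def val(lo, hi):
        lo_c, hi_c = max(lo, 0), min(hi, chrom_len)
        if hi_c <= lo_c:
            return 0.0
        s = float(np.sum(cov[lo_c:hi_c]))
        width = hi_c - lo_c
        return s / ((width / 1e3) * (total / 1e7))

    bounds = [int(np.floor(L * i / B + 0.5)) for i in range(B + 1)]
    body = [val(start + bounds[i], start + bounds[i + 1]) for i in range(B)]
    up = [val(start - flank + j * w, start - flank + (j + 1) * w) for j in range(B)]
    down = [val(end + j * w, end + (j + 1) * w) for j in range(B)]
    if strand == "+":
        return np.array(up + body + down)
    up_m = [val(end + (B - 1 - j) * w, end + (B - j) * w) for j in range(B)]
    down_m = [val(start - (j + 1) * w, start - j * w) for j in range(B)]
    return np.array(up_m + body[::-1] + down_m)


def make_track(cov_by_chrom, total=None):
    data = {c: np.asarray(a, dtype=np.int32) for c, a in cov_by_chrom.items()}
    total = total if total is not None else 100
    return CoverageTrack(data=data, start_positions={c: np.array([], dtype=np.int64) for c in data},
                        total_mapped=total)


class TestComputeCoverage:
    def test_single_fragment(self, layout):
        frags = frame([("mm_chr1", 0, 10, "f", 0, "+")])
        track = compute_coverage(frags, layout)
        assert track.data["mm_chr1"][:10].sum() == 10
        assert track.data["mm_chr1"][10:].sum() == 0
        assert track.total_mapped == 1

    def test_overlapping_fragments_stack(self, layout):
        frags = frame([("mm_chr1", 0, 10, "a", 0, "+"), ("mm_chr1", 5, 15, "b", 0, "+")])
        track = compute_coverage(frags, layout)
        assert (track.data["mm_chr1"][5:10] == 2).all()
        assert (track.data["mm_chr1"][0:5] == 1).all()

    def test_total_coverage_equals_total_fragment_length(self, layout):
        rng = np.random.default_rng(2)
        starts = rng.integers(0, 90_000, size=100)
        lengths = rng.integers(1, 300, size=100)
        frags = pd.DataFrame({"chrom": "mm_chr1", "start": starts, "end": starts + lengths,
                              "strand": "+"})
        track = compute_coverage(frags, layout)
        assert track.data["mm_chr1"].sum() == lengths.sum()

    def test_out_of_bounds_fragment_is_an_error(self, layout):
        frags = frame([("mm_chr2", 49_990, 50_020, "f", 0, "+")])
        with pytest.raises(ValueError, match="outside chromosome bounds"):
            compute_coverage(frags, layout)


class TestRpk10m:
    @pytest.mark.parametrize(
        "count,width,total,expected",
        [(10, 1000, 10_000_000, 10.0), (0, 500, 1_000, 0.0), (25, 500, 5_000_000, 100.0)],
    )
    def test_definition(self, count, width, total, expected):
        assert rpk10m(count, width, total) == pytest.approx(expected)

    @pytest.mark.parametrize("width,total", [(0, 100), (100, 0), (-5, 100)])
    def test_invalid_inputs(self, width, total):
        with pytest.raises(ValueError):
            rpk10m(1, width, total)


class TestStratifyGenes:
    def _genes(self, ids):
        return pd.DataFrame(
            {"gene_id": ids, "chrom": "mm_chr1", "start": 0, "end": 100, "strand": "+"}
        ).assign(start=lambda d: np.arange(len(d)) * 1000, end=lambda d: np.arange(len(d)) * 1000 + 100)

    def test_even_split(self):
        ids = [f"g{i}" for i in range(9)]
        genes = self._genes(ids)
        expr = pd.Series(np.arange(9, 0, -1, dtype=float), index=ids)
        tiers = stratify_genes(genes, expr)
        assert (tiers.value_counts() == 3).all()
        assert set(tiers[ids[:3]]) == {"high"}

    def test_extra_gene_goes_to_high(self):
        ids = [f"g{i}" for i in range(10)]
        expr = pd.Series(np.arange(10, 0, -1, dtype=float), index=ids)
        tiers = stratify_genes(self._genes(ids), expr)
        counts = tiers.value_counts()
        assert counts["high"] == 4 and counts["medium"] == 3 and counts["low"] == 3

    def test_all_equal_expression_is_deterministic(self):
        ids = [f"g{i}" for i in range(7)]
        expr = pd.Series(1.0, index=ids)
        t1 = stratify_genes(self._genes(ids), expr)
        t2 = stratify_genes(self._genes(ids), expr)
        pd.testing.assert_series_equal(t1, t2)
        # ties resolved by gene_id order: g0..g2 high (sizes 3/2/2)
        assert list(t1[["g0", "g1", "g2"]]) == ["high"] * 3

    def test_missing_expression_is_an_error(self):
        ids = ["a", "b", "c"]
        expr = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(KeyError, match="c"):
            stratify_genes(self._genes(ids), expr)

    def test_tss_by_strand(self):
        genes = pd.DataFrame(
            {"gene_id": ["p", "m"], "chrom": "c", "start": [100, 100], "end": [200, 200],
             "strand": ["+", "-"]}
        )
        tss = tss_positions(genes)
        assert tss["p"] == 100 and tss["m"] == 199


class TestMetagene:
    B = 10
    FLANK = 1000

    def test_flat_coverage_gives_flat_profile(self, layout):
        chrom_len = 100_000
        track = make_track({"mm_chr1": np.full(chrom_len, 7)}, total=1000)
        genes = pd.DataFrame(
            {"gene_id": ["a", "b"], "chrom": "mm_chr1", "start": [20_000, 50_000],
             "end": [23_000, 51_237], "strand": ["+", "-"]}
        )
        tiers = pd.Series({"a": "high", "b": "high"})
        prof = metagene_profile(track, genes, tiers, self.B, self.FLANK)
        vals = prof.values.loc["high"].to_numpy()
        assert np.abs(vals / vals[0] - 1).max() < 1e-9

    def test_gene_of_length_n_bins_has_unit_width_bins(self):
        track = make_track({"c": np.arange(5000, dtype=np.int32)}, total=10)
        vec = gene_profile(track, "c", 2000, 2010, "+", n_bins=10, flank_bp=100)
        body = vec[10:20]
        expected = [rpk10m(2000 + i, 1, 10) for i in range(10)]
        np.testing.assert_allclose(body, expected)

    def test_matches_per_base_oracle_on_random_genes(self):
        rng = np.random.default_rng(9)
        chrom_len = 30_000
        cov = rng.integers(0, 20, size=chrom_len).astype(np.int32)
        track = make_track({"c": cov}, total=5000)
        for _ in range(10):
            start = int(rng.integers(500, 20_000))
            length = int(rng.integers(self.B, 4000))
            strand = str(rng.choice(["+", "-"]))
            got = gene_profile(track, "c", start, start + length, strand, self.B, self.FLANK)
            want = brute_force_gene_profile(cov, chrom_len, start, start + length, strand,
                                            5000, self.B, self.FLANK)
            np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_minus_strand_is_mirror_of_plus(self):
        rng = np.random.default_rng(4)
        cov = rng.integers(0, 10, size=20_000).astype(np.int32)
        track = make_track({"c": cov}, total=100)
        mirrored = make_track({"c": cov[::-1].copy()}, total=100)
        start, end = 5_000, 7_000
        plus = gene_profile(track, "c", start, end, "+", self.B, self.FLANK)
        minus = gene_profile(mirrored, "c", 20_000 - end, 20_000 - start, "-", self.B, self.FLANK)
        np.testing.assert_allclose(plus, minus, rtol=1e-12)

    def test_scaling_coverage_scales_profile(self):
        rng = np.random.default_rng(6)
        cov = rng.integers(0, 10, size=10_000).astype(np.int32)
        t1 = make_track({"c": cov}, total=77)
        t3 = CoverageTrack(data={"c": cov * 3}, start_positions={"c": np.array([], dtype=np.int64)},
                           total_mapped=77)
        p1 = gene_profile(t1, "c", 3000, 4000, "+", self.B, self.FLANK)
        p3 = gene_profile(t3, "c", 3000, 4000, "+", self.B, self.FLANK)
        np.testing.assert_allclose(p3, 3 * p1, rtol=1e-12)

    def test_short_genes_excluded_and_empty_tier_is_error(self):
        track = make_track({"c": np.ones(1000, dtype=np.int32)}, total=10)
        genes = pd.DataFrame(
            {"gene_id": ["tiny"], "chrom": "c", "start": [100], "end": [105], "strand": ["+"]}
        )
        tiers = pd.Series({"tiny": "low"})
        with pytest.raises(ValueError, match="low"):
            metagene_profile(track, genes, tiers, n_bins=10, flank_bp=100)
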