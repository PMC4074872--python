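"""FST, window scan, XP-CLR score and EDR/EDS calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecodiff import diff_scan, genotyping, simulate
from ecodiff.diff_scan import (
    call_top_regions,
    fst_per_site,
    identify_eds,
    intersect_to_edrs,
    top_quantile_threshold,
    window_scan,
    xpclr_scan,
)
from ecodiff.genotyping import PopulationFrequencies
from ecodiff.intervals import Region


class TestFstPerSite:
    @pytest.mark.parametrize(
        "p1, p2, expected",
        [
            (0.3, 0.3, 0.0),
            (0.0, 1.0, 1.0),
            (0.2, 0.8, 0.36),  # (0.5 - 0.32) / 0.5
            (0.0, 0.0, 0.0),  # monomorphic
            (1.0, 1.0, 0.0),
        ],
    )
    def test_values(self, p1, p2, expected):
        assert fst_per_site(p1, 10, p2, 10) == pytest.approx(expected)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_range_and_symmetry(self, p1, p2):
        f = fst_per_site(p1, 10, p2, 10)
        assert -1e-12 <= f <= 1 + 1e-12
        assert f == pytest.approx(fst_per_site(p2, 10, p1, 10))
        if p1 == p2:
            assert f == pytest.approx(0.0)

    def test_zero_iff_equal_for_polymorphic(self):
        assert fst_per_site(0.4, 10, 0.41, 10) > 0

    def test_corrected_variant_shrinks_estimate(self):
        raw = fst_per_site(0.2, 20, 0.5, 20)
        corr = fst_per_site(0.2, 20, 0.5, 20, corrected=True)
        assert corr < raw


class TestWindowScan:
    def make_sites(self, pos, values, chrom="chr1"):
        return pd.DataFrame({"chrom": chrom, "pos": pos, "value": values})

    def test_single_snp_window(self):
        out = window_scan(self.make_sites([5_000], [0.7]))
        assert (out["value"] == 0.7).all()
        assert (out["n_snps"] == 1).all()

    def test_mean_of_two(self):
        out = window_scan(self.make_sites([1_000, 2_000], [0.2, 0.4]))
        first = out.iloc[0]
        assert first["value"] == pytest.approx(0.3)
        assert first["start"] == 1 and first["end"] == 20_000

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            window_scan(self.make_sites([2_000, 1_000], [0.1, 0.2]))

    def test_matches_naive_double_loop_oracle(self):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(200_000, 500, replace=False)) + 1
        values = rng.random(500)
        sites = self.make_sites(pos, values)
        out = window_scan(sites, window=20_000, step=2_000)
        # brute force re-scan
        expected = {}
        start = 1
        while start <= pos.max():
            inside = (pos >= start) & (pos <= start + 20_000 - 1)
            if inside.any():
                expected[start] = (values[inside].mean(), int(inside.sum()))
            start += 2_000
        got = {int(r.start): (r.value, int(r.n_snps)) for r in out.itertuples()}
        assert set(got) == set(expected)
        for s in expected:
            assert got[s][0] == pytest.approx(expected[s][0])
            assert got[s][1] == expected[s][1]

    def test_invariant_to_chunked_computation(self):
        rng = np.random.default_rng(10)
        pos = np.sort(rng.choice(100_000, 300, replace=False)) + 1
        sites = self.make_sites(pos, rng.random(300))
        full = window_scan(sites)
        again = window_scan(sites.iloc[np.arange(300)])
        pd.testing.assert_frame_equal(full, again)


def make_freqs(p1, p2, pos=None, chrom="chr1", n=30):
    k = len(p1)
    pos = np.arange(1, k + 1) * 1_000 if pos is None else np.asarray(pos)
    sites = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"})
    return PopulationFrequencies(
        sites=sites,
        p1=np.asarray(p1, float), n1=np.full(k, n),
        p2=np.asarray(p2, float), n2=np.full(k, n),
        mask1=np.zeros(k, bool), mask2=np.zeros(k, bool),
    )


class TestXpclr:
    def test_null_score_zero_when_no_intensity(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.2, 0.8, 200)
        freqs = make_freqs(p, p)
        # forcing the intensity scale to ~0 collapses the sweep model onto the null
        out = xpclr_scan(freqs, s_grid=np.array([1e-12]))
        assert (out["score"] <= 1e-6).all()

    def test_scores_nonnegative_and_grid_spacing(self):
        rng = np.random.default_rng(2)
        p1 = rng.uniform(0.1, 0.9, 400)
        p2 = np.clip(p1 + rng.normal(0, 0.1, 400), 0, 1)
        freqs = make_freqs(p1, p2, pos=np.sort(rng.choice(400_000, 400, replace=False)) + 1)
        out = xpclr_scan(freqs)
        assert (out["score"] >= 0).all()
        spacing = np.diff(np.sort(out["pos"].unique()))
        assert (spacing % 2_000 == 0).all()

    def test_sparse_windows_skipped(self):
        freqs = make_freqs([0.5], [0.5], pos=[10_000])
        out = xpclr_scan(freqs)
        assert len(out) == 0

    def test_planted_sweep_scores_highest(self):
        cfg = simulate.SimConfig(
            seed=8, n_chrom=1, chrom_length=2_000_000, n_snps=4_000,
            sweep_loci=(simulate.SweepLocus("chr1", 1_000_000, 50_000),),
        )
        freqs_df, truth = simulate.simulate_frequencies(cfg)
        m, _, _ = simulate.simulate_genotype_matrix(freqs_df, cfg, emit_records=False)
        pf = genotyping.population_allele_frequencies(m)
        out = xpclr_scan(pf)
        top = out.nlargest(10, "score")
        hits = (top["pos"] - 1_000_000).abs() < 50_000
        assert hits.mean() > 0.5


class TestTopRegions:
    def test_threshold_keeps_exactly_top_fraction(self):
        rng = np.random.default_rng(3)
        values = rng.permutation(1_000).astype(float)
        thr = top_quantile_threshold(values, 0.005)
        assert (values >= thr).sum() == 5
        assert thr == np.sort(values)[-5]

    def test_ties_at_threshold_included(self):
        values = np.array([1.0] * 995 + [5.0] * 5)
        wins = pd.DataFrame(
            {"chrom": "c", "start": np.arange(1_000) * 2_000 + 1,
             "end": np.arange(1_000) * 2_000 + 20_000, "value": values, "n_snps": 1}
        )
        regions = call_top_regions(wins, quantile=0.005)
        # the 5 tied top windows are adjacent -> merged into one region
        total = sum(r.length for r in regions)
        assert total == 4 * 2_000 + 20_000

    def test_all_equal_values_calls_everything(self):
        wins = pd.DataFrame(
            {"chrom": "c", "start": [1, 2_001, 4_001], "end": [20_000, 22_000, 24_000],
             "value": [1.0, 1.0, 1.0], "n_snps": 1}
        )
        with pytest.warns(UserWarning):
            regions = call_top_regions(wins, quantile=0.005)
        assert sum(r.length for r in regions) == 24_000

    def test_consecutive_windows_merge(self):
        wins = pd.DataFrame(
            {"chrom": "c",
             "start": [1, 2_001, 4_001] + list(100_001 + 2_000 * np.arange(600)),
             "end": [20_000, 22_000, 24_000] + list(120_000 + 2_000 * np.arange(600)),
             "value": [9.0, 9.0, 9.0] + [0.0] * 600, "n_snps": 1}
        )
        regions = call_top_regions(wins, quantile=0.005)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 24_000)


class TestEdrsAndEds:
    def test_intersection_examples(self):
        a = [Region("c", 99, 200, source={"fst"})]
        b = [Region("c", 149, 300, source={"xpclr"})]
        edrs = intersect_to_edrs(a, b)
        assert [(r.start, r.end) for r in edrs] == [(149, 200)]
        assert edrs[0].source == {"fst", "xpclr"}
        assert intersect_to_edrs(a, [Region("c", 500, 600)]) == []

    def test_eds_rules(self):
        freqs = make_freqs(
            p1=[0.9, 0.85, 0.9, 0.9],
            p2=[0.2, 0.25, 0.3, 0.0],
            pos=[100, 200, 5_000, 10_000],
        )
        edrs = [Region("chr1", 0, 1_000)]
        eds = identify_eds(freqs, edrs, min_diff=0.6)
        # site 1: diff 0.7 inside EDR -> EDS; site 2: diff exactly 0.6 -> no;
        # sites 3/4 outside the EDR despite large diffs -> no
        assert list(eds["pos"]) == [100]
        assert eds["diff"].iloc[0] == pytest.approx(0.7)

    def test_masked_sites_excluded_from_eds(self):
        freqs = make_freqs([0.9], [0.1], pos=[100])
        freqs.mask2[0] = True
        assert len(identify_eds(freqs, [Region("chr1", 0, 1_000)])) == 0

    def test_eds_count_matches_brute_force(self, small_dataset):
        freqs_df, matrix, _, _ = small_dataset
        pf = genotyping.population_allele_frequencies(matrix, min_called=5)
        edrs = [Region("chr1", 0, 250_000), Region("chr2", 100_000, 400_000)]
        eds = identify_eds(pf, edrs)
        count = 0
        for i in range(len(pf.sites)):
            if pf.mask1[i] or pf.mask2[i]:
                continue
            c, p = pf.sites["chrom"].iloc[i], pf.sites["pos"].iloc[i] - 1
            inside = any(r.chrom == c and r.start <= p < r.end for r in edrs)
            if inside and abs(pf.p1[i] - pf.p2[i]) > 0.6:
                count += 1
        assert len(eds) == count
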