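"""SFS background, CLR sweep scan, sweep-region calling and gene assignment."""

import numpy as np
import pandas as pd
import pytest

from ecodiff import simulate, sweep_scan
from ecodiff.sweep_scan import (
    SweepAssignment,
    assign_edg_population,
    background_sfs,
    call_sweep_regions,
    clr_scan,
)


class TestBackgroundSfs:
    def test_single_frequency_occupies_one_bin(self):
        sfs = background_sfs(np.full(500, 0.5))
        assert sfs.occupied_bins == 1 or (sfs.proportions > 1e-3).sum() == 1

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(0)
        sfs = background_sfs(rng.uniform(0.01, 0.99, 1_000))
        assert sfs.proportions.sum() == pytest.approx(1.0)

    def test_uniform_spectrum_is_flat(self):
        rng = np.random.default_rng(1)
        maf = rng.uniform(0.0001, 0.4999, 50_000)
        sfs = background_sfs(maf, n_bins=10)
        assert np.allclose(sfs.proportions, 0.1, atol=0.01)

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            background_sfs(np.full(50, 0.3))

    def test_folding(self):
        sfs = background_sfs(np.concatenate([np.full(200, 0.9), np.full(200, 0.1)]))
        assert sfs.bin_of(np.array([0.9])) == sfs.bin_of(np.array([0.1]))


class TestClrScan:
    def make_freqs(self, p, pos=None, chrom="chr1"):
        pos = np.arange(1, len(p) + 1) * 500 if pos is None else pos
        return pd.DataFrame({"chrom": chrom, "pos": pos, "p": p})

    def test_null_nesting_small_alpha_gives_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.05, 0.95, 300)
        sfs = background_sfs(p)
        # alpha -> 0 means every lineage escapes: sweep model == background
        out = clr_scan(self.make_freqs(p), sfs, alpha_grid=np.array([1e-12]))
        assert (out["score"] <= 1e-6).all()

    def test_scores_nonnegative(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.05, 0.95, 500)
        sfs = background_sfs(p)
        out = clr_scan(self.make_freqs(p), sfs)
        assert (out["score"] >= 0).all()

    def test_degenerate_background_refused(self):
        sfs = background_sfs(np.full(200, 0.5))
        if sfs.occupied_bins < 2:
            with pytest.raises(ValueError):
                clr_scan(self.make_freqs(np.full(200, 0.5)), sfs)

    def test_top_quantile_fraction_by_construction(self):
        """On a neutral population-model background the empirical top-5%
        threshold calls exactly 5% of grid points (no sweep planted)."""
        cfg = simulate.SimConfig(seed=21, n_chrom=1, chrom_length=1_000_000, n_snps=3_000)
        _, truth = simulate.simulate_frequencies(cfg)
        sfs = background_sfs(truth.p1)
        out = clr_scan(self.make_freqs(truth.p1, pos=truth.sites["pos"].to_numpy()), sfs)
        thr = sweep_scan.top_quantile_threshold(out["score"].to_numpy(), 0.05)
        frac = (out["score"] >= thr).mean()
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_uniform_spectrum_background_scores_zero(self):
        """With a flat spectrum the sweep model never beats the background:
        every score sits at the likelihood-ratio floor of zero."""
        rng = np.random.default_rng(4)
        p = rng.uniform(0.05, 0.95, 2_000)
        pos = np.sort(rng.choice(1_000_000, 2_000, replace=False)) + 1
        out = clr_scan(self.make_freqs(p, pos=pos), background_sfs(p))
        assert (out["score"] == 0).all()

    def test_planted_sweep_peaks_at_locus(self):
        cfg = simulate.SimConfig(
            seed=9, n_chrom=1, chrom_length=2_000_000, n_snps=4_000,
            sweep_loci=(simulate.SweepLocus("chr1", 1_000_000, 50_000, sfs_skew=4.0),),
        )
        _, truth = simulate.simulate_frequencies(cfg)
        freqs = self.make_freqs(truth.p1, pos=truth.sites["pos"].to_numpy())
        sfs = background_sfs(truth.p1)
        out = clr_scan(freqs, sfs)
        top = out.nlargest(20, "score")
        assert ((top["pos"] - 1_000_000).abs() < 60_000).mean() >= 0.5


class TestCallSweepRegions:
    def make_scores(self, sig_pos, chrom="chr1", n=2_000, grid=1_000):
        pos = np.arange(1, n + 1) * grid
        score = np.zeros(n)
        for p in sig_pos:
            score[pos == p] = 100.0
        return pd.DataFrame({"chrom": chrom, "pos": pos, "score": score, "n_snps": 5})

    def test_gene_flank_boundaries(self):
        scores = self.make_scores([100_000])
        genes = pd.DataFrame(
            {
                "chrom": "chr1",
                # gene end 9,999 / 10,001 bp upstream of the point (0-based 99,999)
                "start": [80_000, 80_000, 99_000, 120_000],
                "end": [90_000, 89_998, 101_000, 121_000],
                "gene_id": ["g_at_9999", "g_at_10001", "g_inside", "g_far"],
            }
        )
        _, selected = call_sweep_regions(scores, genes=genes, quantile=0.0005)
        assert selected == {"g_at_9999", "g_inside"}

    def test_no_significant_points_empty(self):
        scores = pd.DataFrame(columns=["chrom", "pos", "score", "n_snps"])
        regions, genes = call_sweep_regions(scores)
        assert regions == [] and genes == set()

    def test_adjacent_points_merge_within_two_steps(self):
        scores = self.make_scores([100_000, 102_000, 110_000])
        regions, _ = call_sweep_regions(scores, quantile=0.0015)
        assert len(regions) == 2

    def test_matches_all_pairs_distance_oracle(self):
        rng = np.random.default_rng(5)
        sig = np.sort(rng.choice(np.arange(1, 1_000) * 1_000, 8, replace=False))
        scores = self.make_scores(sig, n=1_000)
        starts = rng.choice(900_000, 60, replace=False)
        genes = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 3_000,
             "gene_id": [f"g{i}" for i in range(60)]}
        )
        _, selected = call_sweep_regions(scores, genes=genes, quantile=8 / 1_000)
        want = set()
        for g in genes.itertuples():
            for p in sig:
                p0 = p - 1
                if g.start <= p0 < g.end:
                    d = 0
                elif p0 < g.start:
                    d = g.start - p0
                else:
                    d = p0 - (g.end - 1)
                if d <= 10_000:
                    want.add(g.gene_id)
        assert selected == want


class TestAssignment:
    def test_labels(self):
        out = assign_edg_population(
            ["a", "b", "c", "d"], upland_selected={"a", "c"}, irrigated_selected={"b", "c"}
        )
        labels = {x.gene_id: x.label for x in out}
        assert labels == {
            "a": "upland_only", "b": "irrigated_only", "c": "both", "d": "unassigned"
        }

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(200)]
        up = set(rng.choice(genes, 80, replace=False))
        ir = set(rng.choice(genes, 50, replace=False))
        out = assign_edg_population(genes, up, ir)
        assert len(out) == 200
        counts = {lbl: sum(1 for x in out if x.label == lbl) for lbl in
                  ("upland_only", "irrigated_only", "both", "unassigned")}
        assert counts["both"] == len(up & ir)
        assert counts["upland_only"] == len(up - ir)
        assert counts["irrigated_only"] == len(ir - up)
        assert sum(counts.values()) == 200

    def test_single_population_sweeps_label_correctly(self):
        """Sweeps planted only in pop1 produce mostly pop1-only labels."""
        cfg = simulate.SimConfig(
            seed=10, n_chrom=2, chrom_length=2_000_000, n_snps=8_000,
            sweep_loci=(
                simulate.SweepLocus("chr1", 1_000_000, 50_000, swept_pop="pop1"),
                simulate.SweepLocus("chr2", 1_000_000, 50_000, swept_pop="pop1"),
            ),
        )
        _, truth = simulate.simulate_frequencies(cfg)
        genes = pd.DataFrame(
            {
                "chrom": ["chr1", "chr2", "chr1"],
                "start": [990_000, 990_000, 200_000],
                "end": [1_010_000, 1_010_000, 210_000],
                "gene_id": ["swept1", "swept2", "neutral"],
            }
        )
        selected = {}
        for tag, p in (("pop1", truth.p1), ("pop2", truth.p2)):
            freqs = pd.DataFrame(
                {"chrom": truth.sites["chrom"], "pos": truth.sites["pos"], "p": p}
            )
            sfs = background_sfs(p)
            scores = clr_scan(freqs, sfs)
            _, sel = call_sweep_regions(scores, genes=genes)
            selected[tag] = sel
        out = assign_edg_population(["swept1", "swept2"], selected["pop1"], selected["pop2"])
        assert all(x.label in ("upland_only", "both") for x in out)
        assert sum(x.label == "upland_only" for x in out) >= 1
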