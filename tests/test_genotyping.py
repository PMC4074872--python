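"""Genotype decision rules, site filters and allele-frequency estimation."""

import numpy as np
import pytest

from ecodiff import genotyping, simulate
from ecodiff.genotyping import (
    MISSING,
    SiteCallRecord,
    call_genotype,
    filter_sites,
    population_allele_frequencies,
    select_structure_snps,
    site_filter_reason,
)
from tests.conftest import make_matrix


def record(q_best=30.0, q_second=5.0, q_consensus=5.0, best="A", second="G",
           consensus="A", depth=50, copy_number=1.0, site_quality=30.0):
    return SiteCallRecord(
        chrom="chr1", pos=100, best_base=best, second_base=second,
        q_best=q_best, q_second=q_second, q_consensus=q_consensus,
        consensus_genotype=consensus, depth=depth, copy_number=copy_number,
        site_quality=site_quality,
    )


class TestSiteFilters:
    @pytest.mark.parametrize(
        "kwargs, reason",
        [
            (dict(site_quality=14.9), "quality"),
            (dict(site_quality=15.0), None),
            (dict(copy_number=1.6), "copy_number"),
            (dict(copy_number=1.5), None),
            (dict(depth=5), "depth"),
            (dict(depth=6), None),
            (dict(depth=300), None),
            (dict(depth=301), "depth"),
            (dict(site_quality=30.0, copy_number=1.0, depth=50), None),
        ],
    )
    def test_boundary_semantics(self, kwargs, reason):
        rec = record(**kwargs)
        assert site_filter_reason(rec.site_quality, rec.copy_number, rec.depth) == reason

    def test_filter_sites_splits_and_logs(self):
        recs = [record(), record(site_quality=10), record(depth=301)]
        kept, log = filter_sites(recs)
        assert len(kept) == 1
        assert [reason for _, reason in log] == ["quality", "depth"]

    def test_incomplete_record_rejected(self):
        class Bare:
            site_quality = 30.0
            copy_number = 1.0
            # no depth attribute

        kept, log = filter_sites([Bare()])
        assert kept == [] and log[0][1] == "incomplete"


def oracle_dosage(q_best, q_second, q_consensus, best, second, consensus, ref, alt):
    """Independent restatement of the three decision rules."""
    if q_best >= 20 and q_second < 20:
        pair = (best, best)
    elif q_best >= 20 and q_second >= 20:
        pair = (best, second)
    elif q_consensus >= 20:
        pair = genotyping.IUPAC_TO_PAIR.get(consensus)
        if pair is None:
            return MISSING
    else:
        return MISSING
    if not set(pair) <= {ref, alt}:
        return MISSING
    return sum(1 for b in pair if b == ref)


class TestCallGenotype:
    @pytest.mark.parametrize(
        "q_best, q_second, q_consensus, consensus, expected",
        [
            (30, 5, 0, "A", 0),     # homozygous best base (best=A=alt here? see below)
            (25, 22, 0, "A", 1),    # heterozygous best/second
            (10, 8, 25, "R", 1),    # consensus het A/G
            (10, 8, 15, "R", MISSING),  # nothing reaches quality 20
            (20, 19.9, 0, "A", 0),  # threshold is >= 20
        ],
    )
    def test_rule_examples(self, q_best, q_second, q_consensus, consensus, expected):
        # site ref=G, alt=A; best base A, second base G
        rec = record(q_best=q_best, q_second=q_second, q_consensus=q_consensus,
                     best="A", second="G", consensus=consensus)
        assert call_genotype(rec, ref="G", alt="A") == expected

    def test_inconsistent_consensus_warns_and_misses(self):
        rec = record(q_best=10, q_second=8, q_consensus=30, consensus="S")  # C/G
        with pytest.warns(UserWarning):
            assert call_genotype(rec, ref="A", alt="G") == MISSING

    def test_offtarget_best_base_missing(self):
        rec = record(q_best=30, q_second=5, best="T")
        assert call_genotype(rec, ref="A", alt="G") == MISSING

    def test_exhaustive_quality_grid_matches_oracle(self):
        """Every (q_best, q_second, q_consensus) cell on a coarse grid."""
        ref, alt = "A", "G"
        qs = np.arange(0, 41, 4.0)
        for qb in qs:
            for q2 in qs:
                for qc in qs:
                    rec = record(q_best=qb, q_second=q2, q_consensus=qc,
                                 best="G", second="A", consensus="R")
                    got = call_genotype(rec, ref, alt)
                    want = oracle_dosage(qb, q2, qc, "G", "A", "R", ref, alt)
                    assert got == want


class TestVectorizedCaller:
    def test_matches_scalar_on_simulated_records(self, small_dataset):
        freqs, matrix, table, truth = small_dataset
        called = simulate.call_matrix_from_table(table, matrix.populations)
        ref = table.sites["ref"].to_numpy()
        alt = table.sites["alt"].to_numpy()
        rng = np.random.default_rng(0)
        flat = rng.choice(matrix.n_sites * matrix.n_samples, size=500, replace=False)
        for k in flat:
            i, j = divmod(int(k), matrix.n_samples)
            rec = SiteCallRecord(
                chrom="x", pos=1, best_base=str(table.best_base[i, j]),
                second_base=str(table.second_base[i, j]),
                q_best=float(table.q_best[i, j]), q_second=float(table.q_second[i, j]),
                q_consensus=float(table.q_consensus[i, j]),
                consensus_genotype=str(table.consensus_genotype[i, j]),
                depth=int(table.depth[i, j]), copy_number=1.0, site_quality=30.0,
            )
            assert call_genotype(rec, ref[i], alt[i]) == called.dosage[i, j]

    def test_recovers_truth_at_configured_concordance(self, small_dataset):
        freqs, matrix, table, truth = small_dataset
        called = simulate.call_matrix_from_table(table, matrix.populations)
        both = (called.dosage != MISSING) & (matrix.dosage != MISSING)
        acc = (called.dosage[both] == matrix.dosage[both]).mean()
        assert acc >= 0.94  # generator default concordance 0.96 minus noise


class TestAlleleFrequencies:
    def test_definition_on_known_counts(self):
        dosage = np.array([[2, 2, 1, 0] + [1] * 7 + [0] * 11]).T.reshape(1, 22)
        m = make_matrix(dosage, populations=["pop1"] * 11 + ["pop2"] * 11)
        pf = population_allele_frequencies(m, min_called=10)
        assert pf.p1[0] == pytest.approx((2 + 2 + 1 + 0 + 7) / 22)
        assert pf.p2[0] == pytest.approx(0.0)

    def test_mask_at_exactly_min_called(self):
        # 10 called individuals in pop1 -> masked ("more than 10" rule)
        dosage = np.zeros((1, 22), dtype=np.int8)
        dosage[0, :1] = MISSING  # 10 called in pop1
        m = make_matrix(dosage, populations=["pop1"] * 11 + ["pop2"] * 11)
        pf = population_allele_frequencies(m, min_called=10)
        assert pf.mask1[0] and not pf.mask2[0]
        assert np.isnan(pf.p1[0])

    def test_all_missing_site_masked_everywhere(self):
        dosage = np.full((1, 24), MISSING, dtype=np.int8)
        pf = population_allele_frequencies(make_matrix(dosage))
        assert pf.mask1[0] and pf.mask2[0]

    def test_matches_naive_recount_oracle(self):
        rng = np.random.default_rng(3)
        dosage = rng.integers(-1, 3, size=(40, 30)).astype(np.int8)
        pops = ["pop1"] * 14 + ["pop2"] * 16
        m = make_matrix(dosage, populations=pops)
        pf = population_allele_frequencies(m, min_called=3)
        for i in range(40):
            for tag, sel in (("1", slice(0, 14)), ("2", slice(14, 30))):
                vals = [d for d in dosage[i, sel] if d != MISSING]
                p = getattr(pf, "p" + tag)[i]
                mask = getattr(pf, "mask" + tag)[i]
                if len(vals) <= 3:
                    assert mask
                else:
                    assert not mask
                    assert p == pytest.approx(sum(vals) / (2 * len(vals)))


class TestStructureSubset:
    def test_strict_threshold(self):
        dosage = np.zeros((2, 120), dtype=np.int8)
        dosage[0, :19] = MISSING  # 101 called -> retained
        dosage[1, :20] = MISSING  # 100 called -> dropped
        m = make_matrix(dosage, populations=["pop1"] * 60 + ["pop2"] * 60)
        sub = select_structure_snps(m, min_total_called=100)
        assert sub.n_sites == 1 and sub.sites["pos"].iloc[0] == m.sites["pos"].iloc[0]

    def test_fully_called_matrix_retained(self):
        dosage = np.ones((5, 120), dtype=np.int8)
        m = make_matrix(dosage, populations=["pop1"] * 60 + ["pop2"] * 60)
        assert select_structure_snps(m).n_sites == 5

    def test_matches_brute_force_recount(self, small_dataset):
        _, matrix, _, _ = small_dataset
        sub = select_structure_snps(matrix, min_total_called=25)
        want = [
            i for i in range(matrix.n_sites)
            if int((matrix.dosage[i] != MISSING).sum()) > 25
        ]
        assert list(sub.sites.index) == list(range(len(want)))
        assert np.array_equal(sub.dosage, matrix.dosage[want])
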