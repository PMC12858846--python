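import numpy as np
import pytest
from scipy.stats import binom

from psvkit import (AlignedRead, CandidateVariant, SimConfig,
                    analyse_carrier_cohort, call_haplotype,
                    compare_haplotypes, meiotic_distance,
                    simulate_founder_cohort, split_by_anchor)
from psvkit.haplotype_founder import Haplotype, HaplotypeCall, \
    discover_het_sites, subsample_reads

ANCHOR = CandidateVariant("gene", 50, "T", "A")


def _read(base_at_50, rid, length=100):
    seq = ["C"] * length
    seq[49] = base_at_50
    return AlignedRead(rid, "gene", 1, (("M", length),), "".join(seq))


class TestSplitByAnchor:
    def test_even_split(self):
        reads = [_read("T", f"t{i}") for i in range(5)] + \
                [_read("A", f"a{i}") for i in range(5)]
        split = split_by_anchor(reads, ANCHOR)
        assert (len(split.ref_reads), len(split.alt_reads),
                split.unassigned) == (5, 5, 0)

    def test_read_not_covering_anchor_unassigned(self):
        far = AlignedRead("far", "gene", 200, (("M", 10),), "ACGTACGTAC")
        split = split_by_anchor([far, _read("T", "t0")], ANCHOR)
        assert split.unassigned == 1 and len(split.ref_reads) == 1

    def test_third_allele_unassigned(self):
        split = split_by_anchor([_read("G", "g0")], ANCHOR)
        assert split.unassigned == 1

    def test_partition_is_conserved(self, rng):
        reads = [_read(rng.choice(list("ACGTN")), f"r{i}")
                 for i in range(200)]
        split = split_by_anchor(reads, ANCHOR)
        assert split.total == 200

    def test_zero_covering_reads_warns_not_raises(self, caplog):
        far = AlignedRead("far", "gene", 200, (("M", 10),), "ACGTACGTAC")
        split = split_by_anchor([far], ANCHOR)
        assert split.total == 1 and not split.ref_reads

    def test_het_amplicon_split_within_binomial_bounds(self):
        """At 2000x from a balanced het, the split stays inside the central
        99% binomial(n, 0.5) interval."""
        cfg = SimConfig(seed=41, long_read_len=2000, long_depth=1000,
                        carriers=2)
        cohort = simulate_founder_cohort(cfg)
        sample = next(iter(cohort.reads_by_sample))
        split = split_by_anchor(cohort.reads_by_sample[sample], cohort.anchor)
        n = len(split.ref_reads) + len(split.alt_reads)
        lo, hi = binom.ppf([0.005, 0.995], n, 0.5)
        assert lo <= len(split.alt_reads) <= hi


class TestCallHaplotype:
    def test_error_free_reads_recover_planted_haplotype(self):
        cfg = SimConfig(seed=42, long_read_len=1500, long_depth=60,
                        error_rate=0.0, carriers=2)
        cohort = simulate_founder_cohort(cfg)
        sample = next(iter(cohort.reads_by_sample))
        split = split_by_anchor(cohort.reads_by_sample[sample], cohort.anchor)
        positions = sorted(cohort.founder_sites)
        hap = call_haplotype(split.alt_reads, positions)
        assert hap.no_call_count == 0
        assert hap.called_positions == cohort.founder_sites

    def test_low_depth_site_is_no_call(self):
        reads = [_read("T", f"r{i}") for i in range(5)]
        hap = call_haplotype(reads, [50], min_depth=20)
        assert hap.calls == [] and hap.no_call_count == 1

    def test_ten_percent_discordance_still_called(self):
        reads = [_read("T", f"r{i}") for i in range(27)] + \
                [_read("A", f"d{i}") for i in range(3)]
        hap = call_haplotype(reads, [50], min_depth=20, min_majority=0.8)
        (call,) = hap.calls
        assert call.allele == "T" and call.majority_fraction == 0.9

    def test_exact_tie_is_no_call(self):
        reads = [_read("T", f"r{i}") for i in range(10)] + \
                [_read("A", f"d{i}") for i in range(10)]
        hap = call_haplotype(reads, [50], min_depth=10)
        assert hap.no_call_count == 1


class TestCompareHaplotypes:
    @staticmethod
    def _hap(sample, allele, alleles, positions=(10, 20, 30)):
        return Haplotype(sample, allele,
                         [HaplotypeCall(p, a, 100, 1.0)
                          for p, a in zip(positions, alleles)])

    def test_identical_variant_haplotypes_founder_consistent(self):
        haps = [self._hap("s1", "A", "GCT"), self._hap("s1", "T", "GCA"),
                self._hap("s2", "A", "GCT"), self._hap("s2", "T", "ACT")]
        rep = compare_haplotypes(haps, variant_allele="A")
        assert rep.concordance == 1.0
        assert rep.founder_consistent is True
        assert rep.compared_sites == 3

    def test_one_discordant_site_breaks_founder(self):
        haps = [self._hap("s1", "A", "GCT"), self._hap("s1", "T", "GCA"),
                self._hap("s2", "A", "GCG"), self._hap("s2", "T", "ACT")]
        rep = compare_haplotypes(haps, variant_allele="A")
        assert rep.founder_consistent is False
        assert rep.shared_sites == 2

    def test_variant_equal_to_background_breaks_founder(self):
        haps = [self._hap("s1", "A", "GCT"), self._hap("s1", "T", "GCT"),
                self._hap("s2", "A", "GCT"), self._hap("s2", "T", "ACT")]
        rep = compare_haplotypes(haps, variant_allele="A")
        assert rep.founder_consistent is False

    def test_no_joint_sites_flagged_undefined(self):
        haps = [self._hap("s1", "A", "GCT", (10, 20, 30)),
                self._hap("s2", "A", "GCT", (40, 50, 60))]
        rep = compare_haplotypes(haps, variant_allele="A")
        assert rep.compared_sites == 0
        assert rep.founder_consistent is None

    def test_fewer_than_two_haplotypes_rejected(self):
        with pytest.raises(ValueError):
            compare_haplotypes([self._hap("s1", "A", "GCT")],
                               variant_allele="A")


class TestFounderRecovery:
    def test_shared_founder_haplotype_detected(self):
        """Carriers sharing a planted 12-SNP haplotype are founder-consistent
        across seeds; planting an independent carrier breaks it."""
        for seed in range(5):
            cfg = SimConfig(seed=700 + seed, long_read_len=3000,
                            long_depth=200, carriers=4)
            cohort = simulate_founder_cohort(cfg)
            _, rep = analyse_carrier_cohort(cohort.reads_by_sample,
                                            cohort.anchor)
            assert rep.founder_consistent is True
            cohort_ind = simulate_founder_cohort(cfg, independent_carrier=0)
            _, rep_ind = analyse_carrier_cohort(cohort_ind.reads_by_sample,
                                                cohort_ind.anchor)
            assert rep_ind.founder_consistent is False

    def test_discovered_sites_include_founder_snps(self):
        cfg = SimConfig(seed=43, long_read_len=3000, long_depth=200)
        cohort = simulate_founder_cohort(cfg)
        sample = next(iter(cohort.reads_by_sample))
        split = split_by_anchor(cohort.reads_by_sample[sample], cohort.anchor)
        sites = discover_het_sites(split)
        assert set(cohort.founder_sites) <= set(sites)
        assert cohort.anchor.pos not in sites


def test_subsample_is_seeded_and_capped():
    reads = [_read("T", f"r{i}") for i in range(100)]
    sub1 = subsample_reads(reads, 30, seed=9)
    sub2 = subsample_reads(reads, 30, seed=9)
    assert [r.id for r in sub1] == [r.id for r in sub2]
    assert len(sub1) == 30
    assert subsample_reads(reads, 500) == reads


class TestMeioticDistance:
    @pytest.mark.parametrize("g1,g2,expected", [
        (7, 7, 14),   # sixth cousins via ancestors seven generations up
        (0, 3, 3),    # lineal descent
        (1, 1, 2),    # siblings through shared parents
    ])
    def test_path_lengths(self, g1, g2, expected):
        assert meiotic_distance(g1, g2) == expected

    def test_symmetry(self, rng):
        for _ in range(50):
            a, b = (int(x) for x in rng.integers(0, 20, size=2))
            assert meiotic_distance(a, b) == meiotic_distance(b, a)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            meiotic_distance(-1, 3)
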