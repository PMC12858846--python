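import numpy as np
import pytest

from psvkit import (PrimerPair, SequenceRecord, align_pair,
                    find_diagnostic_positions, in_silico_pcr, region_identity,
                    reverse_complement, window_identity)
from psvkit.paralog_alignment import (DiagnosticPosition, count_gap_columns,
                                      primer_pair_is_nonspecific)
from psvkit.synthetic_data import SimConfig, generate_reference_pair


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate_at(rng, seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
    return "".join(out)


class TestAlignPair:
    def test_identical_sequences(self):
        aln = align_pair(SequenceRecord("g", "ACGT"),
                         SequenceRecord("p", "ACGT"))
        assert len(aln) == 4
        assert find_diagnostic_positions(aln) == []

    def test_single_substitution(self):
        aln = align_pair(SequenceRecord("g", "ACGT"),
                         SequenceRecord("p", "AGGT"))
        psvs = find_diagnostic_positions(aln)
        assert len(psvs) == 1
        assert psvs[0] == DiagnosticPosition(2, 2, "C", "G")

    def test_planted_mutations_align_as_substitutions(self, rng):
        """Mismatch columns of the alignment equal the planted mutation set."""
        for _ in range(10):
            n = int(rng.integers(100, 301))
            gene = _rand_seq(rng, n)
            k = int(rng.integers(1, 12))
            sites = sorted(rng.choice(n, size=k, replace=False))
            pseudo = _mutate_at(rng, gene, sites)
            aln = align_pair(SequenceRecord("g", gene),
                             SequenceRecord("p", pseudo))
            assert count_gap_columns(aln) == 0
            psvs = find_diagnostic_positions(aln)
            assert [p.gene_pos - 1 for p in psvs] == list(sites)

    def test_gap_strip_round_trip(self, rng):
        """Removing gaps from each track reconstructs the inputs exactly."""
        for _ in range(5):
            gene = _rand_seq(rng, 200)
            # introduce a deletion and substitutions in the copy
            cut = int(rng.integers(50, 150))
            pseudo = _mutate_at(rng, gene[:cut] + gene[cut + 5:], [10, 40])
            aln = align_pair(SequenceRecord("g", gene),
                             SequenceRecord("p", pseudo))
            assert aln.gene_sequence() == gene
            assert aln.pseudo_sequence() == pseudo

    def test_offsets_strictly_increasing(self, rng):
        gene = _rand_seq(rng, 150)
        pseudo = _mutate_at(rng, gene[:60] + gene[63:], [5, 20])
        aln = align_pair(SequenceRecord("g", gene),
                         SequenceRecord("p", pseudo))
        for offs in (aln.gene_offsets, aln.pseudo_offsets):
            real = [o for o in offs if o is not None]
            assert real == sorted(real) and len(set(real)) == len(real)

    def test_refuses_mostly_n_sequence(self):
        with pytest.raises(ValueError, match="N"):
            align_pair(SequenceRecord("g", "NNNNNNNNNA"),
                       SequenceRecord("p", "ACGTACGTAC"))


class TestWindowIdentity:
    def test_identical_window(self):
        seq = "ACGTACGTACGTACGTACGTA"
        aln = align_pair(SequenceRecord("g", seq), SequenceRecord("p", seq))
        w = window_identity(aln, 11, 10)
        assert (w.matches, w.columns, w.mismatches) == (21, 21, 0)
        assert w.identity == 1.0

    def test_two_planted_mismatches_in_21_columns(self, rng):
        gene = _rand_seq(rng, 21)
        pseudo = _mutate_at(rng, gene, [4, 16])
        aln = align_pair(SequenceRecord("g", gene),
                         SequenceRecord("p", pseudo))
        w = window_identity(aln, 11, 10)
        assert (w.mismatches, w.columns) == (2, 21)

    def test_center_not_covered_raises(self):
        aln = align_pair(SequenceRecord("g", "ACGTACGT"),
                         SequenceRecord("p", "ACGTACGT"))
        with pytest.raises(ValueError):
            window_identity(aln, 99, 2)

    def test_emulated_variant_window(self, rng):
        """A 121-column window holding 11 planted differences reports 11/121,
        the density that makes mis-mapped reads identifiable."""
        gene = _rand_seq(rng, 121)
        sites = sorted(rng.choice(121, size=11, replace=False))
        pseudo = _mutate_at(rng, gene, sites)
        aln = align_pair(SequenceRecord("g", gene),
                         SequenceRecord("p", pseudo))
        w = window_identity(aln, 61, 60)
        assert (w.mismatches, w.columns) == (11, 121)


class TestRegionIdentity:
    def test_identical_region_is_100(self, rng):
        seq = _rand_seq(rng, 100)
        aln = align_pair(SequenceRecord("g", seq), SequenceRecord("p", seq))
        assert region_identity(aln, (1, 100)) == 100.0

    def test_constructed_875_identity(self, rng):
        cfg = SimConfig(seed=7, gene_length=1000, identity=0.875)
        pair, psvs = generate_reference_pair(cfg)
        assert len(psvs) == 125
        aln = pair.align()
        assert region_identity(aln, (1, 1000)) == pytest.approx(87.5)

    def test_invariant_under_joint_reverse_complement(self, rng):
        gene = _rand_seq(rng, 400)
        sites = sorted(rng.choice(400, size=30, replace=False))
        pseudo = _mutate_at(rng, gene, sites)
        fwd = align_pair(SequenceRecord("g", gene),
                         SequenceRecord("p", pseudo))
        rev = align_pair(SequenceRecord("g", reverse_complement(gene)),
                         SequenceRecord("p", reverse_complement(pseudo)))
        assert region_identity(fwd, (1, 400)) == \
            pytest.approx(region_identity(rev, (1, 400)))

    def test_empty_region_raises(self):
        aln = align_pair(SequenceRecord("g", "ACGTACGT"),
                         SequenceRecord("p", "ACGTACGT"))
        with pytest.raises(ValueError):
            region_identity(aln, (100, 200))


class TestFindDiagnosticPositions:
    def test_substitutions_and_gap_reported_separately(self, rng):
        gene = _rand_seq(rng, 120)
        pseudo = _mutate_at(rng, gene[:50] + gene[51:], [10, 30, 70])
        aln = align_pair(SequenceRecord("g", gene),
                         SequenceRecord("p", pseudo))
        psvs = find_diagnostic_positions(aln)
        assert len(psvs) == 3
        assert count_gap_columns(aln) == 1

    def test_planted_psv_recovery_property(self, rng):
        """Mutating k distinct sites yields exactly those k PSVs."""
        for _ in range(25):
            n = int(rng.integers(50, 2001))
            k = int(rng.integers(1, 16))
            gene = _rand_seq(rng, n)
            sites = sorted(rng.choice(n, size=k, replace=False))
            pseudo = _mutate_at(rng, gene, sites)
            aln = align_pair(SequenceRecord("g", gene),
                             SequenceRecord("p", pseudo))
            assert [p.gene_pos - 1 for p in find_diagnostic_positions(aln)] \
                == list(sites)


class TestInSilicoPcr:
    FWD = "AAGGGTCAAGGGACAGACCT"
    REV = "AAGCTCCCCAAGGAACAGAT"

    def _template(self, rng, gap=460, n=1000):
        filler = _rand_seq(rng, n)
        tpl = (filler[:100] + self.FWD + filler[100:100 + gap] +
               reverse_complement(self.REV) + filler[100 + gap:n - 140])
        return SequenceRecord("t", tpl)

    def test_planted_product_size(self, rng):
        tpl = self._template(rng, gap=480)
        (prod,) = in_silico_pcr(tpl, PrimerPair(self.FWD, self.REV))
        assert prod.product_size == 480 + len(self.FWD) + len(self.REV)
        assert prod.mismatches == 0

    def test_absent_primers_give_no_product(self, rng):
        tpl = SequenceRecord("t", _rand_seq(rng, 500))
        assert in_silico_pcr(tpl, PrimerPair(self.FWD, self.REV)) == []

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            PrimerPair("ACGTACGTACGT", self.REV)

    def test_product_size_matches_construction(self, rng):
        """Product size equals planted distance over random constructions."""
        for _ in range(200):
            gap = int(rng.integers(50, 700))
            tpl = self._template(rng, gap=gap, n=1200)
            prods = in_silico_pcr(tpl, PrimerPair(self.FWD, self.REV))
            assert [p.product_size for p in prods] == \
                [gap + len(self.FWD) + len(self.REV)]

    def test_internal_mismatch_tolerated_three_prime_not(self, rng):
        tpl = self._template(rng, gap=200)
        fwd_mut = "T" + self.FWD[1:]   # 5' mismatch: tolerated
        assert in_silico_pcr(tpl, PrimerPair(fwd_mut, self.REV))
        bad3 = self.FWD[:-1] + ("A" if self.FWD[-1] != "A" else "C")
        assert in_silico_pcr(tpl, PrimerPair(bad3, self.REV)) == []

    def test_nonspecific_flag_on_conserved_sites(self, rng):
        from psvkit.model import GenomicInterval
        from psvkit.paralog_alignment import ReferencePair
        tpl = self._template(rng, gap=300)
        pair = ReferencePair(
            gene=tpl, gene_interval=GenomicInterval("g", 1, len(tpl)),
            pseudogene=SequenceRecord("p", tpl.sequence),
            pseudo_interval=GenomicInterval("p", 1, len(tpl)))
        assert primer_pair_is_nonspecific(pair, PrimerPair(self.FWD, self.REV))
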