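"""Synthetic data emulating a gene/pseudogene locus with a candidate variant.

Generates everything the pipeline consumes, with full truth labels: a
homologous reference pair at a controlled identity, a planted heterozygous
variant on the gene copy, labelled short reads (including pseudogene reads
deliberately emitted in gene coordinates, modelling mis-mapping — the
artefact mechanism under test), long amplicon reads, founder-haplotype
carrier cohorts and case-control allele-count tables.

Defaults mirror the structure of the RP9/RP9P locus: ~87.5% gene-pseudogene
identity, 150 bp short reads at 30x, a ~9 kb amplicon sequenced deeply, and
a founder haplotype of 12 flanking SNPs shared across carriers.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .enrichment_stats import ContingencyTable
from .model import BASES, CandidateVariant, GenomicInterval, SequenceRecord
from .paralog_alignment import DiagnosticPosition, ReferencePair
from .read_adjudication import AlignedRead

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_SCENARIOS = ("h137l_like", "d170g_like", "none")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulated duplicated locus."""

    seed: int = 0
    gene_length: int = 10_000
    identity: float = 0.875
    variant_scenario: str = "h137l_like"
    short_read_len: int = 150
    short_depth: int = 30       # per-locus haploid-pair depth (WGS-like)
    long_read_len: int = 9_000  # amplicon length; long reads span it fully
    long_depth: int = 2_000     # reads per allele in the amplicon data
    error_rate: float = 0.01    # per-base substitution error
    carriers: int = 4
    founder_hap_snps: int = 12
    background_hap_snps: int = 6  # private het SNPs per carrier background

    def __post_init__(self) -> None:
        if not 0.5 < self.identity <= 1.0:
            raise ValueError("identity must be in (0.5, 1]")
        if self.short_depth <= 0 or self.long_depth <= 0:
            raise ValueError("depths must be positive")
        if not 0.0 <= self.error_rate <= 0.2:
            raise ValueError("error rate must be in [0, 0.2]")
        if self.variant_scenario not in _SCENARIOS:
            raise ValueError(f"unknown scenario {self.variant_scenario!r}")


@dataclass
class TruthBundle:
    """Everything planted by the simulator, for use as a test oracle."""

    config: SimConfig
    reference_pair: ReferencePair
    planted_psvs: list[DiagnosticPosition]
    planted_variant: CandidateVariant | None
    variant_copy: str | None  # which copy carries the variant ("gene" or None)
    reads: list[AlignedRead] = field(default_factory=list)


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASE_ARR[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, arr: np.ndarray,
            positions: np.ndarray) -> np.ndarray:
    """Substitute each listed position with a uniformly different base."""
    out = arr.copy()
    idx = np.searchsorted(_BASE_ARR, out[positions])
    shift = rng.integers(1, 4, size=len(positions))
    out[positions] = _BASE_ARR[(idx + shift) % 4]
    return out


def generate_reference_pair(cfg: SimConfig,
                            rng: np.random.Generator | None = None,
                            ) -> tuple[ReferencePair, list[DiagnosticPosition]]:
    """A random gene sequence and a pseudogene copy diverged from it by
    exactly ``round((1 - identity) * L)`` substitutions at distinct seeded
    positions (no indels).  The planted positions are returned as truth
    PSVs."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    L = cfg.gene_length
    n_sub = round((1.0 - cfg.identity) * L)
    if n_sub > L:
        raise ValueError("identity too low to place distinct substitutions")
    gene_arr = _random_seq(rng, L)
    sub_pos = np.sort(rng.choice(L, size=n_sub, replace=False))
    pseudo_arr = _mutate(rng, gene_arr, sub_pos)
    pair = ReferencePair(
        gene=SequenceRecord("gene", _decode(gene_arr)),
        gene_interval=GenomicInterval("gene", 1, L, "-"),
        pseudogene=SequenceRecord("pseudogene", _decode(pseudo_arr)),
        pseudo_interval=GenomicInterval("pseudogene", 1, L, "-"))
    psvs = [DiagnosticPosition(int(p) + 1, int(p) + 1,
                               chr(gene_arr[p]), chr(pseudo_arr[p]))
            for p in sub_pos]
    return pair, psvs


def plant_variant(pair: ReferencePair, psvs: list[DiagnosticPosition],
                  scenario: str, rng: np.random.Generator,
                  margin: int | None = None) -> CandidateVariant | None:
    """Choose a heterozygous variant site on the gene copy.

    * ``h137l_like`` — a site where gene and pseudogene agree (the pseudogene
      homolog equals the gene reference); the alt allele differs from both.
    * ``d170g_like`` — a PSV site, with alt equal to the pseudogene base, so
      mis-mapped pseudogene reads mimic the variant exactly.
    """
    if scenario == "none":
        return None
    L = len(pair.gene)
    margin = L // 10 if margin is None else margin
    psv_pos = {p.gene_pos for p in psvs}
    psv_by_pos = {p.gene_pos: p for p in psvs}
    if scenario == "h137l_like":
        candidates = [p for p in range(margin + 1, L - margin + 1)
                      if p not in psv_pos]
        if not candidates:
            raise ValueError("no non-PSV site available for the variant")
        pos = int(rng.choice(candidates))
        ref = pair.gene.sequence[pos - 1]
        alt = rng.choice([b for b in BASES if b != ref])
        return CandidateVariant("gene", pos, ref, str(alt),
                                pseudo_homolog_base=ref)
    if scenario == "d170g_like":
        candidates = [p for p in sorted(psv_pos)
                      if margin < p <= L - margin]
        if not candidates:
            raise ValueError("no PSV site available for the variant")
        pos = int(rng.choice(candidates))
        psv = psv_by_pos[pos]
        return CandidateVariant("gene", pos, psv.gene_base, psv.pseudo_base,
                                pseudo_homolog_base=psv.pseudo_base)
    raise ValueError(f"unknown scenario {scenario!r}")


def _emit_reads(rng: np.random.Generator, hap: np.ndarray, n_reads: int,
                read_len: int, error_rate: float, origin: str,
                id_prefix: str) -> list[AlignedRead]:
    """Uniformly placed single-block reads from one haplotype, with uniform
    substitution errors, in gene coordinates."""
    L = len(hap)
    starts = np.sort(rng.integers(0, L - read_len + 1, size=n_reads))
    mat = hap[starts[:, None] + np.arange(read_len)]
    if error_rate > 0:
        err = rng.random(mat.shape) < error_rate
        if err.any():
            idx = np.searchsorted(_BASE_ARR, mat[err])
            shift = rng.integers(1, 4, size=int(err.sum()))
            mat[err] = _BASE_ARR[(idx + shift) % 4]
    cigar = (("M", read_len),)
    return [AlignedRead(f"{id_prefix}_{i:06d}", "gene", int(starts[i]) + 1,
                        cigar, _decode(mat[i]), origin_truth=origin)
            for i in range(n_reads)]


def simulate_reads(pair: ReferencePair, variant: CandidateVariant | None,
                   cfg: SimConfig,
                   rng: np.random.Generator | None = None,
                   ) -> list[AlignedRead]:
    """Short reads from the diploid gene (one haplotype carrying the planted
    variant, if any) and the diploid pseudogene.

    Each locus is sequenced to ``short_depth``: per-locus read count is
    round(depth * L / read_len), split evenly between its two haplotypes.
    Pseudogene reads are placed at their source coordinates on the GENE
    coordinate system, emulating mis-mapping onto the gene copy.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    L = len(pair.gene)
    gene_arr = np.frombuffer(pair.gene.sequence.encode("ascii"),
                             dtype=np.uint8).copy()
    pseudo_arr = np.frombuffer(pair.pseudogene.sequence.encode("ascii"),
                               dtype=np.uint8).copy()
    gene_h1 = gene_arr.copy()
    if variant is not None:
        gene_h1[variant.pos - 1] = ord(variant.alt)
    per_locus = round(cfg.short_depth * L / cfg.short_read_len)
    per_hap = per_locus // 2
    reads: list[AlignedRead] = []
    for hap, origin, prefix, n in (
            (gene_h1, "gene", "g1", per_hap),
            (gene_arr, "gene", "g2", per_locus - per_hap),
            (pseudo_arr, "pseudogene", "p1", per_hap),
            (pseudo_arr, "pseudogene", "p2", per_locus - per_hap)):
        reads.extend(_emit_reads(rng, hap, n, cfg.short_read_len,
                                 cfg.error_rate, origin, prefix))
    return reads


def simulate_scenario(cfg: SimConfig) -> TruthBundle:
    """Full short-read scenario: reference pair, planted variant, reads."""
    rng = np.random.default_rng(cfg.seed)
    pair, psvs = generate_reference_pair(cfg, rng)
    variant = plant_variant(pair, psvs, cfg.variant_scenario, rng)
    reads = simulate_reads(pair, variant, cfg, rng)
    return TruthBundle(cfg, pair, psvs, variant,
                       "gene" if variant is not None else None, reads)


@dataclass
class FounderCohort:
    """Amplicon long-read data for a carrier cohort sharing (or not) a
    founder haplotype around the anchor variant."""

    amplicon: SequenceRecord
    anchor: CandidateVariant
    founder_sites: dict[int, str]           # pos -> founder (non-ref) allele
    background_haps: dict[str, dict[int, str]]  # sample -> private het sites
    reads_by_sample: dict[str, list[AlignedRead]]
    independent_sample: str | None = None


def simulate_founder_cohort(cfg: SimConfig,
                            independent_carrier: int | None = None,
                            ) -> FounderCohort:
    """Long amplicon reads for ``cfg.carriers`` heterozygous carriers.

    All carriers share one variant-bearing haplotype (anchor alt plus the
    non-reference allele at ``founder_hap_snps`` flanking SNPs); each has an
    independent background haplotype with private het SNPs.  When
    ``independent_carrier`` is given, that carrier's variant haplotype gets
    freshly drawn alleles at the founder sites instead (no shared descent).
    """
    if cfg.carriers < 2:
        raise ValueError("need at least 2 carriers")
    rng = np.random.default_rng(cfg.seed)
    L = cfg.long_read_len
    ref_arr = _random_seq(rng, L)
    amplicon = SequenceRecord("amplicon", _decode(ref_arr))
    anchor_pos = L // 2
    anchor_ref = chr(ref_arr[anchor_pos - 1])
    anchor_alt = str(rng.choice([b for b in BASES if b != anchor_ref]))
    anchor = CandidateVariant("gene", anchor_pos, anchor_ref, anchor_alt)

    margin = max(L // 20, 1)
    eligible = np.setdiff1d(
        np.arange(margin + 1, L - margin + 1), [anchor_pos])
    site_budget = cfg.founder_hap_snps + cfg.carriers * cfg.background_hap_snps
    all_sites = rng.choice(eligible, size=site_budget, replace=False)
    founder_pos = np.sort(all_sites[:cfg.founder_hap_snps])
    founder_sites = {}
    for p in founder_pos:
        ref_b = chr(ref_arr[p - 1])
        founder_sites[int(p)] = str(rng.choice(
            [b for b in BASES if b != ref_b]))

    founder_hap = ref_arr.copy()
    founder_hap[anchor_pos - 1] = ord(anchor_alt)
    for p, allele in founder_sites.items():
        founder_hap[p - 1] = ord(allele)

    reads_by_sample: dict[str, list[AlignedRead]] = {}
    background_haps: dict[str, dict[int, str]] = {}
    independent_name: str | None = None
    offset = cfg.founder_hap_snps
    for i in range(cfg.carriers):
        sample = f"carrier_{i + 1}"
        var_hap = founder_hap
        if independent_carrier is not None and i == independent_carrier:
            independent_name = sample
            var_hap = ref_arr.copy()
            var_hap[anchor_pos - 1] = ord(anchor_alt)
            while True:  # independent alleles at the founder sites
                drawn = {p: str(rng.choice(BASES_LIST))
                         for p in founder_sites}
                if any(drawn[p] != founder_sites[p] for p in founder_sites):
                    break
            for p, allele in drawn.items():
                var_hap[p - 1] = ord(allele)
        private = np.sort(
            all_sites[offset + i * cfg.background_hap_snps:
                      offset + (i + 1) * cfg.background_hap_snps])
        bg_hap = ref_arr.copy()
        bg_sites = {}
        for p in private:
            ref_b = chr(ref_arr[p - 1])
            allele = str(rng.choice([b for b in BASES if b != ref_b]))
            bg_sites[int(p)] = allele
            bg_hap[p - 1] = ord(allele)
        background_haps[sample] = bg_sites
        reads = _emit_full_span_reads(rng, var_hap, cfg.long_depth,
                                      cfg.error_rate, f"{sample}_var")
        reads += _emit_full_span_reads(rng, bg_hap, cfg.long_depth,
                                       cfg.error_rate, f"{sample}_bg")
        reads_by_sample[sample] = reads
    return FounderCohort(amplicon, anchor, founder_sites, background_haps,
                         reads_by_sample, independent_name)


BASES_LIST = list(BASES)


def _emit_full_span_reads(rng: np.random.Generator, hap: np.ndarray,
                          n_reads: int, error_rate: float,
                          id_prefix: str) -> list[AlignedRead]:
    """Full-length amplicon reads (PCR products are sequenced end to end)."""
    L = len(hap)
    mat = np.tile(hap, (n_reads, 1))
    if error_rate > 0:
        err = rng.random(mat.shape) < error_rate
        if err.any():
            idx = np.searchsorted(_BASE_ARR, mat[err])
            shift = rng.integers(1, 4, size=int(err.sum()))
            mat[err] = _BASE_ARR[(idx + shift) % 4]
    cigar = (("M", L),)
    return [AlignedRead(f"{id_prefix}_{i:06d}", "gene", 1, cigar,
                        _decode(mat[i]))
            for i in range(n_reads)]


def simulate_cohort_counts(n_case_probands: int, n_control_alleles: int,
                           case_carriers: int, seed: int = 0,
                           control_carriers: int = 0,
                           ) -> tuple[ContingencyTable, pd.DataFrame]:
    """Allele-level case/control table for heterozygous carriers (one variant
    allele each) plus a per-proband genotype table with seeded carrier
    placement."""
    if case_carriers > n_case_probands:
        raise ValueError("more carriers than probands")
    if control_carriers > n_control_alleles:
        raise ValueError("more control carriers than control alleles")
    table = ContingencyTable(case_carriers,
                             2 * n_case_probands - case_carriers,
                             control_carriers,
                             n_control_alleles - control_carriers)
    rng = np.random.default_rng(seed)
    carriers = set(rng.choice(n_case_probands, size=case_carriers,
                              replace=False).tolist())
    genotypes = pd.DataFrame({
        "sample": [f"case_{i + 1:04d}" for i in range(n_case_probands)],
        "genotype": ["het" if i in carriers else "hom_ref"
                     for i in range(n_case_probands)]})
    return table, genotypes
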