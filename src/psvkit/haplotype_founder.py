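"""Allele-split haplotyping of long amplicon reads and founder analysis.

Long reads spanning an amplicon are partitioned by the base they carry at an
anchor variant; a consensus haplotype is called separately for each
partition.  Apparently unrelated carriers share a founder allele when their
variant-anchored haplotypes are identical at every jointly-called SNP while
each differs from its own non-variant background haplotype.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .model import CandidateVariant
from .read_adjudication import AlignedRead

logger = logging.getLogger(__name__)


@dataclass
class AlleleSplit:
    """Reads partitioned by the base observed at the anchor variant."""

    anchor: CandidateVariant
    ref_reads: list[AlignedRead]
    alt_reads: list[AlignedRead]
    unassigned: int

    @property
    def total(self) -> int:
        return len(self.ref_reads) + len(self.alt_reads) + self.unassigned


class HaplotypeCall(NamedTuple):
    pos: int
    allele: str
    depth: int
    majority_fraction: float


@dataclass
class Haplotype:
    """A consensus haplotype called from one allele partition."""

    sample_id: str
    anchor_allele: str
    calls: list[HaplotypeCall]
    no_call_count: int = 0

    def __post_init__(self) -> None:
        pos = [c.pos for c in self.calls]
        if pos != sorted(set(pos)):
            raise ValueError("haplotype positions must be strictly increasing")

    @property
    def called_positions(self) -> dict[int, str]:
        return {c.pos: c.allele for c in self.calls}


@dataclass
class FounderReport:
    samples: list[str]
    shared_sites: int
    compared_sites: int
    concordance: float | None
    founder_consistent: bool | None  # None when no jointly-called sites
    per_sample_background_diffs: dict[str, int] = field(default_factory=dict)
    flanking_snp_genotypes: list | None = None


def split_by_anchor(reads: list[AlignedRead],
                    anchor: CandidateVariant) -> AlleleSplit:
    """Partition reads by the base at the anchor position; reads not covering
    the anchor or carrying a third allele are left unassigned."""
    ref_reads, alt_reads, unassigned = [], [], 0
    for r in reads:
        b = r.base_at(anchor.pos) if r.contig == anchor.contig else None
        if b == anchor.ref:
            ref_reads.append(r)
        elif b == anchor.alt:
            alt_reads.append(r)
        else:
            unassigned += 1
    if not ref_reads and not alt_reads:
        logger.warning("no reads cover the anchor %s", anchor)
    return AlleleSplit(anchor, ref_reads, alt_reads, unassigned)


def subsample_reads(reads: list[AlignedRead], max_reads: int,
                    seed: int = 0) -> list[AlignedRead]:
    """Seeded, reproducible down-sampling to a depth cap."""
    if len(reads) <= max_reads:
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=max_reads, replace=False))
    return [reads[i] for i in idx]


_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _read_matrix(reads: list[AlignedRead]) -> tuple[np.ndarray, int] | None:
    """Stack single-block reads with a common span into a base matrix.

    Returns (matrix, start) or None when reads are heterogeneous; amplicon
    reads are typically full-span single-block alignments, for which this
    vectorised path makes whole-amplicon site discovery cheap.
    """
    if not reads:
        return None
    first = reads[0]
    if not all(len(r.cigar) == 1 and r.cigar[0][0] in "M=X" and
               r.start == first.start and len(r.seq) == len(first.seq)
               for r in reads):
        return None
    mat = np.vstack([np.frombuffer(r.seq.encode("ascii"), dtype=np.uint8)
                     for r in reads])
    return mat, first.start


def _column_consensus(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column (major base code, depth, majority fraction)."""
    counts = np.stack([(mat == b).sum(axis=0) for b in _BASE_CODES])
    depth = counts.sum(axis=0)
    major = counts.argmax(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, counts.max(axis=0) / np.maximum(depth, 1), 0.0)
    return _BASE_CODES[major], depth, frac


def call_haplotype(reads: list[AlignedRead], positions: list[int],
                   min_depth: int = 20, min_majority: float = 0.8,
                   sample_id: str = "", anchor_allele: str = "") -> Haplotype:
    """Call the consensus allele at each position from one read partition.

    A site is called when at least ``min_depth`` reads report an A/C/G/T base
    there and the modal base reaches ``min_majority`` of them; otherwise the
    site is a no-call.  Deterministic: exact ties no-call.
    """
    positions = sorted(positions)
    calls: list[HaplotypeCall] = []
    no_calls = 0
    packed = _read_matrix(reads)
    for pos in positions:
        if packed is not None:
            mat, start = packed
            if not (start <= pos < start + mat.shape[1]):
                no_calls += 1
                continue
            col = mat[:, pos - start]
            counts = [(int((col == b).sum()), chr(b)) for b in _BASE_CODES]
        else:
            bases = [r.base_at(pos) for r in reads]
            counts = [(sum(1 for b in bases if b == a), a) for a in "ACGT"]
        depth = sum(c for c, _ in counts)
        best, second = sorted(counts, reverse=True)[:2]
        if depth < min_depth or best[0] == second[0]:
            no_calls += 1
            continue
        frac = best[0] / depth
        if frac < min_majority:
            no_calls += 1
            continue
        calls.append(HaplotypeCall(pos, best[1], depth, frac))
    return Haplotype(sample_id, anchor_allele, calls, no_calls)


def discover_het_sites(split: AlleleSplit, min_depth: int = 20,
                       min_majority: float = 0.8,
                       exclude: frozenset[int] | set[int] = frozenset(),
                       ) -> list[int]:
    """Heterozygous sites in the amplicon: positions where the two allele
    partitions have confidently different consensus bases.

    The anchor itself and any positions in ``exclude`` (e.g. PSVs) are
    omitted.  Falls back to a per-position scan for heterogeneous reads.
    """
    excluded = set(exclude) | {split.anchor.pos}
    packed_ref = _read_matrix(split.ref_reads)
    packed_alt = _read_matrix(split.alt_reads)
    if packed_ref is not None and packed_alt is not None and \
            packed_ref[1] == packed_alt[1] and \
            packed_ref[0].shape[1] == packed_alt[0].shape[1]:
        start = packed_ref[1]
        base_r, depth_r, frac_r = _column_consensus(packed_ref[0])
        base_a, depth_a, frac_a = _column_consensus(packed_alt[0])
        ok = ((depth_r >= min_depth) & (depth_a >= min_depth) &
              (frac_r >= min_majority) & (frac_a >= min_majority) &
              (base_r != base_a))
        sites = [int(i) + start for i in np.nonzero(ok)[0]]
        return [p for p in sites if p not in excluded]
    # generic path
    if not split.ref_reads or not split.alt_reads:
        return []
    lo = max(min(r.start for r in split.ref_reads),
             min(r.start for r in split.alt_reads))
    hi = min(max(r.end for r in split.ref_reads),
             max(r.end for r in split.alt_reads))
    sites = []
    for pos in range(lo, hi + 1):
        if pos in excluded:
            continue
        h_r = call_haplotype(split.ref_reads, [pos], min_depth, min_majority)
        h_a = call_haplotype(split.alt_reads, [pos], min_depth, min_majority)
        if h_r.calls and h_a.calls and h_r.calls[0].allele != h_a.calls[0].allele:
            sites.append(pos)
    return sites


def compare_haplotypes(haps: list[Haplotype], variant_allele: str,
                       flanking_snp_genotypes: list | None = None,
                       ) -> FounderReport:
    """Test whether variant-anchored haplotypes are consistent with a single
    founder.

    ``founder_consistent`` is True iff every pair of variant-anchored
    haplotypes agrees at every jointly-called site AND each differs from its
    own sample's non-variant haplotype at >= 1 jointly-called site.
    """
    if len(haps) < 2:
        raise ValueError("need at least two haplotypes to compare")
    variant_haps = [h for h in haps if h.anchor_allele == variant_allele]
    background = {h.sample_id: h for h in haps
                  if h.anchor_allele != variant_allele}
    if len(variant_haps) < 2:
        raise ValueError("need at least two variant-anchored haplotypes")

    joint = set(variant_haps[0].called_positions)
    for h in variant_haps[1:]:
        joint &= set(h.called_positions)
    compared = len(joint)
    shared = sum(1 for p in joint
                 if len({h.called_positions[p] for h in variant_haps}) == 1)

    per_sample_diffs: dict[str, int] = {}
    for h in variant_haps:
        bg = background.get(h.sample_id)
        if bg is None:
            continue
        pair_joint = set(h.called_positions) & set(bg.called_positions)
        per_sample_diffs[h.sample_id] = sum(
            1 for p in pair_joint
            if h.called_positions[p] != bg.called_positions[p])

    if compared == 0:
        concordance = None
        consistent = None
        logger.warning("no jointly-called sites; founder status undefined")
    else:
        concordance = shared / compared
        consistent = (shared == compared and
                      bool(per_sample_diffs) and
                      all(d >= 1 for d in per_sample_diffs.values()))
    return FounderReport(
        samples=sorted({h.sample_id for h in haps}),
        shared_sites=shared, compared_sites=compared,
        concordance=concordance, founder_consistent=consistent,
        per_sample_background_diffs=per_sample_diffs,
        flanking_snp_genotypes=flanking_snp_genotypes)


def analyse_carrier_cohort(reads_by_sample: dict[str, list[AlignedRead]],
                           anchor: CandidateVariant,
                           min_depth: int = 20, min_majority: float = 0.8,
                           exclude: frozenset[int] | set[int] = frozenset(),
                           max_depth: int | None = None,
                           seed: int = 0) -> tuple[list[Haplotype],
                                                   FounderReport]:
    """End-to-end allele-split founder analysis for several carriers.

    Per sample: split reads by the anchor allele (optionally down-sampling
    each partition to ``max_depth``), discover heterozygous sites, then call
    both haplotypes at the union of sites discovered across all samples.
    PSV positions may be passed in ``exclude`` so paralog differences are
    never mistaken for haplotype SNPs.
    """
    splits: dict[str, AlleleSplit] = {}
    union_sites: set[int] = set()
    for sample, reads in reads_by_sample.items():
        split = split_by_anchor(reads, anchor)
        if max_depth is not None:
            split = AlleleSplit(
                anchor,
                subsample_reads(split.ref_reads, max_depth, seed),
                subsample_reads(split.alt_reads, max_depth, seed + 1),
                split.unassigned)
        splits[sample] = split
        union_sites.update(discover_het_sites(split, min_depth, min_majority,
                                              exclude))
    positions = sorted(union_sites)
    haps: list[Haplotype] = []
    for sample, split in splits.items():
        haps.append(call_haplotype(split.alt_reads, positions, min_depth,
                                   min_majority, sample, anchor.alt))
        haps.append(call_haplotype(split.ref_reads, positions, min_depth,
                                   min_majority, sample, anchor.ref))
    return haps, compare_haplotypes(haps, variant_allele=anchor.alt)


def meiotic_distance(gen1: int, gen2: int) -> int:
    """Meioses separating two individuals along the pedigree path through
    their common ancestor: gen1 + gen2 (generations down each side)."""
    if gen1 < 0 or gen2 < 0:
        raise ValueError("generation counts must be non-negative")
    return gen1 + gen2
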