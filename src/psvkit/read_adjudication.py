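"""Read-origin classification at a duplicated locus and variant adjudication.

Short reads from a pseudogene that mis-map onto the gene can mimic (or mask)
a heterozygous variant.  Each read is assigned to gene or pseudogene by
majority vote over the diagnostic positions (PSVs) it covers; the candidate
variant is then adjudicated from the origin-labelled read stack.
"""
from __future__ import annotations

import bisect
import enum
from dataclasses import dataclass, field

from .model import CandidateVariant
from .paralog_alignment import DiagnosticPosition

CIGAR_OPS = "MIDNSHP=X"
_REF_CONSUMING = frozenset("M=XDN")
_QUERY_CONSUMING = frozenset("M=XIS")


@dataclass
class AlignedRead:
    """A mapped read: placement, CIGAR, and base lookup by reference position.

    ``origin_truth`` is populated only for simulated reads and records which
    copy the read was actually drawn from.
    """

    id: str
    contig: str
    start: int  # 1-based leftmost reference position
    cigar: tuple[tuple[str, int], ...]
    seq: str
    origin_truth: str = "unknown"  # {gene, pseudogene, unknown}

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"read {self.id}: start must be >= 1")
        for op, _ in self.cigar:
            if op not in CIGAR_OPS:
                raise ValueError(f"read {self.id}: unknown CIGAR op {op!r}")

    @property
    def end(self) -> int:
        """Rightmost reference position covered (1-based, inclusive)."""
        span = sum(n for op, n in self.cigar if op in _REF_CONSUMING)
        return self.start + span - 1

    def base_at(self, pos: int) -> str | None:
        """Read base aligned to reference position ``pos``; None when the
        position is outside the span or deleted in the read."""
        if pos < self.start or pos > self.end:
            return None
        # fast path: a single aligned block (the common simulated case)
        if len(self.cigar) == 1 and self.cigar[0][0] in "M=X":
            return self.seq[pos - self.start]
        ref = self.start
        q = 0
        for op, n in self.cigar:
            if op in "M=X":
                if ref <= pos < ref + n:
                    return self.seq[q + pos - ref]
                ref += n
                q += n
            elif op == "I" or op == "S":
                q += n
            elif op == "D" or op == "N":
                if ref <= pos < ref + n:
                    return None
                ref += n
            # H consumes neither
        return None


@dataclass(frozen=True)
class OriginCall:
    """Outcome of PSV voting for one read."""

    label: str  # {gene, pseudogene, ambiguous}
    gene_votes: int
    pseudo_votes: int
    informative_sites: int

    def __post_init__(self) -> None:
        if self.gene_votes + self.pseudo_votes > self.informative_sites:
            raise ValueError("votes exceed informative sites")


class Verdict(enum.Enum):
    GENE_DERIVED = "gene_derived"
    PSEUDOGENE_ARTEFACT_POSSIBLE = "pseudogene_artefact_possible"
    GENE_DERIVED_CONFIRMED = "gene_derived_confirmed"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class AdjudicationParams:
    min_informative: int = 2     # PSVs a read must cover to be labelled
    min_depth: int = 20          # total reads covering the variant
    min_alt_reads: int = 5
    het_band: tuple[float, float] = (0.2, 0.8)


def classify_read(read: AlignedRead, psvs: list[DiagnosticPosition],
                  min_informative: int = 2) -> OriginCall:
    """Vote the read's origin over the PSVs it covers.

    At each covered PSV the read base votes gene (equals the gene base),
    pseudogene (equals the pseudogene base), or abstains (sequencing error or
    third allele).  The label is the strict majority, provided at least
    ``min_informative`` PSVs were informative; ties are ambiguous.
    """
    positions = [p.gene_pos for p in psvs]
    lo = bisect.bisect_left(positions, read.start)
    hi = bisect.bisect_right(positions, read.end)
    gene = pseudo = informative = 0
    for psv in psvs[lo:hi]:
        b = read.base_at(psv.gene_pos)
        if b is None or b == "N":
            continue
        informative += 1
        if b == psv.gene_base:
            gene += 1
        elif b == psv.pseudo_base:
            pseudo += 1
    if informative >= min_informative and gene != pseudo:
        label = "gene" if gene > pseudo else "pseudogene"
    else:
        label = "ambiguous"
    return OriginCall(label, gene, pseudo, informative)


def adjudicate_variant(variant: CandidateVariant, reads: list[AlignedRead],
                       psvs: list[DiagnosticPosition],
                       params: AdjudicationParams = AdjudicationParams(),
                       ) -> tuple[Verdict, dict]:
    """Decide whether ``variant`` is carried by the gene copy or could be a
    pseudogene mapping artefact.

    Two locus configurations arise:

    * ``pseudo_homolog_base != alt`` — pseudogene bleed-through cannot
      produce the alt allele, so enough alt reads at a heterozygous fraction
      (among gene-labelled reads) establish a gene-derived variant.
    * ``pseudo_homolog_base == alt`` — mis-mapped pseudogene reads mimic the
      alt allele exactly; the variant is confirmed only when gene-labelled
      reads themselves carry it, otherwise a pseudogene artefact is possible.
    """
    covering = [r for r in reads
                if r.contig == variant.contig and
                r.base_at(variant.pos) is not None]
    report: dict = {"depth": len(covering)}
    if len(covering) < params.min_depth:
        report["rule"] = "insufficient_depth"
        return Verdict.INDETERMINATE, report

    # the variant site itself must not vote: on the artefact configuration an
    # alt-carrying read would otherwise count as a pseudogene vote
    voting_psvs = [p for p in psvs if p.gene_pos != variant.pos]
    calls = {r.id: classify_read(r, voting_psvs, params.min_informative)
             for r in covering}
    alt_reads = [r for r in covering if r.base_at(variant.pos) == variant.alt]
    gene_reads = [r for r in covering if calls[r.id].label == "gene"]
    gene_alt = [r for r in alt_reads if calls[r.id].label == "gene"]
    report.update(
        n_alt=len(alt_reads), n_gene_labelled=len(gene_reads),
        n_gene_labelled_alt=len(gene_alt),
        n_pseudo_labelled=sum(1 for c in calls.values()
                              if c.label == "pseudogene"),
        n_ambiguous=sum(1 for c in calls.values() if c.label == "ambiguous"))

    if not alt_reads:
        report["rule"] = "no_alt_reads"
        return Verdict.INDETERMINATE, report

    if variant.pseudo_homolog_base != variant.alt:
        # alt allele cannot come from pseudogene reference bleed-through
        lo, hi = params.het_band
        frac = len(gene_alt) / len(gene_reads) if gene_reads else 0.0
        report["gene_alt_fraction"] = frac
        if len(alt_reads) >= params.min_alt_reads and lo <= frac <= hi:
            report["rule"] = "alt_not_in_pseudogene_het_band"
            return Verdict.GENE_DERIVED, report
        report["rule"] = "alt_reads_or_het_band_not_met"
        return Verdict.INDETERMINATE, report

    # artefact-prone configuration: pseudogene base equals the alt allele
    if len(gene_alt) >= params.min_alt_reads:
        report["rule"] = "gene_labelled_reads_carry_alt"
        return Verdict.GENE_DERIVED_CONFIRMED, report
    report["rule"] = "alt_reads_attributable_to_pseudogene"
    return Verdict.PSEUDOGENE_ARTEFACT_POSSIBLE, report
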