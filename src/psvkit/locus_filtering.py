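"""Linked-locus candidate-variant triage.

For a dominant disease locus delimited by crossovers, candidate variants are
those heterozygous in every affected individual, rare in population
databases, and (for indels) outside microsatellite repeats; surviving SNVs
are then classified from in-silico deleteriousness scores.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .model import CandidateVariant, GenomicInterval


@dataclass
class AnnotationRecord:
    """A candidate variant with population frequency, in-silico scores and
    optional per-sample genotypes.  Missing scores are None, never zero."""

    variant: CandidateVariant
    maf: float | None = None
    cadd: float | None = None
    splice_ai: float | None = None
    fathmm_noncoding: float | None = None
    fathmm_coding: float | None = None
    remm: float | None = None
    gene: str = ""
    genotypes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("maf", "splice_ai", "fathmm_noncoding", "fathmm_coding",
                     "remm"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cadd is not None and self.cadd < 0:
            raise ValueError(f"cadd must be >= 0, got {self.cadd}")


@dataclass
class FilterConfig:
    region: GenomicInterval
    maf_max: float = 0.001
    cadd_min: float = 15.0
    splice_ai_min: float = 0.4
    fathmm_cut: float = 0.5
    require_shared_het: bool = True


def filter_candidates(records: list[AnnotationRecord], samples: list[str],
                      cfg: FilterConfig,
                      ) -> tuple[list[AnnotationRecord],
                                 list[AnnotationRecord],
                                 list[tuple[AnnotationRecord, str]]]:
    """Apply the linked-locus triage to candidate variants.

    Keeps variants inside ``cfg.region``, heterozygous in every named sample
    (when ``require_shared_het``), and with MAF strictly below ``maf_max``.
    A missing MAF is treated as 0 (absence from population databases is
    itself evidence of rarity), hence kept.  Surviving SNVs and indels are
    returned separately; every exclusion is logged with the rule that
    removed it.  Output order is positional, independent of input order.
    """
    if not samples:
        raise ValueError("at least one sample must be named")
    snvs: list[AnnotationRecord] = []
    indels: list[AnnotationRecord] = []
    excluded: list[tuple[AnnotationRecord, str]] = []
    for rec in sorted(records, key=lambda r: (r.variant.contig, r.variant.pos,
                                              r.variant.ref, r.variant.alt)):
        v = rec.variant
        if not cfg.region.contains(v.contig, v.pos):
            excluded.append((rec, "outside_region"))
            continue
        if cfg.require_shared_het:
            missing = [s for s in samples if s not in rec.genotypes]
            if missing:
                raise KeyError(
                    f"sample {missing[0]!r} absent from genotypes of {v}")
            if any(rec.genotypes[s] != "het" for s in samples):
                excluded.append((rec, "not_heterozygous_in_all_samples"))
                continue
        if rec.maf is not None and rec.maf >= cfg.maf_max:
            excluded.append((rec, "maf_not_rare"))
            continue
        (snvs if v.is_snv else indels).append(rec)
    return snvs, indels, excluded


def _is_primitive(unit: str) -> bool:
    """True when the repeat unit is not itself a repetition of a shorter one."""
    for u in range(1, len(unit)):
        if len(unit) % u == 0 and unit == unit[:u] * (len(unit) // u):
            return False
    return True


def microsatellite_context(window: str, indel_pos: int,
                           max_unit: int = 6, min_copies: int = 3,
                           min_tract: int = 8) -> tuple[bool, str | None, int]:
    """Is an indel inside a microsatellite (short tandem repeat)?

    ``window`` is the reference sequence around the indel and ``indel_pos``
    the 0-based index of the indel within it.  A microsatellite is a perfect
    tandem repeat with unit length 1-6, >= 3 copies and tract >= 8 bases.
    Returns (is_microsatellite, unit, copies) for the longest qualifying
    tract containing the indel.
    """
    if len(window) < 40:
        raise ValueError(f"window must be >= 40 bases, got {len(window)}")
    if not 0 <= indel_pos < len(window):
        raise ValueError("indel position outside the window")
    best: tuple[int, str, int] | None = None  # (tract_len, unit, copies)
    n = len(window)
    for u in range(1, max_unit + 1):
        i = u
        tract_start = 0
        while i <= n:
            if i < n and window[i] == window[i - u]:
                i += 1
                continue
            tract_len = i - tract_start
            copies = tract_len // u
            unit = window[tract_start:tract_start + u]
            if (copies >= min_copies and tract_len >= min_tract and
                    _is_primitive(unit) and
                    tract_start <= indel_pos < tract_start + tract_len):
                if best is None or tract_len > best[0]:
                    best = (tract_len, unit, copies)
            tract_start = i - u + 1
            i = tract_start + u
    if best is None:
        return False, None, 0
    return True, best[1], best[2]


def score_classify(rec: AnnotationRecord,
                   cfg: FilterConfig) -> tuple[str, str]:
    """Classify a variant as ``deleterious`` or ``low_evidence`` from its
    in-silico scores.

    Deleterious iff CADD > cadd_min, or SpliceAI > splice_ai_min, or both
    FATHMM-MKL scores (coding and non-coding) > fathmm_cut.  Missing scores
    never satisfy a clause.  ReMM is reported, not thresholded.  Returns the
    label and a rationale string naming the clause that fired.
    """
    if all(getattr(rec, f) is None for f in
           ("cadd", "splice_ai", "fathmm_noncoding", "fathmm_coding")):
        raise ValueError(f"no in-silico scores available for {rec.variant}")
    if rec.cadd is not None and rec.cadd > cfg.cadd_min:
        return "deleterious", f"cadd {rec.cadd} > {cfg.cadd_min}"
    if rec.splice_ai is not None and rec.splice_ai > cfg.splice_ai_min:
        return "deleterious", f"splice_ai {rec.splice_ai} > {cfg.splice_ai_min}"
    if (rec.fathmm_coding is not None and rec.fathmm_noncoding is not None and
            rec.fathmm_coding > cfg.fathmm_cut and
            rec.fathmm_noncoding > cfg.fathmm_cut):
        return "deleterious", (f"fathmm coding {rec.fathmm_coding} and "
                               f"non-coding {rec.fathmm_noncoding} > "
                               f"{cfg.fathmm_cut}")
    return "low_evidence", "no score exceeded its threshold"


def load_linked_locus_scores() -> list[AnnotationRecord]:
    """The packaged fixture of in-silico scores for the eleven rare
    shared-heterozygous SNVs found across the RP9-linked 2 Mb locus."""
    from .io_formats import read_annotation_table
    with resources.as_file(
            resources.files("psvkit.data") / "linked_locus_snvs.tsv") as p:
        return read_annotation_table(p)
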