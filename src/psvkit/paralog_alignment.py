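"""Gene/pseudogene pairwise alignment, diagnostic-position (PSV) discovery,
windowed identity, and in-silico PCR primer-specificity checks.

A paralogous sequence variant (PSV) is an alignment column where the gene and
its pseudogene carry different bases.  PSVs are the evidence units used
downstream to decide whether a sequencing read originated from the gene or
from the pseudogene copy.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import NamedTuple

from Bio import Align

from .model import GenomicInterval, SequenceRecord, reverse_complement

GAP = "-"


@dataclass
class PairwiseAlignment:
    """A global alignment of a gene segment against its pseudogene copy.

    ``gene_track``/``pseudo_track`` are equal-length gapped strings.
    ``gene_start``/``pseudo_start`` anchor the first aligned base of each
    track in genomic coordinates (1-based).
    """

    gene_track: str
    pseudo_track: str
    score: float
    gene_start: int = 1
    pseudo_start: int = 1
    gene_offsets: list = field(init=False, repr=False)
    pseudo_offsets: list = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.gene_track) != len(self.pseudo_track):
            raise ValueError("alignment tracks must have equal length")
        self.gene_offsets = _offsets(self.gene_track, self.gene_start)
        self.pseudo_offsets = _offsets(self.pseudo_track, self.pseudo_start)

    def __len__(self) -> int:
        return len(self.gene_track)

    @property
    def columns(self) -> list[tuple[str, str]]:
        return list(zip(self.gene_track, self.pseudo_track))

    def gene_sequence(self) -> str:
        return self.gene_track.replace(GAP, "")

    def pseudo_sequence(self) -> str:
        return self.pseudo_track.replace(GAP, "")

    def column_of_gene_pos(self, pos: int) -> int:
        """Alignment column index (0-based) holding gene position ``pos``."""
        keyed = self._gene_pos_index()
        i = bisect.bisect_left(keyed, (pos, -1))
        if i < len(keyed) and keyed[i][0] == pos:
            return keyed[i][1]
        raise ValueError(f"gene position {pos} is not covered by the alignment")

    def _gene_pos_index(self) -> list[tuple[int, int]]:
        cached = getattr(self, "_pos_index", None)
        if cached is None:
            cached = [(p, i) for i, p in enumerate(self.gene_offsets)
                      if p is not None]
            self._pos_index = cached
        return cached


def _offsets(track: str, start: int) -> list:
    """1-based source position per column; None at gap columns."""
    out: list = []
    pos = start
    for ch in track:
        if ch == GAP:
            out.append(None)
        else:
            out.append(pos)
            pos += 1
    return out


@dataclass(frozen=True)
class DiagnosticPosition:
    """An aligned substitution column: the gene and pseudogene bases differ."""

    gene_pos: int
    pseudo_pos: int
    gene_base: str
    pseudo_base: str

    def __post_init__(self) -> None:
        if self.gene_base == self.pseudo_base:
            raise ValueError("diagnostic position requires differing bases")
        if GAP in (self.gene_base, self.pseudo_base):
            raise ValueError("diagnostic position must be gap-free")


@dataclass
class ReferencePair:
    """Gene and pseudogene segments with genomic anchoring."""

    gene: SequenceRecord
    gene_interval: GenomicInterval
    pseudogene: SequenceRecord
    pseudo_interval: GenomicInterval
    alignment: PairwiseAlignment | None = None

    def __post_init__(self) -> None:
        if len(self.gene_interval) != len(self.gene):
            raise ValueError("gene interval length != gene sequence length")
        if len(self.pseudo_interval) != len(self.pseudogene):
            raise ValueError(
                "pseudogene interval length != pseudogene sequence length")

    def align(self, **params) -> PairwiseAlignment:
        self.alignment = align_pair(
            self.gene, self.pseudogene,
            gene_start=self.gene_interval.start,
            pseudo_start=self.pseudo_interval.start, **params)
        return self.alignment


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair, both given 5'->3'."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 15:
                raise ValueError(f"{name} primer shorter than 15 bases")


class PcrProduct(NamedTuple):
    start: int  # 1-based, first base of the forward primer footprint
    end: int    # 1-based, last base of the reverse primer footprint
    product_size: int
    mismatches: int


def align_pair(gene: SequenceRecord, pseudo: SequenceRecord, *,
               match: float = 1.0, mismatch: float = -2.0,
               gap_open: float = -6.0, gap_extend: float = -1.0,
               gene_start: int = 1, pseudo_start: int = 1,
               max_n_fraction: float = 0.5) -> PairwiseAlignment:
    """Global affine-gap alignment of a gene segment against its paralog.

    Defaults keep point substitutions aligned as substitutions rather than
    split around gaps, appropriate for ~90%-identical paralogs.  A gap of
    length L costs ``gap_open + L * gap_extend``.  Deterministic: the
    highest-scoring alignment reported by the aligner's canonical traceback
    is returned.
    """
    for rec in (gene, pseudo):
        if rec.n_fraction() > max_n_fraction:
            raise ValueError(
                f"sequence {rec.id!r} is more than {max_n_fraction:.0%} N; "
                "refusing to align")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(gene.sequence, pseudo.sequence)[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score),
                             gene_start=gene_start, pseudo_start=pseudo_start)


class WindowIdentity(NamedTuple):
    matches: int
    columns: int
    mismatches: int  # substitution columns only; gaps counted in `columns`

    @property
    def identity(self) -> float:
        return self.matches / self.columns


def window_identity(aln: PairwiseAlignment, center_gene_pos: int,
                    flank: int) -> WindowIdentity:
    """Identity over ``flank`` alignment columns either side of the column
    holding ``center_gene_pos`` (2*flank+1 columns when gap-free)."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    c = aln.column_of_gene_pos(center_gene_pos)
    lo, hi = c - flank, c + flank
    if lo < 0 or hi >= len(aln):
        raise ValueError("window extends beyond the alignment")
    return _count_window(aln, lo, hi)


def _count_window(aln: PairwiseAlignment, lo: int, hi: int) -> WindowIdentity:
    matches = mismatches = 0
    for g, p in zip(aln.gene_track[lo:hi + 1], aln.pseudo_track[lo:hi + 1]):
        if GAP in (g, p):
            continue
        if g == p:
            matches += 1
        else:
            mismatches += 1
    return WindowIdentity(matches, hi - lo + 1, mismatches)


def region_identity(aln: PairwiseAlignment, gene_region: GenomicInterval |
                    tuple[int, int]) -> float:
    """Percent identity (100*matches/columns) over the alignment columns
    spanned by a gene region; gap columns count as non-matches."""
    if isinstance(gene_region, GenomicInterval):
        start, end = gene_region.start, gene_region.end
    else:
        start, end = gene_region
    cols = [i for i, p in enumerate(aln.gene_offsets)
            if p is not None and start <= p <= end]
    if not cols:
        raise ValueError("region not covered by the alignment")
    lo, hi = cols[0], cols[-1]
    w = _count_window(aln, lo, hi)
    return 100.0 * w.matches / w.columns


def find_diagnostic_positions(aln: PairwiseAlignment) -> list[DiagnosticPosition]:
    """All substitution columns, sorted by gene position.  Gap columns are not
    PSVs (see :func:`count_gap_columns`)."""
    out = []
    for i, (g, p) in enumerate(zip(aln.gene_track, aln.pseudo_track)):
        if g != p and g != GAP and p != GAP:
            out.append(DiagnosticPosition(aln.gene_offsets[i],
                                          aln.pseudo_offsets[i], g, p))
    out.sort(key=lambda d: d.gene_pos)
    return out


def count_gap_columns(aln: PairwiseAlignment) -> int:
    return sum(1 for g, p in zip(aln.gene_track, aln.pseudo_track)
               if g == GAP or p == GAP)


def _primer_site_mismatches(primer: str, site: str,
                            three_prime_at_end: bool) -> int | None:
    """Mismatch count if the primer may bind this site, else None.

    The three terminal 3' bases must match exactly (standard PCR specificity
    heuristic); remaining mismatches are counted and limited by the caller.
    """
    if len(primer) != len(site):
        return None
    if three_prime_at_end:
        anchor, body = primer[-3:], primer[:-3]
        s_anchor, s_body = site[-3:], site[:-3]
    else:
        anchor, body = primer[:3], primer[3:]
        s_anchor, s_body = site[:3], site[3:]
    if anchor != s_anchor:
        return None
    return sum(1 for a, b in zip(body, s_body) if a != b)


def in_silico_pcr(template: SequenceRecord, primers: PrimerPair,
                  max_mismatch: int = 2,
                  max_product: int = 20_000) -> list[PcrProduct]:
    """Predict PCR products of ``primers`` on ``template``.

    The forward primer binds the forward strand; the reverse primer binds as
    its reverse complement downstream.  Mismatches are allowed outside each
    primer's three 3'-terminal bases, up to ``max_mismatch`` per primer.
    Positions are 1-based; product size = end - start + 1, inclusive of both
    primer footprints.
    """
    seq = template.sequence
    f, r = primers.forward, primers.reverse
    r_site = reverse_complement(r)  # site as it appears on the forward strand
    fwd_hits: list[tuple[int, int]] = []
    for i in range(len(seq) - len(f) + 1):
        mm = _primer_site_mismatches(f, seq[i:i + len(f)], True)
        if mm is not None and mm <= max_mismatch:
            fwd_hits.append((i, mm))
    rev_hits: list[tuple[int, int]] = []
    for i in range(len(seq) - len(r_site) + 1):
        # reverse primer's 3' end maps to the LEFT end of its forward-strand site
        mm = _primer_site_mismatches(r_site, seq[i:i + len(r_site)], False)
        if mm is not None and mm <= max_mismatch:
            rev_hits.append((i, mm))
    products = []
    for fi, fmm in fwd_hits:
        for ri, rmm in rev_hits:
            end = ri + len(r_site)  # 0-based exclusive
            if end <= fi + len(f):
                continue
            size = end - fi
            if size <= max_product:
                products.append(PcrProduct(fi + 1, end, size, fmm + rmm))
    products.sort(key=lambda p: (p.start, p.end))
    return products


def primer_pair_is_nonspecific(pair: ReferencePair, primers: PrimerPair,
                               max_mismatch: int = 2,
                               max_product: int = 20_000) -> bool:
    """True when the pair amplifies a product from BOTH the gene and the
    pseudogene — i.e. the assay cannot distinguish the two copies."""
    on_gene = in_silico_pcr(pair.gene, primers, max_mismatch, max_product)
    on_pseudo = in_silico_pcr(pair.pseudogene, primers, max_mismatch,
                              max_product)
    return bool(on_gene) and bool(on_pseudo)
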