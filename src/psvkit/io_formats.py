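"""External representations: FASTA, a SAM-subset text format, a VCF-lite
adjudication output, annotation/PSV/cohort TSV tables and YAML configs.

All other modules operate on domain types only; every file touched by the
pipeline goes through this module.  Full binary formats (BAM/CRAM, indexed
VCF) are deliberately out of scope: reads arrive pre-aligned as text.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .locus_filtering import AnnotationRecord
from .model import CandidateVariant, SequenceRecord
from .paralog_alignment import DiagnosticPosition
from .read_adjudication import AlignedRead, Verdict

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A malformed input file."""


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file; sequences are uppercased and validated against the
    DNA alphabet (RNA 'U' is rejected)."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        try:
            records.append(SequenceRecord(rec.id, seq))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ----------------------------------------------------------- SAM subset

_CIGAR_RE = re.compile(r"(\d+)([A-Z=])")
_SUPPORTED_OPS = frozenset("M=XIDSH")


def parse_cigar(text: str) -> tuple[tuple[str, int], ...]:
    """Parse a CIGAR string; only M,=,X,I,D,S,H are supported."""
    if text == "*" or not text:
        raise FormatError("missing CIGAR string")
    ops = []
    consumed = 0
    for m in _CIGAR_RE.finditer(text):
        consumed += len(m.group(0))
        op = m.group(2)
        if op not in _SUPPORTED_OPS:
            raise FormatError(f"unsupported CIGAR op {op!r} in {text!r}")
        ops.append((op, int(m.group(1))))
    if consumed != len(text):
        raise FormatError(f"malformed CIGAR string {text!r}")
    return tuple(ops)


def read_sam_subset(path: str | Path) -> list[AlignedRead]:
    """Read mapped records from a SAM text file or the 6-column subset
    (QNAME FLAG RNAME POS CIGAR SEQ).

    Full 11+ column SAM lines are accepted (optional fields ignored; MAPQ is
    not required downstream because reads are re-assigned by PSV voting).
    Unmapped records (FLAG bit 0x4) are dropped and the count logged.
    """
    path = Path(path)
    reads: list[AlignedRead] = []
    unmapped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                fields = line.split()
            if len(fields) >= 11:
                qname, flag, rname, pos, cigar, seq = (
                    fields[0], fields[1], fields[2], fields[3], fields[5],
                    fields[9])
            elif len(fields) == 6:
                qname, flag, rname, pos, cigar, seq = fields
            else:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 or >=11 columns, "
                    f"got {len(fields)}")
            try:
                flag_i = int(flag)
                pos_i = int(pos)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if flag_i & 0x4:
                unmapped += 1
                continue
            if pos_i < 1:
                raise FormatError(f"{path}:{lineno}: POS must be >= 1, "
                                  f"got {pos_i}")
            try:
                cigar_ops = parse_cigar(cigar)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            reads.append(AlignedRead(qname, rname, pos_i, cigar_ops,
                                     seq.upper()))
    if unmapped:
        logger.info("%s: dropped %d unmapped record(s)", path, unmapped)
    return reads


def write_sam(reads: list[AlignedRead], path: str | Path,
              reference_lengths: dict[str, int] | None = None) -> None:
    """Write reads as minimal valid SAM text (deterministic output)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        if reference_lengths:
            for name in sorted(reference_lengths):
                fh.write(f"@SQ\tSN:{name}\tLN:{reference_lengths[name]}\n")
        for r in reads:
            cigar = "".join(f"{n}{op}" for op, n in r.cigar)
            fh.write(f"{r.id}\t0\t{r.contig}\t{r.start}\t60\t{cigar}\t*\t0\t0"
                     f"\t{r.seq}\t*\n")


# ------------------------------------------------------ annotation TSV

_REQUIRED_ANNOT_COLS = ("position", "gene", "cadd", "fathmm_noncoding",
                        "fathmm_coding", "remm", "maf", "splice_ai")


def _opt_float(value, path, row: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or \
            (isinstance(value, str) and not value.strip()):
        return None
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise FormatError(
            f"{path}: row {row}: non-numeric {column} value {value!r}"
        ) from exc


def read_annotation_table(path: str | Path) -> list[AnnotationRecord]:
    """Read a TSV of per-variant annotations.

    Required columns: position (``chr7:33096550T>A``), gene, cadd,
    fathmm_noncoding, fathmm_coding, remm, maf, splice_ai; empty cells are
    missing values (never coerced to zero).  Per-sample genotype columns
    named ``gt_<sample>`` are collected into the record's genotype map.
    Extra columns are ignored.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_ANNOT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    gt_cols = [c for c in df.columns if c.startswith("gt_")]
    records: list[AnnotationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            variant = CandidateVariant.from_string(row["position"])
        except ValueError as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
        gene = row["gene"]
        genotypes = {c[3:]: row[c] for c in gt_cols
                     if isinstance(row[c], str) and row[c].strip()}
        records.append(AnnotationRecord(
            variant=variant,
            gene="" if not isinstance(gene, str) else gene.strip(),
            cadd=_opt_float(row["cadd"], path, i, "cadd"),
            fathmm_noncoding=_opt_float(row["fathmm_noncoding"], path, i,
                                        "fathmm_noncoding"),
            fathmm_coding=_opt_float(row["fathmm_coding"], path, i,
                                     "fathmm_coding"),
            remm=_opt_float(row["remm"], path, i, "remm"),
            maf=_opt_float(row["maf"], path, i, "maf"),
            splice_ai=_opt_float(row["splice_ai"], path, i, "splice_ai"),
            genotypes=genotypes))
    return records


# -------------------------------------------------------------- PSV TSV

_PSV_COLS = ("gene_pos", "pseudo_pos", "gene_base", "pseudo_base")


def write_psv_table(psvs: list[DiagnosticPosition], path: str | Path) -> None:
    pd.DataFrame(
        [(p.gene_pos, p.pseudo_pos, p.gene_base, p.pseudo_base)
         for p in psvs],
        columns=_PSV_COLS).to_csv(path, sep="\t", index=False)


def read_psv_table(path: str | Path) -> list[DiagnosticPosition]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PSV_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return sorted(
        (DiagnosticPosition(int(r.gene_pos), int(r.pseudo_pos),
                            str(r.gene_base), str(r.pseudo_base))
         for r in df.itertuples(index=False)),
        key=lambda p: p.gene_pos)


# ------------------------------------------------------------- VCF-lite

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=PARALOG_VERDICT,Number=1,Type=String,'
    'Description="Gene-versus-pseudogene adjudication verdict">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")


def write_adjudication_vcf(variants: list[CandidateVariant],
                           verdicts: dict[CandidateVariant, Verdict | str],
                           path: str | Path) -> None:
    """Write adjudicated variants as VCF-lite, the verdict in INFO under the
    PARALOG_VERDICT key.  Positions are 1-based; indels use the left-anchored
    REF/ALT convention of VCF."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for v in sorted(variants, key=lambda v: (v.contig, v.pos, v.ref,
                                                 v.alt)):
            for allele, name in ((v.ref, "REF"), (v.alt, "ALT")):
                if not re.fullmatch(r"[ACGTN]+", allele):
                    raise FormatError(f"{v}: invalid {name} allele "
                                      f"{allele!r}")
            verdict = verdicts[v]
            label = verdict.value if isinstance(verdict, Verdict) else verdict
            fh.write(f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
                     f"PARALOG_VERDICT={label}\n")


def read_adjudication_vcf(path: str | Path,
                          ) -> list[tuple[CandidateVariant, str]]:
    path = Path(path)
    out: list[tuple[CandidateVariant, str]] = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##fileformat"):
            raise FormatError(f"{path}: missing ##fileformat header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(f"{path}:{lineno}: expected 8 columns")
            chrom, pos, _, ref, alt, _, _, info = fields[:8]
            m = re.search(r"PARALOG_VERDICT=([^;]+)", info)
            if m is None:
                raise FormatError(f"{path}:{lineno}: PARALOG_VERDICT missing")
            out.append((CandidateVariant(chrom, int(pos), ref, alt),
                        m.group(1)))
    return out


# ----------------------------------------------------------------- YAML

def load_config(path: str | Path) -> dict:
    """Load a YAML configuration mapping (used for CLI defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return data
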