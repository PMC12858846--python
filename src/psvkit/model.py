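"""Shared domain types used across the pipeline.

Coordinates are genomic, 1-based and inclusive throughout (VCF convention).
Minus-strand genes are handled by keeping all sequence and read data in
forward-strand orientation; strand is carried as metadata only.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

BASES = "ACGT"
_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A closed genomic interval ``contig:start-end`` on ``strand``."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos <= self.end

    @classmethod
    def from_string(cls, text: str, strand: str = "+") -> "GenomicInterval":
        """Parse ``chr7:32320394-34315743`` (commas in numbers tolerated)."""
        m = re.fullmatch(r"([\w.]+):([\d,]+)-([\d,]+)", text.strip())
        if m is None:
            raise ValueError(f"cannot parse interval {text!r}")
        return cls(m.group(1), int(m.group(2).replace(",", "")),
                   int(m.group(3).replace(",", "")), strand)


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def n_fraction(self) -> float:
        return self.sequence.count("N") / len(self.sequence)

    def reverse_complement(self, new_id: str | None = None) -> "SequenceRecord":
        return SequenceRecord(new_id or self.id, reverse_complement(self.sequence))


_VARIANT_RE = re.compile(
    r"([\w.]+):([\d,]+)[:\s]?([ACGTN]+)(?:>|:)([ACGTN]+)")


@dataclass(frozen=True)
class CandidateVariant:
    """A candidate small variant; ``pseudo_homolog_base`` is the pseudogene
    base at the homologous alignment column (None when unknown or gapped)."""

    contig: str
    pos: int
    ref: str
    alt: str
    pseudo_homolog_base: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:
        return f"{self.contig}:{self.pos}{self.ref}>{self.alt}"

    @classmethod
    def from_string(cls, text: str,
                    pseudo_homolog_base: str | None = None) -> "CandidateVariant":
        """Parse ``chr7:33096550T>A`` or ``chr7:33096550:T:A``."""
        m = _VARIANT_RE.fullmatch(text.strip())
        if m is None:
            raise ValueError(f"cannot parse variant {text!r}")
        return cls(m.group(1), int(m.group(2).replace(",", "")),
                   m.group(3), m.group(4), pseudo_homolog_base)
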