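"""Exact case-control allele enrichment and frequency/prevalence arithmetic.

Fisher's exact test is computed from hypergeometric point probabilities in
log space (via log-gamma), so tables with margins near 10^6 — e.g. a rare
variant against a whole population database — are handled without overflow
or normal approximation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_EVEN
from typing import NamedTuple

import numpy as np
from scipy.special import gammaln


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table; rows = cases/controls, columns = variant/non-variant.

    ``a`` = case variant alleles, ``b`` = case non-variant alleles,
    ``c`` = control variant alleles, ``d`` = control non-variant alleles.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"cell {name} is negative ({v})")
        if self.total == 0:
            raise ValueError("table is empty")

    @property
    def row1(self) -> int:
        return self.a + self.b

    @property
    def row2(self) -> int:
        return self.c + self.d

    @property
    def col1(self) -> int:
        return self.a + self.c

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


class FisherResult(NamedTuple):
    p_one_sided_greater: float
    p_two_sided: float


def _log_hypergeom_pmf(k: np.ndarray, r1: int, c1: int, n: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(n, r1, c1)."""
    k = np.asarray(k, dtype=float)
    return (gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
            + gammaln(n - r1 + 1) - gammaln(c1 - k + 1)
            - gammaln(n - r1 - (c1 - k) + 1)
            + gammaln(c1 + 1) + gammaln(n - c1 + 1) - gammaln(n + 1))


def fisher_exact(t: ContingencyTable,
                 rel_tol: float = 1e-7) -> FisherResult:
    """Exact test of association for a 2x2 table.

    One-sided p = P(a >= observed | margins); two-sided p = sum of point
    probabilities <= the observed table's probability (the conventional
    definition, with ties admitted within relative tolerance ``rel_tol``).
    """
    r1, c1, n = t.row1, t.col1, t.total
    k_min = max(0, c1 - t.row2)
    k_max = min(r1, c1)
    support = np.arange(k_min, k_max + 1)
    logp = _log_hypergeom_pmf(support, r1, c1, n)
    logp_obs = _log_hypergeom_pmf(np.array([t.a]), r1, c1, n)[0]
    one_sided = float(np.exp(logp[support >= t.a]).sum())
    two_sided = float(np.exp(logp[logp <= logp_obs + math.log1p(rel_tol)]).sum())
    return FisherResult(min(one_sided, 1.0), min(two_sided, 1.0))


def odds_ratio(t: ContingencyTable, haldane: bool = True) -> float:
    """Sample odds ratio; the Haldane-Anscombe 0.5 correction is applied when
    any cell is zero (and requested)."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if haldane and 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        return math.inf
    return (a * d) / (b * c)


class FrequencyEstimate(NamedTuple):
    count: int
    total: int
    frequency: float
    rounded: float
    sig_figs: int
    one_in: float  # 1 / rounded frequency ("1 in N alleles")


def allele_frequency(count: int, total: int,
                     sig_figs: int = 2) -> FrequencyEstimate:
    """Allele frequency count/total with round-half-even to ``sig_figs``
    significant figures, as population frequencies are conventionally
    printed."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0 or count > total:
        raise ValueError("count must be within [0, total]")
    freq = count / total
    if count == 0:
        return FrequencyEstimate(count, total, 0.0, 0.0, sig_figs, math.inf)
    exact = Decimal(count) / Decimal(total)
    exponent = exact.adjusted()  # floor(log10(|exact|))
    quantum = Decimal(1).scaleb(exponent - sig_figs + 1)
    rounded = float(exact.quantize(quantum, rounding=ROUND_HALF_EVEN))
    return FrequencyEstimate(count, total, freq, rounded, sig_figs,
                             1.0 / rounded)


class PrevalenceReport(NamedTuple):
    allele_frequency: float
    carrier_frequency: float
    disease_prevalence: float
    assumed_penetrance: float
    incompatible_with_fully_penetrant_dominant: bool


def prevalence_consistency(allele_freq: float, disease_prevalence: float,
                           assumed_penetrance: float = 1.0,
                           ) -> PrevalenceReport:
    """Compare the expected affected-carrier frequency of a dominant allele,
    2*q*(1-q)*penetrance, with the disease prevalence.

    When carriers would outnumber all affected individuals the variant
    cannot be a fully penetrant dominant cause at the assumed penetrance.
    """
    if not 0.0 <= allele_freq <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    if not 0.0 < disease_prevalence <= 1.0:
        raise ValueError("prevalence must be in (0, 1]")
    if not 0.0 < assumed_penetrance <= 1.0:
        raise ValueError("penetrance must be in (0, 1]")
    carrier = 2.0 * allele_freq * (1.0 - allele_freq) * assumed_penetrance
    return PrevalenceReport(allele_freq, carrier, disease_prevalence,
                            assumed_penetrance, carrier > disease_prevalence)
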