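"""ACMG/AMP evidence combination with manual strength re-weighting.

Evidence codes (PVS/PS/PM/PP pathogenic; BA/BS/BP benign) are combined by
the published rule table into a five-tier classification.  Each item may be
applied at a strength other than its default — e.g. cosegregation (PP1)
escalated to very strong, or case-control enrichment (PS4) applied at
strong — as clinical interpretation platforms allow.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass


class Classification(enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN_SIGNIFICANCE = "uncertain_significance"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


PATHOGENIC_STRENGTHS = ("very_strong", "strong", "moderate", "supporting")
BENIGN_STRENGTHS = ("stand_alone_benign", "strong_benign",
                    "supporting_benign")

_DEFAULT_BY_PREFIX = {
    "PVS": "very_strong",
    "PS": "strong",
    "PM": "moderate",
    "PP": "supporting",
    "BA": "stand_alone_benign",
    "BS": "strong_benign",
    "BP": "supporting_benign",
}


def _prefix(code: str) -> str:
    for pre in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if code.upper().startswith(pre):
            return pre
    raise ValueError(f"unrecognised ACMG code {code!r}")


@dataclass(frozen=True)
class EvidenceItem:
    """One ACMG criterion at a (possibly re-weighted) strength."""

    code: str
    applied_strength: str | None = None

    def __post_init__(self) -> None:
        pre = _prefix(self.code)
        default = _DEFAULT_BY_PREFIX[pre]
        applied = self.applied_strength or default
        if applied not in PATHOGENIC_STRENGTHS + BENIGN_STRENGTHS:
            raise ValueError(f"unknown strength {applied!r}")
        benign_code = pre in ("BA", "BS", "BP")
        benign_strength = applied in BENIGN_STRENGTHS
        if benign_code != benign_strength:
            raise ValueError(
                f"{self.code}: strength {applied!r} is on the wrong side of "
                "the pathogenic/benign divide")
        object.__setattr__(self, "applied_strength", applied)

    @property
    def default_strength(self) -> str:
        return _DEFAULT_BY_PREFIX[_prefix(self.code)]

    @property
    def is_benign(self) -> bool:
        return self.applied_strength in BENIGN_STRENGTHS


def _pathogenic_rule(vs: int, s: int, m: int, p: int) -> str | None:
    if vs >= 2:
        # not in the original combining table (which leaves two very-strong
        # items unclassifiable); required for re-weighting monotonicity and
        # consistent with later sequence-variant interpretation guidance
        return "pathogenic: >=2 very strong"
    if vs >= 1:
        if s >= 1:
            return "pathogenic: 1 very strong + >=1 strong"
        if m >= 2:
            return "pathogenic: 1 very strong + >=2 moderate"
        if m >= 1 and p >= 1:
            return "pathogenic: 1 very strong + 1 moderate + 1 supporting"
        if p >= 2:
            return "pathogenic: 1 very strong + >=2 supporting"
    if s >= 2:
        return "pathogenic: >=2 strong"
    if s >= 1:
        if m >= 3:
            return "pathogenic: 1 strong + >=3 moderate"
        if m >= 2 and p >= 2:
            return "pathogenic: 1 strong + 2 moderate + >=2 supporting"
        if m >= 1 and p >= 4:
            return "pathogenic: 1 strong + 1 moderate + >=4 supporting"
    return None


def _likely_pathogenic_rule(vs: int, s: int, m: int, p: int) -> str | None:
    if vs >= 1 and m >= 1:
        return "likely pathogenic: 1 very strong + 1 moderate"
    if s >= 1 and m >= 1:
        return "likely pathogenic: 1 strong + 1-2 moderate"
    if s >= 1 and p >= 2:
        return "likely pathogenic: 1 strong + >=2 supporting"
    if m >= 3:
        return "likely pathogenic: >=3 moderate"
    if m >= 2 and p >= 2:
        return "likely pathogenic: 2 moderate + >=2 supporting"
    if m >= 1 and p >= 4:
        return "likely pathogenic: 1 moderate + >=4 supporting"
    return None


def _benign_rule(ba: int, bs: int, bp: int) -> tuple[Classification, str] | None:
    if ba >= 1:
        return Classification.BENIGN, "benign: stand-alone (BA1)"
    if bs >= 2:
        return Classification.BENIGN, "benign: >=2 strong benign"
    if bs >= 1 and bp >= 1:
        return (Classification.LIKELY_BENIGN,
                "likely benign: 1 strong benign + 1 supporting benign")
    if bp >= 2:
        return Classification.LIKELY_BENIGN, "likely benign: >=2 supporting benign"
    return None


def combine_criteria(evidence: list[EvidenceItem],
                     ) -> tuple[Classification, str]:
    """Combine evidence items into a classification.

    Counts use each item's applied strength.  When both a pathogenic and a
    benign rule fire, the evidence is contradictory and the variant is of
    uncertain significance.  Deterministic and order-invariant.
    """
    codes = [e.code.upper() for e in evidence]
    if len(codes) != len(set(codes)):
        dup = sorted({c for c in codes if codes.count(c) > 1})
        raise ValueError(f"duplicate evidence code(s): {', '.join(dup)}")
    strengths = [e.applied_strength for e in evidence]
    vs = strengths.count("very_strong")
    s = strengths.count("strong")
    m = strengths.count("moderate")
    p = strengths.count("supporting")
    ba = strengths.count("stand_alone_benign")
    bs = strengths.count("strong_benign")
    bp = strengths.count("supporting_benign")

    path_rule = _pathogenic_rule(vs, s, m, p)
    if path_rule is not None:
        path = (Classification.PATHOGENIC, path_rule)
    else:
        lp_rule = _likely_pathogenic_rule(vs, s, m, p)
        path = (Classification.LIKELY_PATHOGENIC, lp_rule) if lp_rule else None
    benign = _benign_rule(ba, bs, bp)

    if path and benign:
        return (Classification.UNCERTAIN_SIGNIFICANCE,
                "conflicting pathogenic and benign evidence")
    if path:
        return path
    if benign:
        return benign
    return (Classification.UNCERTAIN_SIGNIFICANCE,
            "criteria not met for any other class")


def evidence_from_enrichment(fisher_p: float,
                             alpha: float = 1e-4) -> EvidenceItem | None:
    """PS4 (prevalence significantly increased in affected individuals) at
    strong strength when the enrichment p-value is below ``alpha``."""
    if not 0.0 < fisher_p <= 1.0:
        raise ValueError("p-value must be in (0, 1]")
    if fisher_p < alpha:
        return EvidenceItem("PS4", "strong")
    return None
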