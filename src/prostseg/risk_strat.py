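"""Low/medium/high risk grouping of prostate-cancer cases.

The stratifier combines the three standard prognostic axes — Gleason score,
serum PSA (ng/mL) and clinical T-stage — with the canonical D'Amico-style
thresholds as defaults:

* **high**:   Gleason >= 8, or PSA > 20, or stage >= T2c
* **medium**: otherwise, if Gleason == 7, or 10 <= PSA <= 20, or stage == T2b
* **low**:    otherwise (Gleason <= 6 and PSA < 10 and stage <= T2a)

Precedence high > medium > low makes the rule total and mutually exclusive,
and monotone in each axis.  All thresholds are configurable through
:class:`RiskRule`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from prostseg.phantoms import STAGES, CaseRecord

__all__ = [
    "RiskRule",
    "RISK_GROUPS",
    "assign_risk",
    "stratify_cohort",
    "gleason_pattern_reference",
]

RISK_GROUPS = ("low", "medium", "high")


def stage_index(stage: str) -> int:
    """Ordinal position of a clinical T-stage (T1 < T2a < T2b < T2c < T3 < T4)."""
    try:
        return STAGES.index(stage)
    except ValueError:
        raise ValueError(f"unknown clinical stage {stage!r}") from None


@dataclass(frozen=True)
class RiskRule:
    """Configurable thresholds of the three-axis risk grouping."""

    gleason_high: int = 8  # high if score >= this
    psa_high: float = 20.0  # high if PSA strictly above this
    stage_high: str = "T2c"  # high if stage >= this
    gleason_medium: int = 7  # medium if score == this (and not high)
    psa_medium_low: float = 10.0  # medium if psa_medium_low <= PSA <= psa_high
    stage_medium: str = "T2b"  # medium if stage == this (and not high)


def assign_risk(record: CaseRecord, rule: RiskRule | None = None) -> str:
    """Assign a cancer case to 'low', 'medium' or 'high'.

    Raises for hyperplasia records (benign disease is not risk-graded) and
    for Gleason scores outside 2-10.
    """
    if rule is None:
        rule = RiskRule()
    if record.true_class != "cancer":
        raise ValueError("risk groups are assigned only to cancer cases")
    g, psa, stage = record.gleason_score, record.psa, record.clinical_stage
    if not (2 <= g <= 10):
        raise ValueError(f"Gleason score {g} outside 2-10")
    if psa < 0:
        raise ValueError("PSA must be non-negative")
    s = stage_index(stage)
    if g >= rule.gleason_high or psa > rule.psa_high or s >= stage_index(rule.stage_high):
        return "high"
    if (
        g == rule.gleason_medium
        or rule.psa_medium_low <= psa <= rule.psa_high
        or s == stage_index(rule.stage_medium)
    ):
        return "medium"
    return "low"


def stratify_cohort(
    records: Iterable[CaseRecord], rule: RiskRule | None = None
) -> dict[str, int]:
    """Count cancer cases per risk group; totals equal the number of records."""
    counts = Counter({g: 0 for g in RISK_GROUPS})
    for record in records:
        counts[assign_risk(record, rule)] += 1
    return dict(counts)


# The five histologic pattern descriptions of the standard Gleason grading
# scheme, used for documentation and CLI help only; grading itself uses the
# numeric score.
_GLEASON_PATTERNS: Mapping[int, str] = {
    1: (
        "Cancer tissue is extremely rare. Its borders are very clear, it grows "
        "expansively, and it hardly invades the matrix; the carcinomas are "
        "simple, usually round, and moderately sized and are packed together; "
        "the cytoplasm of cancer cells closely resembles that of benign "
        "epithelial cells."
    ),
    2: (
        "Cancer tissue is rare, which mostly occurs in the transitional area "
        "of the prostate. The tumor boundary is not very clear, and the "
        "carcinomas are separated by the stroma. They are simple, round, "
        "different in size, and irregular in shape and are loosely arranged "
        "together."
    ),
    3: (
        "Cancer tissue is the most common, which mostly occurs in the "
        "peripheral area of the prostate. Its most important feature is "
        "invasive growth, the carcinomas are of different sizes and shapes, "
        "nucleoli are large and red, and the cytoplasm is mostly alkaline "
        "staining."
    ),
    4: (
        "The cancer tissue is poorly differentiated and grows infiltrating; "
        "the carcinomas are irregularly fused to form tiny papillary or "
        "sieve-shaped, large and red nucleoli; the cytoplasm can be alkaline "
        "or gray."
    ),
    5: (
        "The cancer tissue is very poorly differentiated. The border can be "
        "regularly round or irregular, accompanied by invasive growth; the "
        "growth form is sheet-like single cell type or acne-like carcinoma "
        "type, accompanied by necrosis; cancer cells have large nuclei and "
        "large and red nucleoli; cytoplasmic staining may vary."
    ),
}


def gleason_pattern_reference(pattern: int | None = None):
    """Histologic description of a Gleason pattern grade (1-5).

    With no argument, returns the full ``{grade: description}`` mapping.
    """
    if pattern is None:
        return dict(_GLEASON_PATTERNS)
    if pattern not in _GLEASON_PATTERNS:
        raise ValueError(f"Gleason pattern grade must be 1-5, got {pattern}")
    return _GLEASON_PATTERNS[pattern]
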