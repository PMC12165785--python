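"""Functional categories and the PS3/BS3 evidence code.

Each QC-passing day-12 arm gets a category from the replicate-mean
normalized ratio: deleterious (≤ 25%), intermediate (25–50%], or neutral
(> 50%). Category boundaries follow the printed inequalities, so exactly
25 is deleterious and exactly 50 is intermediate.

A variant's single functional evidence code is derived from its
per-condition categories: deleterious in ANY arm → PS3 at the calibrated
strength; otherwise intermediate in any arm → PS3 at indeterminate
strength (zero points — intermediate behaviour must not be abated into
benign evidence); otherwise all-neutral → BS3 at the calibrated strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .acmg import EvidenceCode
from .calibration import THRESHOLD_DELETERIOUS, THRESHOLD_NEUTRAL
from .ingest import DAY12_CONDITIONS
from .ratios import RatioSeries

__all__ = ["CATEGORIES", "FunctionalCall", "categorize", "assign_functional_code", "score_variant"]

CATEGORIES = ("deleterious", "intermediate", "neutral")


@dataclass(frozen=True)
class FunctionalCall:
    variant_id: str
    categories: Mapping[str, str]  # day-12 condition -> category
    code: Optional[EvidenceCode]  # None when no condition was assessable


def categorize(
    mean_ratio: float,
    threshold_deleterious: float = THRESHOLD_DELETERIOUS,
    threshold_neutral: float = THRESHOLD_NEUTRAL,
) -> str:
    """Map a replicate-mean normalized ratio (percent) onto a category."""
    if mean_ratio < 0:
        raise ValueError(f"normalized ratio cannot be negative, got {mean_ratio}")
    if mean_ratio <= threshold_deleterious:
        return "deleterious"
    if mean_ratio <= threshold_neutral:
        return "intermediate"
    return "neutral"


def assign_functional_code(
    calls: Mapping[str, str],
    variant_id: str = "",
    ps3_strength: str = "moderate",
    bs3_strength: str = "moderate",
) -> EvidenceCode:
    """One PS3/BS3 code from the per-condition categories.

    Invariant to condition ordering: only the set of categories matters.
    """
    if not calls:
        raise ValueError(f"{variant_id or 'variant'}: no categorized conditions")
    cats = set(calls.values())
    unknown = cats - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    if "deleterious" in cats:
        return EvidenceCode("PS3", "pathogenic", ps3_strength)
    if "intermediate" in cats:
        return EvidenceCode("PS3", "pathogenic", "indeterminate")
    return EvidenceCode("BS3", "benign", bs3_strength)


def score_variant(
    rs: RatioSeries,
    threshold_deleterious: float = THRESHOLD_DELETERIOUS,
    threshold_neutral: float = THRESHOLD_NEUTRAL,
    ps3_strength: str = "moderate",
    bs3_strength: str = "moderate",
) -> FunctionalCall:
    """Categorize each present day-12 arm and derive the functional code.

    A variant with zero QC-passing day-12 arms is returned with
    ``code=None`` ("not assessable").
    """
    categories = {
        cond: categorize(stats.mean, threshold_deleterious, threshold_neutral)
        for cond, stats in rs.conditions.items()
        if cond in DAY12_CONDITIONS
    }
    if not categories:
        return FunctionalCall(rs.variant_id, {}, None)
    code = assign_functional_code(
        categories, rs.variant_id, ps3_strength=ps3_strength, bs3_strength=bs3_strength
    )
    return FunctionalCall(rs.variant_id, categories, code)
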