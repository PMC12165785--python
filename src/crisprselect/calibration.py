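"""Assay calibration from previously classified control variants.

Control variants of known truth (benign vs pathogenic) anchor three pieces
of the interpretation machinery:

1. **Thresholds.** ROC analysis over the calibration score (the minimum
   replicate-mean normalized ratio across the four day-12 arms — the
   variant's worst-case behaviour) confirms the operating thresholds.
   The default two-threshold scheme (deleterious ≤ 25%, neutral > 50%,
   intermediate in between) is configuration, not inference; the ROC also
   reports the Youden-J optimal single cutoff for transparency.
2. **Sensitivity/specificity** with Wilson 95% score intervals.
3. **OddsPath** — the odds of pathogenicity delivered by the binary assay
   readout, following the ClinGen SVI functional-evidence calibration:
   with prior P1 (proportion pathogenic among controls) and posterior P2
   (proportion pathogenic within a readout class),

       OddsPath = [P2 × (1 − P1)] / [(1 − P2) × P1].

   A readout class containing only one truth (a "perfect" assay) gets one
   hypothetical opposite-truth control added before computing P2, keeping
   the odds finite. OddsPath maps to PS3/BS3 evidence strength via fixed
   cutpoints (≥ 18.7 strong, ≥ 4.3 moderate, ≥ 2.1 supporting on the
   pathogenic side, reciprocal bands on the benign side).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

from .ingest import DAY12_CONDITIONS
from .ratios import RatioSeries

__all__ = [
    "THRESHOLD_DELETERIOUS",
    "THRESHOLD_NEUTRAL",
    "ControlVariant",
    "RocResult",
    "CalibrationResult",
    "calibration_score",
    "roc_curve",
    "wilson_interval",
    "compute_oddspath",
    "strength_from_oddspath",
    "calibrate",
]

#: Normalized-ratio thresholds (percent): ≤ deleterious, > neutral.
THRESHOLD_DELETERIOUS = 25.0
THRESHOLD_NEUTRAL = 50.0

# OddsPath → evidence-strength cutpoints (ClinGen SVI calibration scale).
_PATHOGENIC_CUTPOINTS = (
    (350.0, "very_strong"),
    (18.7, "strong"),
    (4.3, "moderate"),
    (2.1, "supporting"),
)
_BENIGN_CUTPOINTS = (
    (0.00285, "very_strong"),
    (0.053, "strong"),
    (0.23, "moderate"),
    (0.48, "supporting"),
)


@dataclass(frozen=True)
class ControlVariant:
    """One calibration control: known truth plus its assay score."""

    variant_id: str
    truth: str  # benign | pathogenic
    calibration_score: float  # percent

    def __post_init__(self) -> None:
        if self.truth not in ("benign", "pathogenic"):
            raise ValueError(f"truth must be benign|pathogenic, got {self.truth!r}")


@dataclass(frozen=True)
class RocResult:
    fpr: tuple
    tpr: tuple
    thresholds: tuple
    auc: float
    youden_cutoff: float  # score cutoff maximizing TPR − FPR


@dataclass(frozen=True)
class CalibrationResult:
    threshold_deleterious: float
    threshold_neutral: float
    auc: float
    sensitivity: float
    specificity: float
    sens_ci: tuple
    spec_ci: tuple
    oddspath_pathogenic: float
    oddspath_benign: float
    p1_prior: float
    p2_abnormal: float
    p2_normal: float
    ps3_strength: str
    bs3_strength: str
    n_pathogenic: int
    n_benign: int


def calibration_score(rs: RatioSeries) -> float:
    """Worst-case functional score: the minimum replicate-mean normalized
    ratio across the day-12 arms.

    PS3 is triggered by deleteriousness in any single arm, so the
    decision-relevant score is the most depleted one.
    """
    means = [
        stats.mean for cond, stats in rs.conditions.items() if cond in DAY12_CONDITIONS
    ]
    if not means:
        raise ValueError(f"{rs.variant_id}: no day-12 conditions to score")
    return min(means)


def roc_curve(controls: Sequence[ControlVariant]) -> RocResult:
    """ROC over score cutoffs, where a LOWER score predicts pathogenic.

    AUC by the trapezoid rule. Requires at least one control of each truth.
    """
    truths = {c.truth for c in controls}
    if truths != {"benign", "pathogenic"}:
        raise ValueError("ROC requires at least one benign and one pathogenic control")
    y = np.array([1 if c.truth == "pathogenic" else 0 for c in controls])
    # Negate so that higher transformed score = more pathogenic.
    score = -np.array([c.calibration_score for c in controls], dtype=float)
    fpr, tpr, thr = _sk_roc_curve(y, score)
    roc_auc = float(_auc(fpr, tpr))
    j = tpr - fpr
    best = int(np.argmax(j))
    return RocResult(
        fpr=tuple(fpr.tolist()),
        tpr=tuple(tpr.tolist()),
        thresholds=tuple((-thr).tolist()),
        auc=roc_auc,
        youden_cutoff=float(-thr[best]),
    )


def wilson_interval(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    For ``successes == trials`` the lower bound reduces to the closed form
    n / (n + z²).
    """
    if trials < 1:
        raise ValueError("trials must be ≥ 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must be in [0, trials]")
    lower, upper = proportion_confint(successes, trials, alpha=1 - confidence, method="wilson")
    return float(lower), float(upper)


def compute_oddspath(
    path_abnormal: int,
    path_normal: int,
    benign_abnormal: int,
    benign_normal: int,
) -> tuple[float, float, float, float, float]:
    """OddsPath for the abnormal and normal readout classes.

    Inputs are the 2×2 control confusion matrix. P1 is the pathogenic
    proportion among all controls (the prior); P2 is the pathogenic
    proportion within a readout class (the posterior). When a readout class
    contains only one truth, one hypothetical opposite-truth control is
    added to that class before computing P2 — the calibration framework's
    correction for perfect assays.

    Returns ``(oddspath_pathogenic, oddspath_benign, p1, p2_abnormal,
    p2_normal)``.
    """
    n_path = path_abnormal + path_normal
    n_benign = benign_abnormal + benign_normal
    if n_path < 1 or n_benign < 1:
        raise ValueError("need at least one pathogenic and one benign control")
    if path_abnormal + benign_abnormal == 0:
        raise ValueError("abnormal readout class is empty")
    if path_normal + benign_normal == 0:
        raise ValueError("normal readout class is empty")

    # Counts are integers, so the odds are rational; exact arithmetic avoids
    # round-off on quantities that are compared against published values.
    p1 = Fraction(n_path, n_path + n_benign)

    def corrected_p2(n_path_in_class: int, n_benign_in_class: int) -> Fraction:
        if n_benign_in_class == 0:
            n_benign_in_class = 1
        elif n_path_in_class == 0:
            n_path_in_class = 1
        return Fraction(n_path_in_class, n_path_in_class + n_benign_in_class)

    p2_abnormal = corrected_p2(path_abnormal, benign_abnormal)
    p2_normal = corrected_p2(path_normal, benign_normal)

    def odds(p2: Fraction) -> float:
        return float((p2 * (1 - p1)) / ((1 - p2) * p1))

    return (
        odds(p2_abnormal),
        odds(p2_normal),
        float(p1),
        float(p2_abnormal),
        float(p2_normal),
    )


def strength_from_oddspath(value: float, direction: str) -> str:
    """Map an OddsPath value to PS3 (pathogenic) or BS3 (benign) strength."""
    if value <= 0:
        raise ValueError(f"OddsPath must be positive, got {value}")
    if direction == "pathogenic":
        for cut, strength in _PATHOGENIC_CUTPOINTS:
            if value >= cut:
                return strength
        return "indeterminate"
    if direction == "benign":
        for cut, strength in _BENIGN_CUTPOINTS:
            if value <= cut:
                return strength
        return "indeterminate"
    raise ValueError(f"direction must be pathogenic|benign, got {direction!r}")


def calibrate(
    controls: Sequence[ControlVariant],
    threshold_deleterious: float = THRESHOLD_DELETERIOUS,
    threshold_neutral: float = THRESHOLD_NEUTRAL,
    confidence: float = 0.95,
) -> CalibrationResult:
    """Full calibration from a control set at the given thresholds.

    Binary readout for the confusion matrix: abnormal = score ≤ the
    deleterious threshold; normal otherwise (intermediate scores count as
    normal readout for sensitivity/specificity and OddsPath purposes).
    Risk-allele-role variants must already be excluded from ``controls``.
    """
    if not 0 < threshold_deleterious < threshold_neutral:
        raise ValueError("need 0 < threshold_deleterious < threshold_neutral")
    roc = roc_curve(controls)

    path = [c for c in controls if c.truth == "pathogenic"]
    benign = [c for c in controls if c.truth == "benign"]
    path_abn = sum(c.calibration_score <= threshold_deleterious for c in path)
    ben_abn = sum(c.calibration_score <= threshold_deleterious for c in benign)
    path_norm = len(path) - path_abn
    ben_norm = len(benign) - ben_abn

    sensitivity = path_abn / len(path)
    specificity = ben_norm / len(benign)
    sens_ci = wilson_interval(path_abn, len(path), confidence)
    spec_ci = wilson_interval(ben_norm, len(benign), confidence)

    op_path, op_benign, p1, p2_abn, p2_norm = compute_oddspath(
        path_abn, path_norm, ben_abn, ben_norm
    )
    return CalibrationResult(
        threshold_deleterious=threshold_deleterious,
        threshold_neutral=threshold_neutral,
        auc=roc.auc,
        sensitivity=sensitivity,
        specificity=specificity,
        sens_ci=sens_ci,
        spec_ci=spec_ci,
        oddspath_pathogenic=op_path,
        oddspath_benign=op_benign,
        p1_prior=p1,
        p2_abnormal=p2_abn,
        p2_normal=p2_norm,
        ps3_strength=strength_from_oddspath(op_path, "pathogenic"),
        bs3_strength=strength_from_oddspath(op_benign, "benign"),
        n_pathogenic=len(path),
        n_benign=len(benign),
    )
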