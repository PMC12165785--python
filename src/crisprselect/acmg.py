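"""ACMG/AMP evidence codes and their combination into a 5-tier class.

Implements the subset of evidence codes usable for rare variants assayed by
the competitive knockin screen, following ClinGen BRCA1/2 VCEP practice:

* PS3/BS3 — functional-assay evidence, at the OddsPath-calibrated strength
  (supplied by :mod:`crisprselect.functional`);
* PM2/BA1/BS1 — population-frequency banding on the filter allele frequency
  (FAF, maximum over the five gnomAD nonfounder populations) and minor
  allele frequency (MAF);
* PP3/BP4 — computational evidence from BayesDel_noAF and the SpliceAI
  delta-score maximum;
* PS1(Splicing) and PVS1(RNA) — splicing codes asserted externally (from
  ClinVar/LOVD precedent and minigene assay results respectively) and
  passed through with mutual-exclusion rules.

Codes are combined twice: by the point-based system (supporting = ±1,
moderate = ±2, strong = ±4, very strong = ±8, indeterminate = 0; class
boundaries benign ≤ −7, likely benign −6..−2, uncertain −1..5, likely
pathogenic 6..9, pathogenic ≥ 10) and by the original 2015 qualitative
combining rules. The final call requires concordance; discordant systems
yield "uncertain" with a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "STRENGTHS",
    "PATHOGENIC_POINTS",
    "CLASSES",
    "EvidenceCode",
    "VariantAnnotation",
    "ClassificationResult",
    "points_for",
    "population_code",
    "computational_code",
    "apply_asserted_splicing_codes",
    "assemble_codes",
    "combine_points",
    "combine_qualitative",
    "classify_variant",
    "write_annotation_table",
    "read_annotation_table",
]

STRENGTHS = ("indeterminate", "supporting", "moderate", "strong", "very_strong")

PATHOGENIC_POINTS = {
    "indeterminate": 0,
    "supporting": 1,
    "moderate": 2,
    "strong": 4,
    "very_strong": 8,
}

CLASSES = ("benign", "likely_benign", "uncertain", "likely_pathogenic", "pathogenic")

# Population-frequency bands (FAF = filter allele frequency; MAF = minor
# allele frequency), per the BRCA1/2 VCEP recommendations.
BA1_FAF = 0.001
BS1_FAF = 0.0001
BS1_SUPPORTING_FAF = 0.00002
PM2_MAF = 0.00002

# Computational-evidence cutoffs on the precomputed annotation scores.
PP3_SPLICEAI = 0.2
PP3_BAYESDEL = 0.30
BP4_SPLICEAI = 0.1
BP4_BAYESDEL = 0.18


@dataclass(frozen=True)
class EvidenceCode:
    """One applied ACMG/AMP code instance."""

    code_id: str
    direction: str  # pathogenic | benign | stand_alone_benign
    strength: str
    points: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.strength not in STRENGTHS:
            raise ValueError(f"unknown strength {self.strength!r}")
        if self.direction not in ("pathogenic", "benign", "stand_alone_benign"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.points is None:
            object.__setattr__(
                self, "points", points_for(self.code_id, self.direction, self.strength)
            )


@dataclass(frozen=True)
class VariantAnnotation:
    """Externally supplied per-variant annotations.

    ``faf_max``/``maf_max`` are maxima over the five nonfounder gnomAD
    populations; ``None`` means absent from controls. ``asserted_codes``
    carries externally justified splicing codes as (code_id, strength)
    pairs, e.g. ``("PVS1_RNA", "strong")`` from a minigene assay.
    """

    variant_id: str
    role: str = "query"  # control_benign | control_pathogenic | query | risk_allele
    prior_classification: Optional[str] = None
    faf_max: Optional[float] = None
    maf_max: Optional[float] = None
    bayesdel_noaf: Optional[float] = None
    spliceai_delta: Optional[float] = None
    asserted_codes: tuple = ()

    def __post_init__(self) -> None:
        for name in ("faf_max", "maf_max", "spliceai_delta"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {val}")


@dataclass(frozen=True)
class ClassificationResult:
    variant_id: str
    applied_codes: tuple
    point_total: int
    point_class: str
    qualitative_class: str
    final_class: str
    discordant: bool


def write_annotation_table(annotations: Iterable[VariantAnnotation], path) -> None:
    """Serialize annotations as TSV; asserted codes as ``code:strength`` pairs
    joined by ``;``; absent values as empty fields."""
    import pandas as pd

    rows = []
    for ann in annotations:
        rows.append(
            {
                "variant_id": ann.variant_id,
                "role": ann.role,
                "prior_classification": ann.prior_classification or "",
                "faf_max": "" if ann.faf_max is None else repr(ann.faf_max),
                "maf_max": "" if ann.maf_max is None else repr(ann.maf_max),
                "bayesdel_noaf": "" if ann.bayesdel_noaf is None else repr(ann.bayesdel_noaf),
                "spliceai_delta": "" if ann.spliceai_delta is None else repr(ann.spliceai_delta),
                "asserted_codes": ";".join(f"{c}:{s}" for c, s in ann.asserted_codes),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation_table(path) -> list[VariantAnnotation]:
    """Inverse of :func:`write_annotation_table`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    def opt_float(v: str):
        return float(v) if v != "" else None

    out = []
    for _, rec in df.iterrows():
        asserted = tuple(
            tuple(pair.split(":", 1)) for pair in rec["asserted_codes"].split(";") if pair
        )
        out.append(
            VariantAnnotation(
                variant_id=rec["variant_id"],
                role=rec["role"],
                prior_classification=rec["prior_classification"] or None,
                faf_max=opt_float(rec["faf_max"]),
                maf_max=opt_float(rec["maf_max"]),
                bayesdel_noaf=opt_float(rec["bayesdel_noaf"]),
                spliceai_delta=opt_float(rec["spliceai_delta"]),
                asserted_codes=asserted,
            )
        )
    return out


def points_for(code_id: str, direction: str, strength: str) -> int:
    """Integer points for a code at a given strength; benign codes negate."""
    if strength not in PATHOGENIC_POINTS:
        raise ValueError(f"unknown strength {strength!r}")
    base = PATHOGENIC_POINTS[strength]
    if direction in ("benign", "stand_alone_benign"):
        return -base
    if direction == "pathogenic":
        return base
    raise ValueError(f"unknown direction {direction!r}")


def population_code(ann: VariantAnnotation) -> EvidenceCode:
    """Assign exactly one population-frequency code from the FAF/MAF bands.

    BA1 (FAF > 0.001) is stand-alone benign; BS1 and BS1-supporting cover
    the next two FAF bands; PM2-indeterminate covers observed-but-very-rare
    variants (MAF ≤ 2e-5); a variant absent from controls earns
    PM2-supporting.
    """
    faf = ann.faf_max
    if faf is not None:
        if faf > BA1_FAF:
            return EvidenceCode("BA1", "stand_alone_benign", "very_strong")
        if faf > BS1_FAF:
            return EvidenceCode("BS1", "benign", "strong")
        if faf > BS1_SUPPORTING_FAF:
            return EvidenceCode("BS1", "benign", "supporting")
    maf = ann.maf_max
    if maf is not None and maf > 0:
        # Observed but very rare (the band tops out at MAF 2e-5; a larger
        # MAF that still escaped the FAF bands is treated the same way):
        # zero-weight evidence either direction.
        return EvidenceCode("PM2", "pathogenic", "indeterminate")
    # Absent in population controls.
    return EvidenceCode("PM2", "pathogenic", "supporting")


def computational_code(
    ann: VariantAnnotation, pvs1_asserted: bool = False
) -> Optional[EvidenceCode]:
    """PP3/BP4 from SpliceAI and BayesDel, or ``None`` in the gap zone.

    PP3 requires SpliceAI ≥ 0.2 or BayesDel ≥ 0.30; BP4 requires SpliceAI
    ≤ 0.1 and BayesDel ≤ 0.18. PP3 is suppressed when PVS1(RNA) is asserted
    for the same variant, since the splicing impact is then counted by the
    stronger RNA-assay code.
    """
    spliceai = ann.spliceai_delta
    bayesdel = ann.bayesdel_noaf
    if spliceai is None or bayesdel is None:
        return None
    if spliceai >= PP3_SPLICEAI or bayesdel >= PP3_BAYESDEL:
        if pvs1_asserted:
            return None
        return EvidenceCode("PP3", "pathogenic", "supporting")
    if spliceai <= BP4_SPLICEAI and bayesdel <= BP4_BAYESDEL:
        return EvidenceCode("BP4", "benign", "supporting")
    return None


def apply_asserted_splicing_codes(ann: VariantAnnotation) -> list[EvidenceCode]:
    """Pass through externally asserted splicing codes, enforcing exclusions.

    PVS1(RNA) subsumes PS1(Splicing): when both are asserted for one
    variant, PS1 is dropped with a warning.
    """
    asserted = {code_id: strength for code_id, strength in ann.asserted_codes}
    out: list[EvidenceCode] = []
    if "PVS1_RNA" in asserted:
        out.append(EvidenceCode("PVS1_RNA", "pathogenic", asserted["PVS1_RNA"]))
        if "PS1_splicing" in asserted:
            warnings.warn(
                f"{ann.variant_id}: PS1_splicing dropped because PVS1_RNA is asserted",
                stacklevel=2,
            )
    elif "PS1_splicing" in asserted:
        out.append(EvidenceCode("PS1_splicing", "pathogenic", asserted["PS1_splicing"]))
    return out


def assemble_codes(
    functional_code: Optional[EvidenceCode], ann: VariantAnnotation
) -> list[EvidenceCode]:
    """Collect all applicable codes for one variant, exclusions applied."""
    codes: list[EvidenceCode] = []
    if functional_code is not None:
        codes.append(functional_code)
    codes.append(population_code(ann))
    splicing = apply_asserted_splicing_codes(ann)
    pvs1 = any(c.code_id == "PVS1_RNA" for c in splicing)
    comp = computational_code(ann, pvs1_asserted=pvs1)
    if comp is not None:
        codes.append(comp)
    codes.extend(splicing)
    return codes


def _point_class(total: int) -> str:
    if total <= -7:
        return "benign"
    if total <= -2:
        return "likely_benign"
    if total <= 5:
        return "uncertain"
    if total <= 9:
        return "likely_pathogenic"
    return "pathogenic"


def combine_points(codes: Iterable[EvidenceCode]) -> tuple[int, str]:
    """Sum code points and map onto the 5-tier point scale.

    BA1 is stand-alone: any bundle containing it is benign regardless of
    the sum.
    """
    codes = list(codes)
    total = sum(c.points for c in codes)
    if any(c.code_id == "BA1" for c in codes):
        return total, "benign"
    return total, _point_class(total)


# --- qualitative (2015) combining rules -----------------------------------

def _strength_counts(codes: Sequence[EvidenceCode]):
    """Count pathogenic codes per strength tier and benign codes.

    Moderate-strength benign codes have no slot in the 2015 rules; they are
    counted as two benign-supporting, matching common VCEP practice.
    Indeterminate-strength codes are ignored.
    """
    n_vs = n_s = n_m = n_p = 0
    n_bs = n_bp = 0
    stand_alone = False
    for c in codes:
        if c.strength == "indeterminate":
            continue
        if c.direction == "stand_alone_benign":
            stand_alone = True
        elif c.direction == "pathogenic":
            if c.strength == "very_strong":
                n_vs += 1
            elif c.strength == "strong":
                n_s += 1
            elif c.strength == "moderate":
                n_m += 1
            else:
                n_p += 1
        else:  # benign
            if c.strength in ("strong", "very_strong"):
                n_bs += 1
            elif c.strength == "moderate":
                n_bp += 2
            else:
                n_bp += 1
    return stand_alone, n_vs, n_s, n_m, n_p, n_bs, n_bp


def combine_qualitative(codes: Iterable[EvidenceCode]) -> str:
    """The 2015 qualitative combining rules over the implemented codes.

    Pathogenic: 1 very strong with (≥1 strong | ≥2 moderate | 1 moderate +
    1 supporting | ≥2 supporting); or ≥2 strong; or 1 strong with
    (≥3 moderate | 2 moderate + ≥2 supporting | 1 moderate + ≥4 supporting).
    Likely pathogenic: 1 very strong + 1 moderate; 1 strong + 1–2 moderate;
    1 strong + ≥2 supporting; ≥3 moderate; 2 moderate + ≥2 supporting;
    1 moderate + ≥4 supporting.
    Benign: BA1 alone, or ≥2 strong benign. Likely benign: 1 strong benign
    + 1 supporting benign, or ≥2 supporting benign.
    Both a pathogenic and a benign rule satisfied → uncertain.
    """
    stand_alone, n_vs, n_s, n_m, n_p, n_bs, n_bp = _strength_counts(list(codes))

    if stand_alone:
        return "benign"

    pathogenic = (
        (n_vs >= 1 and (n_s >= 1 or n_m >= 2 or (n_m == 1 and n_p >= 1) or n_p >= 2))
        or n_s >= 2
        or (n_s == 1 and (n_m >= 3 or (n_m == 2 and n_p >= 2) or (n_m == 1 and n_p >= 4)))
    )
    likely_pathogenic = (
        (n_vs == 1 and n_m == 1)
        or (n_s == 1 and 1 <= n_m <= 2)
        or (n_s == 1 and n_p >= 2)
        or n_m >= 3
        or (n_m == 2 and n_p >= 2)
        or (n_m == 1 and n_p >= 4)
    )
    benign = n_bs >= 2
    likely_benign = (n_bs == 1 and n_bp >= 1) or n_bp >= 2

    path_call = pathogenic or likely_pathogenic
    benign_call = benign or likely_benign
    if path_call and benign_call:
        return "uncertain"
    if pathogenic:
        return "pathogenic"
    if likely_pathogenic:
        return "likely_pathogenic"
    if benign:
        return "benign"
    if likely_benign:
        return "likely_benign"
    return "uncertain"


def classify_variant(
    functional_code: Optional[EvidenceCode], ann: VariantAnnotation
) -> ClassificationResult:
    """Assemble all codes and classify by both systems.

    The final class is the shared class when the point-based and
    qualitative systems agree, else ``uncertain`` with ``discordant=True``.
    """
    codes = assemble_codes(functional_code, ann)
    point_total, point_class = combine_points(codes)
    qualitative_class = combine_qualitative(codes)
    if point_class == qualitative_class:
        final, discordant = point_class, False
    else:
        final, discordant = "uncertain", True
    return ClassificationResult(
        variant_id=ann.variant_id,
        applied_codes=tuple(codes),
        point_total=point_total,
        point_class=point_class,
        qualitative_class=qualitative_class,
        final_class=final,
        discordant=discordant,
    )
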