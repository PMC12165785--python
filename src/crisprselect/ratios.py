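"""Variant/WT' and frameshift/WT' ratio computation and normalization.

The functional score of the assay is the read-count ratio of the
variant-edited allele to the synonymous internal-control (WT') allele,
normalized so that the day-2 baseline of the same replicate equals 100%.
A variant with no fitness effect stays near 100% at day 12; a deleterious
variant is depleted relative to WT' and falls below it.

Normalization is performed per replicate and replicates are aggregated
afterwards to mean ± sample SD — never by pooling counts across replicates.
The same machinery applied with the frameshift-indel class in the numerator
yields the internal null-effect control series, which must show depletion
(frameshift alleles knock out the gene) for a run to be trusted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .ingest import ALL_CONDITIONS, DAY2, DAY12_CONDITIONS, SampleCounts

__all__ = [
    "WTPrimeZeroError",
    "ConditionStats",
    "RatioSeries",
    "compute_ratio",
    "normalize_to_day2",
    "aggregate_replicates",
    "build_ratio_series",
    "frameshift_selection_report",
    "ratio_table",
]

Numerator = Literal["variant", "frameshift"]


class WTPrimeZeroError(ZeroDivisionError):
    """WT' read count is zero: the ratio is undefined and the sample must be
    flagged rather than silently dropped."""


@dataclass(frozen=True)
class ConditionStats:
    """Replicate-level normalized ratios for one condition, with summary."""

    values: tuple  # normalized percent per replicate, replicate order
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class RatioSeries:
    """Per-condition normalized ratio percentages for one variant.

    ``conditions`` maps condition name to :class:`ConditionStats`; day 2 is
    identically 100% per replicate by construction. ``raw_day2_ratios``
    keeps the unnormalized day-2 ratios per replicate for provenance.
    """

    variant_id: str
    numerator: str
    conditions: Mapping[str, ConditionStats]
    raw_day2_ratios: Mapping[str, float] = field(default_factory=dict)

    def day12_means(self) -> dict[str, float]:
        return {
            cond: stats.mean
            for cond, stats in self.conditions.items()
            if cond in DAY12_CONDITIONS
        }


def compute_ratio(sc: SampleCounts, numerator: Numerator = "variant") -> float:
    """Numerator-class reads divided by WT' reads for one sample."""
    if sc.wtprime_reads == 0:
        raise WTPrimeZeroError(
            f"{sc.variant_id}/{sc.condition}/{sc.replicate_id}: WT' reads are zero"
        )
    num = sc.variant_reads if numerator == "variant" else sc.frameshift_reads
    return num / sc.wtprime_reads


def normalize_to_day2(day2_ratio: float, dayx_ratio: float) -> float:
    """Express a ratio as a percentage of the same replicate's day-2 ratio."""
    if day2_ratio <= 0:
        raise ValueError(f"day-2 ratio must be positive, got {day2_ratio}")
    return 100.0 * dayx_ratio / day2_ratio


def aggregate_replicates(values: Sequence[float]) -> tuple[float, float, int]:
    """Arithmetic mean and sample SD (n−1 denominator) over replicates.

    A single replicate yields SD 0 with a warning: the spread is undefined
    and the result should not be reported as a replicate summary.
    """
    n = len(values)
    if n == 0:
        raise ValueError("no replicate values to aggregate")
    mean = sum(values) / n
    if n == 1:
        warnings.warn("single replicate: SD undefined, reported as 0", stacklevel=2)
        return mean, 0.0, 1
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var), n


def build_ratio_series(
    samples: Iterable[SampleCounts], numerator: Numerator = "variant"
) -> RatioSeries:
    """Normalize each day-12 sample to its replicate's day-2 baseline.

    ``samples`` holds all {condition, replicate} samples of one variant.
    Replicates lacking a day-2 sample are an error; conditions are reported
    only for replicates present in both the baseline and that arm.
    """
    samples = list(samples)
    variant_ids = {sc.variant_id for sc in samples}
    if len(variant_ids) != 1:
        raise ValueError(f"samples span multiple variants: {sorted(variant_ids)}")
    (variant_id,) = variant_ids

    day2 = {sc.replicate_id: sc for sc in samples if sc.condition == DAY2}
    if not day2:
        raise ValueError(f"{variant_id}: no day-2 baseline samples")
    day2_ratios = {rep: compute_ratio(sc, numerator) for rep, sc in day2.items()}

    per_condition: dict[str, ConditionStats] = {}
    reps_sorted = sorted(day2_ratios)
    # Day 2 normalizes to itself: identically 100 per replicate.
    day2_values = tuple(
        normalize_to_day2(day2_ratios[rep], day2_ratios[rep]) for rep in reps_sorted
    )
    mean, sd, n = aggregate_replicates(day2_values)
    per_condition[DAY2] = ConditionStats(day2_values, mean, sd, n)

    for cond in DAY12_CONDITIONS:
        cond_samples = {sc.replicate_id: sc for sc in samples if sc.condition == cond}
        if not cond_samples:
            continue
        values = []
        for rep in sorted(cond_samples):
            if rep not in day2_ratios:
                raise ValueError(f"{variant_id}/{cond}/{rep}: no matching day-2 baseline")
            values.append(
                normalize_to_day2(day2_ratios[rep], compute_ratio(cond_samples[rep], numerator))
            )
        mean, sd, n = aggregate_replicates(values)
        per_condition[cond] = ConditionStats(tuple(values), mean, sd, n)

    return RatioSeries(
        variant_id=variant_id,
        numerator=numerator,
        conditions=per_condition,
        raw_day2_ratios=dict(sorted(day2_ratios.items())),
    )


def frameshift_selection_report(fs: RatioSeries, k: float = 2.0) -> dict[str, str]:
    """Flag each day-12 arm as depleted / not_depleted for the frameshift
    internal control.

    Frameshift alleles disrupt the gene, so their normalized ratio must fall
    under negative selection; an arm is ``depleted`` when its mean lies
    below 100 − k·SD. This is a run-level QC gate, not a variant call.
    """
    report = {}
    for cond, stats in fs.conditions.items():
        if cond == DAY2:
            continue
        depleted = stats.mean < 100.0 - k * stats.sd
        report[cond] = "depleted" if depleted else "not_depleted"
    return report


def ratio_table(series: Iterable[RatioSeries]) -> pd.DataFrame:
    """Long-format summary table: one row per variant × condition."""
    rows = []
    for rs in series:
        for cond in ALL_CONDITIONS:
            stats = rs.conditions.get(cond)
            if stats is None:
                continue
            rows.append(
                {
                    "variant_id": rs.variant_id,
                    "numerator": rs.numerator,
                    "condition": cond,
                    "n_replicates": stats.n,
                    "mean_percent": stats.mean,
                    "sd_percent": stats.sd,
                    "replicate_values": ";".join(f"{v:.4f}" for v in stats.values),
                }
            )
    return pd.DataFrame(rows)
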