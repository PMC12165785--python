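"""Synthetic variant panels and allele-count tables.

This module emulates the count structure of the competitive knockin
experiment so the whole downstream pipeline is testable without the
deposited sequencing data. For each variant it simulates a day-2 baseline
plus four day-12 arms (untreated, PARPi, cisplatin, MMC) over ≥ 3
replicates, drawing the four read classes (variant, WT', frameshift,
other) multinomially per sample.

Selection is parameterized directly by the target normalized ratio — the
measurand itself — rather than by a per-generation fitness, so the
generator's ground truth is exactly the quantity the pipeline estimates:
for each day-12 arm the variant class fraction is rescaled so that

    E[(variant/WT')_day12 / (variant/WT')_day2] = true_normalized_ratio / 100,

with the WT' fraction held at its day-2 value in expectation (WT' is the
neutral internal reference by design) and the frameshift fraction
multiplied by a day-12 retention factor (< 1 encodes the negative
selection against gene-disrupting indels). Replicate-to-replicate spread
is a multiplicative mean-one log-normal factor on the variant fraction,
parameterized by its coefficient of variation.

What this generator does NOT emulate: sequencing error, PCR jackpots,
alignment ambiguity, or variant-specific editing-efficiency differences
beyond the configurable day-2 class fractions.
"""

from __future__ import annotations

import math
import re
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .acmg import VariantAnnotation
from .ingest import ALL_CONDITIONS, DAY2, DAY12_CONDITIONS, EditDefinition, SampleCounts

__all__ = [
    "DEFAULT_DAY2_FRACTIONS",
    "TrueEffectProfile",
    "SimulationConfig",
    "PanelVariant",
    "SimplexError",
    "generate_variant_panel",
    "make_edit_definition",
    "simulate_counts",
    "simulate_panel",
    "write_allele_tables",
]

#: Day-2 class fractions (variant, WT', frameshift, other). The source
#: experiments do not report HDR incorporation fractions; these defaults
#: put each knockin allele at ~12% and CRISPR by-product indels at 25%,
#: typical of ssODN-templated editing with an efficient guide.
DEFAULT_DAY2_FRACTIONS = (0.12, 0.12, 0.25, 0.51)

_AMPLICON_LENGTH = 80
_EDIT_POS = 40      # variant substitution offset within the amplicon
_WTPRIME_POS = 43   # synonymous internal-control substitution offset
_BASES = np.array(list("ACGT"))


class SimplexError(ValueError):
    """Rescaled class fractions left the probability simplex — the effect
    profile is mis-specified (e.g. ratio too large for the day-2 fractions)."""


@dataclass(frozen=True)
class TrueEffectProfile:
    """Ground-truth effect of one variant, on the scale of the measurand.

    ``true_normalized_ratio`` holds the target normalized variant/WT' ratio
    (percent) per day-12 condition; 100 means no effect, 0 means complete
    loss of the variant-edited population.
    """

    variant_id: str
    true_normalized_ratio: Mapping[str, float]
    day2_hdr_fractions: tuple = DEFAULT_DAY2_FRACTIONS
    replicate_cv: float = 0.1

    def __post_init__(self) -> None:
        missing = set(DAY12_CONDITIONS) - set(self.true_normalized_ratio)
        if missing:
            raise ValueError(f"{self.variant_id}: missing conditions {sorted(missing)}")
        for cond, ratio in self.true_normalized_ratio.items():
            if not 0 <= ratio <= 150:
                raise ValueError(f"{self.variant_id}/{cond}: ratio {ratio} outside [0, 150]")
        fr = self.day2_hdr_fractions
        if len(fr) != 4 or any(f < 0 for f in fr) or sum(fr) > 1 + 1e-12:
            raise ValueError(f"{self.variant_id}: day-2 fractions must be ≥0 and sum to ≤1")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be ≥ 0")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_reads_per_sample: int = 10_000
    n_replicates: int = 3
    frameshift_day12_retention: float = 0.2

    def __post_init__(self) -> None:
        if self.n_reads_per_sample < 1:
            raise ValueError("n_reads_per_sample must be ≥ 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be ≥ 1")
        if not 0 <= self.frameshift_day12_retention <= 1:
            raise ValueError("frameshift_day12_retention must be in [0, 1]")


@dataclass(frozen=True)
class PanelVariant:
    annotation: VariantAnnotation
    profile: TrueEffectProfile

    @property
    def variant_id(self) -> str:
        return self.annotation.variant_id


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return 1.0
    sigma2 = math.log1p(cv * cv)
    return float(rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2)))


def _variant_rng(seed: int, variant_id: str) -> np.random.Generator:
    # crc32 gives a stable (non-salted) per-variant stream offset.
    return np.random.default_rng([seed, zlib.crc32(variant_id.encode())])


def simulate_counts(profile: TrueEffectProfile, cfg: SimulationConfig) -> list[SampleCounts]:
    """Simulate classified read counts for every {condition, replicate}.

    One multinomial draw of ``n_reads_per_sample`` reads per sample, after
    applying the per-sample noise factor to the variant fraction and the
    arm-specific rescaling described in the module docstring. Deterministic
    given (profile, cfg).
    """
    rng = _variant_rng(cfg.seed, profile.variant_id)
    f_var, f_wt, f_fs, _ = profile.day2_hdr_fractions
    retention = cfg.frameshift_day12_retention
    out: list[SampleCounts] = []
    for rep in range(1, cfg.n_replicates + 1):
        rep_id = f"rep{rep}"
        for cond in ALL_CONDITIONS:
            if cond == DAY2:
                fv, ff = f_var, f_fs
            else:
                fv = f_var * profile.true_normalized_ratio[cond] / 100.0
                ff = f_fs * retention
            fv *= _lognormal_factor(rng, profile.replicate_cv)
            f_other = 1.0 - (fv + f_wt + ff)
            if f_other < 0:
                raise SimplexError(
                    f"{profile.variant_id}/{cond}: class fractions sum to {fv + f_wt + ff:.4f} > 1"
                )
            counts = rng.multinomial(cfg.n_reads_per_sample, [fv, f_wt, ff, f_other])
            out.append(
                SampleCounts(
                    variant_id=profile.variant_id,
                    condition=cond,
                    replicate_id=rep_id,
                    variant_reads=int(counts[0]),
                    wtprime_reads=int(counts[1]),
                    frameshift_reads=int(counts[2]),
                    other_reads=int(counts[3]),
                )
            )
    return out


def simulate_panel(
    panel: Sequence[PanelVariant], cfg: SimulationConfig
) -> dict[str, list[SampleCounts]]:
    """Simulate every panel variant; per-variant streams are independent."""
    return {pv.variant_id: simulate_counts(pv.profile, cfg) for pv in panel}


# --- panel generation ------------------------------------------------------

def _draw_ratios(rng: np.random.Generator, lo: float, hi: float) -> dict[str, float]:
    return {cond: float(rng.uniform(lo, hi)) for cond in DAY12_CONDITIONS}


def _benign_like_annotations(rng: np.random.Generator) -> dict:
    return {
        "bayesdel_noaf": float(rng.uniform(0.0, 0.15)),
        "spliceai_delta": float(rng.uniform(0.0, 0.08)),
    }


def generate_variant_panel(
    n_benign_controls: int,
    n_pathogenic_controls: int,
    n_query: int,
    seed: int,
    query_strata: tuple = (0.80, 0.06, 0.14),
    splice_fraction_deleterious: float = 0.5,
    replicate_cv: float = 0.1,
    day2_hdr_fractions: tuple = DEFAULT_DAY2_FRACTIONS,
) -> list[PanelVariant]:
    """Generate a variant panel with role labels, effects and annotations.

    Benign controls behave neutrally in every arm (true ratio > 50%);
    pathogenic controls are strongly depleted in every arm (≤ 25%). Query
    variants are drawn from neutral / intermediate / deleterious strata
    with weights ``query_strata``. Intermediate queries are hypomorphic:
    neutral untreated but 25–50% under the drug arms. A configurable
    fraction of deleterious queries are "splice-region"-like: depleted
    only in the MMC arm, carrying a high splicing-impact score and an
    asserted same-consequence splicing code — the rest are missense-like
    and keep a benign-leaning in-silico score (mirroring the discordance
    between functional impact and metapredictor scores seen in this
    domain).

    Deterministic: the same arguments produce an identical panel.
    """
    for name, n in (
        ("n_benign_controls", n_benign_controls),
        ("n_pathogenic_controls", n_pathogenic_controls),
        ("n_query", n_query),
    ):
        if n < 0:
            raise ValueError(f"{name} must be ≥ 0, got {n}")
    if not math.isclose(sum(query_strata), 1.0, abs_tol=1e-9):
        raise ValueError("query_strata must sum to 1")

    rng = np.random.default_rng(seed)
    panel: list[PanelVariant] = []
    pos = 28  # synthetic HGVS coordinates, one position per variant

    def next_id() -> str:
        nonlocal pos
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        vid = f"c.{pos}{ref}>{alt}"
        pos += 1
        return vid

    def add(role: str, ratios: dict, ann_fields: dict) -> None:
        vid = next_id()
        ann = VariantAnnotation(variant_id=vid, role=role, **ann_fields)
        profile = TrueEffectProfile(
            variant_id=vid,
            true_normalized_ratio=ratios,
            day2_hdr_fractions=day2_hdr_fractions,
            replicate_cv=replicate_cv,
        )
        panel.append(PanelVariant(ann, profile))

    for _ in range(n_benign_controls):
        faf = float(10 ** rng.uniform(-4.0, -2.5))
        add(
            "control_benign",
            _draw_ratios(rng, 70, 110),
            {
                "prior_classification": "benign",
                "faf_max": faf,
                "maf_max": min(1.0, faf * 1.2),
                **_benign_like_annotations(rng),
            },
        )

    for _ in range(n_pathogenic_controls):
        add(
            "control_pathogenic",
            _draw_ratios(rng, 1, 18),
            {
                "prior_classification": "pathogenic",
                # Absent from population controls; in-silico score stays in
                # the benign band — functional truth and metapredictors can
                # disagree in this domain.
                "bayesdel_noaf": float(rng.uniform(0.02, 0.18)),
                "spliceai_delta": float(rng.uniform(0.0, 0.08)),
            },
        )

    strata = np.array(query_strata)
    for _ in range(n_query):
        stratum = rng.choice(3, p=strata)
        if stratum == 0:  # neutral
            ann = dict(_benign_like_annotations(rng))
            if rng.uniform() < 0.5:
                ann["maf_max"] = float(rng.uniform(1e-6, 2e-5))
            add("query", _draw_ratios(rng, 60, 110), ann)
        elif stratum == 1:  # intermediate / hypomorphic
            ratios = {"day12_untreated": float(rng.uniform(60, 100))}
            for cond in DAY12_CONDITIONS[1:]:
                ratios[cond] = float(rng.uniform(28, 48))
            add("query", ratios, _benign_like_annotations(rng))
        else:  # deleterious
            if rng.uniform() < splice_fraction_deleterious:
                ratios = {cond: float(rng.uniform(60, 100)) for cond in DAY12_CONDITIONS[:-1]}
                ratios["day12_mmc"] = float(rng.uniform(5, 20))
                add(
                    "query",
                    ratios,
                    {
                        "bayesdel_noaf": float(rng.uniform(0.0, 0.15)),
                        "spliceai_delta": float(rng.uniform(0.3, 0.9)),
                        "asserted_codes": (("PS1_splicing", "moderate"),),
                    },
                )
            else:
                add(
                    "query",
                    _draw_ratios(rng, 2, 18),
                    {
                        "bayesdel_noaf": float(rng.uniform(0.02, 0.18)),
                        "spliceai_delta": float(rng.uniform(0.0, 0.08)),
                    },
                )
    return panel


def make_edit_definition(variant_id: str, seed: int = 0) -> EditDefinition:
    """Deterministic synthetic amplicon triplet for one variant."""
    rng = _variant_rng(seed, variant_id)
    ref = "".join(rng.choice(_BASES, size=_AMPLICON_LENGTH))

    def substitute(seq: str, pos: int) -> str:
        alt = rng.choice([b for b in "ACGT" if b != seq[pos]])
        return seq[:pos] + alt + seq[pos + 1 :]

    return EditDefinition(
        variant_id=variant_id,
        reference_amplicon=ref,
        variant_amplicon=substitute(ref, _EDIT_POS),
        wtprime_amplicon=substitute(ref, _WTPRIME_POS),
    )


def _sanitize(variant_id: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "_", variant_id)


def write_allele_tables(
    samples: Iterable[SampleCounts],
    edit_defs: Mapping[str, EditDefinition],
    out_dir: Path,
) -> pd.DataFrame:
    """Emit one tab-delimited allele table per sample, plus a manifest.

    Each table carries four rows: the variant amplicon, the WT' amplicon,
    one frameshift allele (a 2-nt deletion at the cut site, net indel not
    divisible by three) and the unedited reference. Ingesting and
    classifying these files reproduces the input counts exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for sc in samples:
        edits = edit_defs[sc.variant_id]
        fs_seq = edits.reference_amplicon[:_EDIT_POS] + edits.reference_amplicon[_EDIT_POS + 2 :]
        table = pd.DataFrame(
            {
                "Aligned_Sequence": [
                    edits.variant_amplicon,
                    edits.wtprime_amplicon,
                    fs_seq,
                    edits.reference_amplicon,
                ],
                "Reads": [
                    sc.variant_reads,
                    sc.wtprime_reads,
                    sc.frameshift_reads,
                    sc.other_reads,
                ],
                "n_inserted": [0, 0, 0, 0],
                "n_deleted": [0, 0, 2, 0],
            }
        )
        fname = f"{_sanitize(sc.variant_id)}__{sc.condition}__{sc.replicate_id}.tsv"
        table.to_csv(out_dir / fname, sep="\t", index=False)
        records.append(
            {
                "file": fname,
                "variant_id": sc.variant_id,
                "condition": sc.condition,
                "replicate_id": sc.replicate_id,
                "total_reads": sc.total_reads,
            }
        )
    manifest = pd.DataFrame(
        records, columns=["file", "variant_id", "condition", "replicate_id", "total_reads"]
    )
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
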