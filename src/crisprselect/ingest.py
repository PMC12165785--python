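"""Allele-count table ingestion and read classification.

The competitive knockin assay sequences an amplicon spanning the edited
locus. An upstream aligner (CRISPResso2-style) reduces each sample's reads
to an allele table: one row per distinct aligned sequence with its read
count and the number of inserted/deleted bases relative to the reference
amplicon. This module parses those tables and partitions every read into
one of four classes:

``variant``
    exact match to the expected variant-edited amplicon,
``wtprime``
    exact match to the synonymous internal-control (WT') amplicon,
``frameshift``
    any other allele whose net indel length is not a multiple of three,
``other``
    everything else — unedited reference reads, in-frame indels and
    substitution-only mismatches.

Classification is exact-match by design: fuzzy placement of reads onto the
reference belongs to the upstream aligner, which has already emitted aligned
allele strings. Exactness keeps the partition bit-for-bit reproducible.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

__all__ = [
    "DAY2",
    "DAY12_CONDITIONS",
    "ALL_CONDITIONS",
    "EditDefinition",
    "AlleleRow",
    "SampleCounts",
    "QCResult",
    "SchemaError",
    "parse_allele_table",
    "classify_alleles",
    "qc_check",
    "MIN_READS_DEFAULT",
]

DAY2 = "day2"
DAY12_CONDITIONS = ("day12_untreated", "day12_parpi", "day12_cisplatin", "day12_mmc")
ALL_CONDITIONS = (DAY2,) + DAY12_CONDITIONS

#: QC floor on per-sample read depth.
MIN_READS_DEFAULT = 7500

REQUIRED_COLUMNS = ("Aligned_Sequence", "Reads", "n_inserted", "n_deleted")

_DNA = set("ACGT")


class SchemaError(ValueError):
    """Input table does not conform to the expected allele-table dialect."""


@dataclass(frozen=True)
class EditDefinition:
    """Expected amplicon sequences for one variant's editing outcomes.

    The variant and WT' single-stranded oligo templates produce two distinct
    edited amplicons; reads matching neither are CRISPR by-products or
    unedited cells.
    """

    variant_id: str
    reference_amplicon: str
    variant_amplicon: str
    wtprime_amplicon: str

    def __post_init__(self) -> None:
        seqs = {
            "reference_amplicon": self.reference_amplicon,
            "variant_amplicon": self.variant_amplicon,
            "wtprime_amplicon": self.wtprime_amplicon,
        }
        for name, seq in seqs.items():
            if not seq:
                raise ValueError(f"{name} must be non-empty for {self.variant_id!r}")
            if not set(seq) <= _DNA:
                raise ValueError(f"{name} contains non-ACGT characters for {self.variant_id!r}")
        if len({self.reference_amplicon, self.variant_amplicon, self.wtprime_amplicon}) != 3:
            raise ValueError(
                f"reference, variant and WT' amplicons must be pairwise distinct for {self.variant_id!r}"
            )


@dataclass(frozen=True)
class AlleleRow:
    sequence: str
    reads: int
    n_inserted: int
    n_deleted: int

    def __post_init__(self) -> None:
        if self.reads < 0 or self.n_inserted < 0 or self.n_deleted < 0:
            raise ValueError("reads and indel counts must be non-negative")


@dataclass(frozen=True)
class SampleCounts:
    """Classified read counts for one {variant, condition, replicate} sample."""

    variant_id: str
    condition: str
    replicate_id: str
    variant_reads: int
    wtprime_reads: int
    frameshift_reads: int
    other_reads: int

    def __post_init__(self) -> None:
        if self.condition not in ALL_CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        for field in ("variant_reads", "wtprime_reads", "frameshift_reads", "other_reads"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be non-negative")

    @property
    def total_reads(self) -> int:
        return self.variant_reads + self.wtprime_reads + self.frameshift_reads + self.other_reads


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reason: Union[str, None] = None


def parse_allele_table(source: Union[str, Path, io.IOBase]) -> list[AlleleRow]:
    """Parse a tab-delimited allele table into :class:`AlleleRow` records.

    Expects columns ``Aligned_Sequence``, ``Reads``, ``n_inserted`` and
    ``n_deleted``. Raises :class:`SchemaError` on a missing column,
    non-integer counts, or an empty file.
    """
    try:
        df = pd.read_csv(source, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError("allele table is empty") from exc

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"allele table missing required column(s): {', '.join(missing)}")

    rows: list[AlleleRow] = []
    for idx, rec in df.iterrows():
        try:
            reads = int(rec["Reads"])
            n_ins = int(rec["n_inserted"])
            n_del = int(rec["n_deleted"])
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"non-integer count in allele table row {idx}") from exc
        rows.append(
            AlleleRow(
                sequence=str(rec["Aligned_Sequence"]).strip().upper(),
                reads=reads,
                n_inserted=n_ins,
                n_deleted=n_del,
            )
        )
    return rows


def is_frameshift(n_inserted: int, n_deleted: int) -> bool:
    """A net indel length not divisible by three shifts the reading frame."""
    return (n_inserted - n_deleted) % 3 != 0


def classify_alleles(
    rows: Iterable[AlleleRow],
    edits: EditDefinition,
    condition: str,
    replicate_id: str,
) -> SampleCounts:
    """Partition every allele row into variant / WT' / frameshift / other.

    Exact sequence identity decides the two edited classes; the remaining
    rows are split by reading-frame status of their net indel. Rows equal to
    the unedited reference amplicon land in ``other`` (unedited cells).
    Read totals are conserved by construction.
    """
    variant = wtprime = frameshift = other = 0
    for row in rows:
        if row.sequence == edits.variant_amplicon:
            variant += row.reads
        elif row.sequence == edits.wtprime_amplicon:
            wtprime += row.reads
        elif is_frameshift(row.n_inserted, row.n_deleted):
            frameshift += row.reads
        else:
            other += row.reads
    return SampleCounts(
        variant_id=edits.variant_id,
        condition=condition,
        replicate_id=replicate_id,
        variant_reads=variant,
        wtprime_reads=wtprime,
        frameshift_reads=frameshift,
        other_reads=other,
    )


def write_edit_definitions(edits: Iterable[EditDefinition], path: Union[str, Path]) -> None:
    """Write edit definitions as a TSV (one row per variant)."""
    df = pd.DataFrame(
        [
            {
                "variant_id": e.variant_id,
                "reference_amplicon": e.reference_amplicon,
                "variant_amplicon": e.variant_amplicon,
                "wtprime_amplicon": e.wtprime_amplicon,
            }
            for e in edits
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_edit_definitions(path: Union[str, Path]) -> dict[str, EditDefinition]:
    """Read a TSV of edit definitions keyed by variant id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"variant_id", "reference_amplicon", "variant_amplicon", "wtprime_amplicon"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"edit-definition table missing column(s): {', '.join(sorted(missing))}")
    out: dict[str, EditDefinition] = {}
    for _, rec in df.iterrows():
        e = EditDefinition(
            variant_id=rec["variant_id"],
            reference_amplicon=rec["reference_amplicon"].strip().upper(),
            variant_amplicon=rec["variant_amplicon"].strip().upper(),
            wtprime_amplicon=rec["wtprime_amplicon"].strip().upper(),
        )
        out[e.variant_id] = e
    return out


def qc_check(sc: SampleCounts, min_reads: int = MIN_READS_DEFAULT) -> QCResult:
    """Depth gate: a sample needs at least ``min_reads`` total reads.

    Failed samples are excluded from ratio analysis by the pipeline and
    recorded in the run manifest.
    """
    if sc.total_reads < min_reads:
        return QCResult(
            passed=False,
            reason=(
                f"{sc.variant_id}/{sc.condition}/{sc.replicate_id}: "
                f"{sc.total_reads} reads < required {min_reads}"
            ),
        )
    return QCResult(passed=True)
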