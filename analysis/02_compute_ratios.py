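"""Ingest the simulated allele tables and compute normalized ratios.

Classifies every allele row into variant / WT' / frameshift / other,
applies the 7,500-read QC floor, normalizes each day-12 variant/WT' ratio
to its replicate's day-2 baseline (= 100%) and aggregates replicates to
mean +/- SD. The same computation with the frameshift class in the
numerator yields the internal null-effect control, which must be depleted
in every arm for the run to be trusted.
"""

import pandas as pd

from crisprselect import ingest, ratios

from pathlib import Path

BASE = Path(__file__).resolve().parent.parent / "results"
IN = BASE / "01_simulated"
OUT = BASE / "02_ratios"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    edit_defs = ingest.read_edit_definitions(IN / "edit_definitions.tsv")
    manifest = pd.read_csv(IN / "manifest.tsv", sep="\t", dtype=str)

    by_variant: dict[str, list] = {}
    n_failed = 0
    for _, rec in manifest.iterrows():
        rows = ingest.parse_allele_table(IN / rec["file"])
        sc = ingest.classify_alleles(
            rows, edit_defs[rec["variant_id"]], rec["condition"], rec["replicate_id"]
        )
        if not ingest.qc_check(sc).passed:
            n_failed += 1
            continue
        by_variant.setdefault(sc.variant_id, []).append(sc)

    variant_series = [ratios.build_ratio_series(s, "variant") for s in by_variant.values()]
    fs_series = [ratios.build_ratio_series(s, "frameshift") for s in by_variant.values()]
    ratios.ratio_table(variant_series).to_csv(OUT / "ratios.tsv", sep="\t", index=False)
    ratios.ratio_table(fs_series).to_csv(OUT / "frameshift_ratios.tsv", sep="\t", index=False)

    pooled: dict[str, list] = {}
    for rs in fs_series:
        for cond, stats in rs.conditions.items():
            if cond != ingest.DAY2:
                pooled.setdefault(cond, []).extend(stats.values)
    run_stats = {
        cond: ratios.ConditionStats(tuple(v), *ratios.aggregate_replicates(v))
        for cond, v in pooled.items()
    }
    flags = ratios.frameshift_selection_report(
        ratios.RatioSeries("__run__", "frameshift", run_stats)
    )

    print(f"{len(by_variant)} variants, {n_failed} samples failed the 7,500-read QC floor")
    print("frameshift internal control:", flags)
    print(f"wrote {OUT / 'ratios.tsv'} and {OUT / 'frameshift_ratios.tsv'}")


if __name__ == "__main__":
    main()
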