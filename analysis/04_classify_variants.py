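"""Classify every panel variant by both ACMG/AMP combining systems.

Categorizes each day-12 arm (deleterious <= 25% < intermediate <= 50% <
neutral), derives the single PS3/BS3 functional code at the calibrated
strength, assembles the population (PM2/BA1/BS1), computational (PP3/BP4)
and asserted splicing codes, and combines them by the point-based and the
qualitative 2015 systems; a reportable call requires concordance.
"""

import json
from pathlib import Path

import pandas as pd

from crisprselect import acmg, functional
from crisprselect.ingest import DAY12_CONDITIONS

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    annotations = {
        ann.variant_id: ann
        for ann in acmg.read_annotation_table(BASE / "01_simulated" / "annotations.tsv")
    }
    calib = json.loads((BASE / "03_calibration.json").read_text())
    df = pd.read_csv(BASE / "02_ratios" / "ratios.tsv", sep="\t")
    day12 = df[df["condition"].isin(DAY12_CONDITIONS)]

    rows = []
    class_counts: dict[str, int] = {}
    for vid, grp in day12.groupby("variant_id"):
        categories = {
            rec["condition"]: functional.categorize(rec["mean_percent"])
            for _, rec in grp.iterrows()
        }
        code = functional.assign_functional_code(
            categories, vid, ps3_strength=calib["ps3_strength"], bs3_strength=calib["bs3_strength"]
        )
        res = acmg.classify_variant(code, annotations[vid])
        rows.append(
            {
                "variant_id": vid,
                "role": annotations[vid].role,
                "applied_codes": ";".join(
                    f"{c.code_id}:{c.strength}:{c.points:+d}" for c in res.applied_codes
                ),
                "point_total": res.point_total,
                "point_class": res.point_class,
                "qualitative_class": res.qualitative_class,
                "final_class": res.final_class,
                "discordant": res.discordant,
            }
        )
        if annotations[vid].role == "query":
            class_counts[res.final_class] = class_counts.get(res.final_class, 0) + 1

    out = BASE / "04_classifications.tsv"
    pd.DataFrame(rows).sort_values("variant_id").to_csv(out, sep="\t", index=False)
    n_classified = sum(v for k, v in class_counts.items() if k != "uncertain")
    n_query = sum(class_counts.values())
    print(f"query classifications: {class_counts}")
    print(f"classified {n_classified} of {n_query} query variants")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
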