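"""Calibrate the assay from the control variants.

Takes each control's worst-case score (minimum replicate-mean normalized
ratio over the four day-12 arms), runs ROC analysis, estimates
sensitivity/specificity with Wilson 95% CIs at the 25%/50% thresholds,
computes OddsPath for both readout classes, and maps the OddsPath values
to PS3/BS3 evidence strengths.
"""

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from crisprselect import acmg, calibration
from crisprselect.ingest import DAY12_CONDITIONS

BASE = Path(__file__).resolve().parent.parent / "results"


def control_scores(ratio_tsv: Path, annotations) -> list[calibration.ControlVariant]:
    df = pd.read_csv(ratio_tsv, sep="\t")
    day12 = df[df["condition"].isin(DAY12_CONDITIONS)]
    scores = day12.groupby("variant_id")["mean_percent"].min()
    controls = []
    for ann in annotations:
        if ann.role == "control_benign":
            controls.append(calibration.ControlVariant(ann.variant_id, "benign", scores[ann.variant_id]))
        elif ann.role == "control_pathogenic":
            controls.append(
                calibration.ControlVariant(ann.variant_id, "pathogenic", scores[ann.variant_id])
            )
    return controls


def main() -> None:
    annotations = acmg.read_annotation_table(BASE / "01_simulated" / "annotations.tsv")
    controls = control_scores(BASE / "02_ratios" / "ratios.tsv", annotations)
    calib = calibration.calibrate(controls)
    out = BASE / "03_calibration.json"
    out.write_text(json.dumps(asdict(calib), indent=2, sort_keys=True) + "\n")

    print(f"{calib.n_pathogenic} pathogenic + {calib.n_benign} benign controls, AUC {calib.auc:.3f}")
    print(
        f"sensitivity {calib.sensitivity:.0%} (95% CI {calib.sens_ci[0]:.1%}-{calib.sens_ci[1]:.0%}), "
        f"specificity {calib.specificity:.0%} (95% CI {calib.spec_ci[0]:.1%}-{calib.spec_ci[1]:.0%})"
    )
    print(
        f"OddsPath: {calib.oddspath_pathogenic:g} (pathogenic) / "
        f"{calib.oddspath_benign:.3f} (benign) -> PS3 {calib.ps3_strength}, BS3 {calib.bs3_strength}"
    )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
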