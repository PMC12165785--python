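"""End-to-end orchestration: counts → ratios → calibration → classification.

``run_pipeline`` chains the stages behind one reproducible entry point
driven by a key-value configuration::

    mode: simulate            # or: ingest
    seed: 1                   # simulate mode; drives every random draw
    out_dir: results/run1
    simulate:
      n_benign_controls: 9
      n_pathogenic_controls: 14
      n_query: 54
      n_reads_per_sample: 10000
      n_replicates: 3
      frameshift_day12_retention: 0.2
      replicate_cv: 0.1
    ingest:                   # ingest mode only
      allele_table_dir: path/with/manifest.tsv
      edit_definitions: edits.tsv
      annotations: annotations.tsv
    min_reads: 7500
    thresholds: {deleterious: 25.0, neutral: 50.0}
    confidence: 0.95
    frameshift_k: 2.0

In simulate mode the panel is generated, written as allele tables, and
read back through the same ingest path used for real data, so the whole
pipeline is exercised end to end. Samples under the read-depth floor are
excluded (a failed day-2 baseline drops its whole replicate) and logged in
the run manifest, which also records the config snapshot, seed, input and
output checksums, and the frameshift internal-control flags.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import acmg, calibration, functional, ingest, ratios, synthetic

__all__ = ["ConfigError", "StageError", "RunManifest", "PipelineResult", "run_pipeline"]


class ConfigError(ValueError):
    """The run configuration does not validate against the schema."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and offender."""


@dataclass(frozen=True)
class RunManifest:
    config: dict
    seed: Optional[int]
    input_checksums: dict
    output_checksums: dict
    qc_failed_samples: tuple
    frameshift_flags: dict
    n_variants: int
    class_counts: dict


@dataclass(frozen=True)
class PipelineResult:
    manifest: RunManifest
    ratio_series: dict
    frameshift_series: dict
    calibration: calibration.CalibrationResult
    functional_calls: dict
    classifications: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(config: dict, key: str, stage: str = "config"):
    if key not in config:
        raise ConfigError(f"{stage}: missing required key {key!r}")
    return config[key]


def _validate_config(config: dict) -> None:
    mode = _require(config, "mode")
    if mode not in ("simulate", "ingest"):
        raise ConfigError(f"mode must be simulate|ingest, got {mode!r}")
    _require(config, "out_dir")
    if mode == "simulate":
        _require(config, "seed")
        _require(config, "simulate")
    else:
        sub = _require(config, "ingest")
        for key in ("allele_table_dir", "edit_definitions", "annotations"):
            _require(sub, key, stage="ingest")


def _ingest_tables(
    table_dir: Path, edit_defs: dict
) -> list[ingest.SampleCounts]:
    manifest_path = table_dir / "manifest.tsv"
    if not manifest_path.exists():
        raise StageError(f"ingest: no manifest.tsv under {table_dir}")
    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str)
    samples = []
    for _, rec in manifest.iterrows():
        rows = ingest.parse_allele_table(table_dir / rec["file"])
        samples.append(
            ingest.classify_alleles(
                rows, edit_defs[rec["variant_id"]], rec["condition"], rec["replicate_id"]
            )
        )
    return samples


def run_pipeline(config: dict) -> PipelineResult:
    """Run every stage and write all outputs under ``config['out_dir']``.

    Idempotent for a fixed config and seed: rerunning produces
    byte-identical outputs.
    """
    _validate_config(config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    min_reads = int(config.get("min_reads", ingest.MIN_READS_DEFAULT))
    thresholds = config.get("thresholds", {})
    thr_del = float(thresholds.get("deleterious", calibration.THRESHOLD_DELETERIOUS))
    thr_neu = float(thresholds.get("neutral", calibration.THRESHOLD_NEUTRAL))
    confidence = float(config.get("confidence", 0.95))
    fs_k = float(config.get("frameshift_k", 2.0))

    # --- stage: simulate | ingest -----------------------------------------
    input_checksums: dict = {}
    if config["mode"] == "simulate":
        seed = int(config["seed"])
        sim = config["simulate"]
        panel = synthetic.generate_variant_panel(
            n_benign_controls=int(sim.get("n_benign_controls", 9)),
            n_pathogenic_controls=int(sim.get("n_pathogenic_controls", 14)),
            n_query=int(sim.get("n_query", 54)),
            seed=seed,
            replicate_cv=float(sim.get("replicate_cv", 0.1)),
        )
        cfg = synthetic.SimulationConfig(
            seed=seed,
            n_reads_per_sample=int(sim.get("n_reads_per_sample", 10_000)),
            n_replicates=int(sim.get("n_replicates", 3)),
            frameshift_day12_retention=float(sim.get("frameshift_day12_retention", 0.2)),
        )
        sim_dir = out_dir / "simulated"
        edit_defs = {pv.variant_id: synthetic.make_edit_definition(pv.variant_id, seed) for pv in panel}
        all_samples = [
            sc for pv in panel for sc in synthetic.simulate_counts(pv.profile, cfg)
        ]
        synthetic.write_allele_tables(all_samples, edit_defs, sim_dir)
        ingest.write_edit_definitions(edit_defs.values(), sim_dir / "edit_definitions.tsv")
        acmg.write_annotation_table((pv.annotation for pv in panel), sim_dir / "annotations.tsv")
        table_dir = sim_dir
        annotations = {pv.variant_id: pv.annotation for pv in panel}
    else:
        seed = None
        sub = config["ingest"]
        table_dir = Path(sub["allele_table_dir"])
        edit_defs = ingest.read_edit_definitions(sub["edit_definitions"])
        annotations = {
            ann.variant_id: ann for ann in acmg.read_annotation_table(sub["annotations"])
        }
        for key in ("edit_definitions", "annotations"):
            input_checksums[str(sub[key])] = _sha256(Path(sub[key]))

    input_checksums[str(table_dir / "manifest.tsv")] = _sha256(table_dir / "manifest.tsv")
    samples = _ingest_tables(table_dir, edit_defs)

    # --- stage: QC ---------------------------------------------------------
    qc_failures = []
    passing = []
    for sc in samples:
        res = ingest.qc_check(sc, min_reads)
        (passing if res.passed else qc_failures).append((sc, res.reason))
    failed_day2 = {
        (sc.variant_id, sc.replicate_id)
        for sc, _ in qc_failures
        if sc.condition == ingest.DAY2
    }
    # A failed day-2 baseline invalidates its whole replicate.
    kept = [
        sc
        for sc, _ in passing
        if (sc.variant_id, sc.replicate_id) not in failed_day2
    ]

    by_variant: dict[str, list] = {}
    for sc in kept:
        by_variant.setdefault(sc.variant_id, []).append(sc)

    # --- stage: ratios ------------------------------------------------------
    ratio_series: dict[str, ratios.RatioSeries] = {}
    fs_series: dict[str, ratios.RatioSeries] = {}
    for vid, vsamples in by_variant.items():
        try:
            ratio_series[vid] = ratios.build_ratio_series(vsamples, "variant")
            fs_series[vid] = ratios.build_ratio_series(vsamples, "frameshift")
        except (ValueError, ratios.WTPrimeZeroError) as exc:
            raise StageError(f"ratios: {vid}: {exc}") from exc

    ratios.ratio_table(ratio_series.values()).to_csv(out_dir / "ratios.tsv", sep="\t", index=False)
    ratios.ratio_table(fs_series.values()).to_csv(
        out_dir / "frameshift_ratios.tsv", sep="\t", index=False
    )

    # Run-level frameshift internal control: pool per-replicate normalized
    # frameshift/WT' values across variants per arm.
    pooled: dict[str, list] = {}
    for rs in fs_series.values():
        for cond, stats in rs.conditions.items():
            if cond == ingest.DAY2:
                continue
            pooled.setdefault(cond, []).extend(stats.values)
    pooled_stats = {
        cond: ratios.ConditionStats(tuple(vals), *ratios.aggregate_replicates(vals))
        for cond, vals in pooled.items()
    }
    run_fs = ratios.RatioSeries("__run__", "frameshift", pooled_stats)
    frameshift_flags = ratios.frameshift_selection_report(run_fs, k=fs_k)

    # --- stage: calibrate ---------------------------------------------------
    controls = []
    for vid, rs in ratio_series.items():
        ann = annotations.get(vid)
        if ann is None or ann.role not in ("control_benign", "control_pathogenic"):
            continue
        truth = "benign" if ann.role == "control_benign" else "pathogenic"
        controls.append(
            calibration.ControlVariant(vid, truth, calibration.calibration_score(rs))
        )
    try:
        calib = calibration.calibrate(controls, thr_del, thr_neu, confidence)
    except ValueError as exc:
        raise StageError(f"calibrate: {exc}") from exc
    (out_dir / "calibration.json").write_text(
        json.dumps(asdict(calib), indent=2, sort_keys=True) + "\n"
    )

    # --- stage: score (functional interpretation) ---------------------------
    functional_calls = {
        vid: functional.score_variant(
            rs, thr_del, thr_neu, ps3_strength=calib.ps3_strength, bs3_strength=calib.bs3_strength
        )
        for vid, rs in ratio_series.items()
    }
    func_rows = []
    for vid, call in sorted(functional_calls.items()):
        row = {"variant_id": vid}
        for cond in ingest.DAY12_CONDITIONS:
            row[cond] = call.categories.get(cond, "")
        row["code"] = call.code.code_id if call.code else "not_assessable"
        row["strength"] = call.code.strength if call.code else ""
        func_rows.append(row)
    pd.DataFrame(func_rows).to_csv(out_dir / "functional_calls.tsv", sep="\t", index=False)

    # --- stage: classify ----------------------------------------------------
    classifications = {}
    for vid, call in functional_calls.items():
        ann = annotations.get(vid)
        if ann is None:
            raise StageError(f"classify: {vid}: no annotation record")
        classifications[vid] = acmg.classify_variant(call.code, ann)

    cls_rows = []
    for vid, res in sorted(classifications.items()):
        cls_rows.append(
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
    cls_df = pd.DataFrame(cls_rows)
    cls_df.to_csv(out_dir / "classifications.tsv", sep="\t", index=False)

    # --- stage: report ------------------------------------------------------
    query_ids = [vid for vid, ann in annotations.items() if ann.role == "query"]
    class_counts = {cls: 0 for cls in acmg.CLASSES}
    for vid in query_ids:
        if vid in classifications:
            class_counts[classifications[vid].final_class] += 1

    report = {
        "n_variants": len(ratio_series),
        "n_queries": len(query_ids),
        "class_counts_queries": class_counts,
        "calibration": asdict(calib),
        "frameshift_flags": frameshift_flags,
        "qc_failed_samples": [reason for _, reason in qc_failures],
        "per_variant": {
            vid: {
                "final_class": res.final_class,
                "point_total": res.point_total,
                "discordant": res.discordant,
            }
            for vid, res in sorted(classifications.items())
        },
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    output_checksums = {
        name: _sha256(out_dir / name)
        for name in (
            "ratios.tsv",
            "frameshift_ratios.tsv",
            "calibration.json",
            "functional_calls.tsv",
            "classifications.tsv",
            "report.json",
        )
    }
    manifest = RunManifest(
        config=config,
        seed=seed,
        input_checksums=input_checksums,
        output_checksums=output_checksums,
        qc_failed_samples=tuple(reason for _, reason in qc_failures),
        frameshift_flags=frameshift_flags,
        n_variants=len(ratio_series),
        class_counts=class_counts,
    )
    (out_dir / "run_manifest.json").write_text(
        json.dumps(asdict(manifest), indent=2, sort_keys=True, default=str) + "\n"
    )
    return PipelineResult(
        manifest=manifest,
        ratio_series=ratio_series,
        frameshift_series=fs_series,
        calibration=calib,
        functional_calls=functional_calls,
        classifications=classifications,
    )
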