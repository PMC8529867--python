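"""End-to-end orchestration: ingest → lesion selection → texture extraction
→ aggregation → delta features → survival analysis → reports.

The disk interface is a manifest JSON listing lesions
(``[{patient_id, lesion_id, timepoint, image, roi}, ...]``, paths relative
to the manifest) plus a clinical CSV
(``patient_id, ldh_pre, ldh_post, n_sites, os_months, os_event,
pfs_months, pfs_event``).  Reports are plain CSV/JSON; the config and seed
are serialized next to them so every number is traceable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate, imaging, survival, texture
from .config import PipelineConfig

log = logging.getLogger("deltarad")


class PipelineError(RuntimeError):
    pass


@dataclass
class ValidationReport:
    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def _load_manifest(config: PipelineConfig) -> list[dict]:
    path = Path(config.manifest)
    if not path.exists():
        raise PipelineError(f"manifest not found: {path}")
    entries = json.loads(path.read_text())
    root = path.parent
    for entry in entries:
        entry["_image_path"] = root / entry["image"]
        if isinstance(entry.get("roi"), str):
            entry["_roi_path"] = root / entry["roi"]
    return entries


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Check schema, id cross-references and timepoint pairing without
    mutating anything."""
    report = ValidationReport()
    try:
        entries = _load_manifest(config)
    except (PipelineError, json.JSONDecodeError, KeyError) as exc:
        report.fatal.append(f"manifest: {exc}")
        return report
    clinical_path = Path(config.clinical_csv)
    if not clinical_path.exists():
        report.fatal.append(f"clinical CSV not found: {clinical_path}")
        return report
    clinical = pd.read_csv(clinical_path)
    required = {
        "patient_id",
        "ldh_pre",
        "ldh_post",
        "n_sites",
        "os_months",
        "os_event",
        "pfs_months",
        "pfs_event",
    }
    missing_cols = required - set(clinical.columns)
    if missing_cols:
        report.fatal.append(f"clinical CSV missing columns: {sorted(missing_cols)}")
        return report

    by_patient: dict[str, dict[str, set[str]]] = {}
    for entry in entries:
        for key in ("patient_id", "lesion_id", "timepoint", "image", "roi"):
            if key not in entry:
                report.fatal.append(f"manifest entry missing {key!r}: {entry}")
                continue
        if entry["timepoint"] not in imaging.TIMEPOINTS:
            report.fatal.append(
                f"{entry.get('lesion_id')}: unknown timepoint {entry.get('timepoint')!r}"
            )
            continue
        by_patient.setdefault(entry["patient_id"], {}).setdefault(
            entry["timepoint"], set()
        ).add(entry["lesion_id"])
        img = entry.get("_image_path")
        if img is not None:
            if not img.exists():
                report.fatal.append(f"{entry['lesion_id']}: image file missing: {img}")
            elif img.suffix.lower() in (".png", ".txt") and not Path(
                str(img) + ".json"
            ).exists():
                report.fatal.append(
                    f"{entry['lesion_id']}: image {img.name} has no spacing sidecar"
                )
        roi = entry.get("_roi_path")
        if roi is not None and not roi.exists():
            report.fatal.append(f"{entry['lesion_id']}: ROI file missing: {roi}")

    for pid in clinical["patient_id"].astype(str):
        if pid not in by_patient or not by_patient[pid].get(imaging.BASELINE):
            report.fatal.append(f"patient {pid}: no baseline lesion in manifest")
    for pid, tps in by_patient.items():
        base = tps.get(imaging.BASELINE, set())
        post = tps.get(imaging.POST, set())
        for lesion in sorted(base - post):
            report.warnings.append(
                f"lesion {lesion} present only at baseline (excluded from delta)"
            )
        for lesion in sorted(post - base):
            report.warnings.append(
                f"lesion {lesion} present only post-therapy (excluded from delta)"
            )
    return report


def _entry_to_lesion(entry: dict, config: PipelineConfig) -> imaging.LesionRecord:
    image = imaging.read_slice(
        entry["_image_path"],
        patient_id=entry["patient_id"],
        timepoint=entry["timepoint"],
    )
    roi = entry.get("roi")
    if isinstance(roi, dict) and "polygon" in roi:
        mask = imaging.polygon_to_mask(roi["polygon"], image)
    else:
        mask = imaging.read_mask(entry["_roi_path"], image)
    if config.exclusion_window_enabled:
        mask = imaging.apply_exclusion_window(
            image,
            mask,
            config.exclusion_low_hu,
            config.exclusion_high_hu,
            lesion_id=entry["lesion_id"],
        )
    return imaging.make_lesion_record(image, mask, entry["lesion_id"])


def build_patient_table(config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Ingest manifest + clinical CSV into the analysis-ready patient table.

    Returns the table and a per-stage accounting dict mirroring the study's
    exclusion flow (patients in, ineligible, no matched lesion pair, out).
    """
    entries = _load_manifest(config)
    clinical = pd.read_csv(config.clinical_csv)
    clinical["patient_id"] = clinical["patient_id"].astype(str)

    lesions: dict[str, dict[str, list[imaging.LesionRecord]]] = {}
    for entry in entries:
        rec = _entry_to_lesion(entry, config)
        lesions.setdefault(entry["patient_id"], {}).setdefault(
            entry["timepoint"], []
        ).append(rec)

    counts = {
        "patients_in": int(clinical["patient_id"].nunique()),
        "patients_ineligible": 0,
        "patients_no_matched_pair": 0,
    }
    rows = []
    for _, crow in clinical.iterrows():
        pid = crow["patient_id"]
        tps = lesions.get(pid, {})
        try:
            base = imaging.select_target_lesions(
                tps.get(imaging.BASELINE, []),
                max_n=config.max_target_lesions,
                min_diameter_mm=config.min_diameter_mm,
            )
            post = imaging.select_target_lesions(
                tps.get(imaging.POST, []),
                max_n=config.max_target_lesions,
                min_diameter_mm=config.min_diameter_mm,
            )
        except imaging.PatientIneligibleError as exc:
            log.info("excluding patient %s: %s", pid, exc)
            counts["patients_ineligible"] += 1
            continue

        def extract(records):
            return [
                texture.extract_features(
                    rec,
                    scales_mm=config.scales_mm,
                    entropy_base=config.entropy_base,
                    kurtosis_convention=config.kurtosis_convention,
                    bin_before_stats=config.bin_before_stats,
                )
                for rec in records
            ]

        base_fv, post_fv = extract(base), extract(post)
        base_pf = aggregate.average_over_lesions(base_fv)
        try:
            delta = aggregate.aggregate_delta(
                base_fv, post_fv, convention=config.sign_convention
            )
        except aggregate.AggregationError as exc:
            log.info("excluding patient %s from delta: %s", pid, exc)
            counts["patients_no_matched_pair"] += 1
            continue
        row = dict(crow)
        row["n_lesions"] = base_pf.n_lesions
        row["n_matched"] = delta.n_matched
        row.update(base_pf.values.to_dict())
        row.update(delta.values.to_dict())
        rows.append(row)
    counts["patients_out"] = len(rows)
    if not rows:
        raise PipelineError("no patient survived lesion selection")
    return pd.DataFrame(rows), counts


def run_study(patient_table: pd.DataFrame, config: PipelineConfig) -> dict:
    """Run both endpoint analyses on an in-memory patient table."""
    reports = {}
    for endpoint in (survival.OS, survival.PFS):
        reports[endpoint] = survival.run_endpoint_analysis(
            patient_table,
            endpoint,
            uln=config.uln,
            k_folds=config.k_folds,
            seed=config.seed,
            sign_convention=config.sign_convention,
            fixed_cutoffs=config.km_fixed_cutoffs,
            report_markers_baseline=config.report_markers_baseline,
            report_markers_delta=config.report_markers_delta,
            min_events=config.min_events,
        )
    return reports


def write_reports(
    reports: dict, patient_table: pd.DataFrame, config: PipelineConfig, counts: dict | None = None
) -> Path:
    """Write CSV/JSON reports: Cox tables, KM tables, LASSO paths, the
    patient feature table, the config and the stage accounting."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.10g"

    os_rep, pfs_rep = reports[survival.OS], reports[survival.PFS]
    survival.cox_table(os_rep).to_csv(out / "table2_like.csv", index=False, float_format=float_fmt)
    survival.km_table(os_rep).to_csv(out / "table3_like.csv", index=False, float_format=float_fmt)
    survival.cox_table(pfs_rep).to_csv(out / "table4_like.csv", index=False, float_format=float_fmt)
    survival.km_table(pfs_rep).to_csv(out / "table5_like.csv", index=False, float_format=float_fmt)
    patient_table.to_csv(out / "patient_features.csv", index=False, float_format=float_fmt)

    lasso = {}
    for endpoint, rep in reports.items():
        for family, sel in (("baseline", rep.lasso_baseline), ("delta", rep.lasso_delta)):
            lasso[f"{endpoint}_{family}"] = {
                "lambda_grid": [float(v) for v in sel.lambda_grid],
                "chosen_lambda": sel.chosen_lambda,
                "cv_deviance": [float(v) for v in sel.cv_deviance],
                "selected": list(sel.selected),
                "best_feature": sel.best_feature,
                "coefficients": {
                    k: float(v) for k, v in sel.coefficients.items() if v != 0
                },
                "n_used": sel.n_used,
                "n_events": sel.n_events,
            }
    (out / "lasso_path.json").write_text(json.dumps(lasso, indent=1))
    config.to_yaml(out / "config.yaml")
    if counts is not None:
        (out / "stage_counts.json").write_text(json.dumps(counts, indent=1))
    notes = {ep: list(rep.notes) for ep, rep in reports.items()}
    (out / "notes.json").write_text(json.dumps(notes, indent=1))
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """The full disk-to-disk pipeline; deterministic given config + seed."""
    validation = validate_inputs(config)
    for message in validation.warnings:
        log.warning("%s", message)
    if not validation.ok:
        raise PipelineError("input validation failed:\n" + "\n".join(validation.fatal))
    patient_table, counts = build_patient_table(config)
    reports = run_study(patient_table, config)
    out = write_reports(reports, patient_table, config, counts)
    log.info("pipeline complete: %s (%s)", out, counts)
    return out
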