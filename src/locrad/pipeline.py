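"""End-to-end orchestration of the three study designs.

* ``run_biregional`` — two regions per patient (GTVrec vs GTVcontrol),
  cascade trained on the training cohort, validated on the held-out cohort.
* ``run_local_fixed_count`` — 8 octant sub-regions per patient, recurrence
  *detection* without location information, plus a per-patient summary of
  whether at least one truly recurrent sub-region was found and how much of
  the recurrence volume the detections cover.
* ``run_local_fixed_size_loocv`` — 5x5x5-cell sub-regions, leave-one-
  patient-out cross-validation (only patients with both sub-region classes).

All three share the identical preprocessing and feature extractor; every
report embeds the resolved configuration and seed, and every exclusion
(too-small region, single-class patient) is logged, never silent.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .imaging_io import ImageVolume, ROIMask, read_mask, read_volume
from .local_partition import (
    Partition,
    build_feature_table,
    label_subregions,
    partition_fixed_count,
    partition_fixed_size,
)
from .model_selection import (
    CascadeResult,
    apply_model,
    bootstrap_auc_ci,
    loocv_patient,
    rank_auc,
    run_cascade,
)
from .preprocessing import (
    MaskedVolume,
    apply_hu_window,
    derive_region_pair,
    remove_artifact_slices,
    resample_isotropic,
    resample_mask_isotropic,
)
from .texture_features import FEATURE_NAMES, SmallRegionError, extract_feature_vector

__all__ = [
    "PatientData",
    "load_cohort",
    "cohort_from_manifest",
    "prepare_patient",
    "extract_biregional_table",
    "extract_local_table",
    "run_biregional",
    "run_local_fixed_count",
    "run_local_fixed_size_loocv",
]

logger = logging.getLogger(__name__)


@dataclass
class PatientData:
    patient_id: str
    cohort: str  # train | validation
    image: ImageVolume
    gtv: ROIMask
    rec: ROIMask
    artifact_slices: tuple[int, ...] = ()


@dataclass
class PreparedPatient:
    patient_id: str
    cohort: str
    volume: MaskedVolume  # windowed image over the (resampled) GTV
    gtv: ROIMask  # analysable GTV voxels on the analysis grid
    gtvrec: ROIMask
    gtvcontrol: ROIMask


def load_cohort(cohort_dir) -> list[PatientData]:
    """Load a cohort written as NIfTI triplets + ``manifest.csv``."""
    manifest = pd.read_csv(os.path.join(cohort_dir, "manifest.csv"))
    return cohort_from_manifest(manifest)


def cohort_from_manifest(manifest: pd.DataFrame) -> list[PatientData]:
    """Accepts manifests holding either file paths or in-memory volumes."""
    patients = []
    for _, row in manifest.iterrows():
        if "image" in row and isinstance(row.get("image"), ImageVolume):
            image, gtv, rec = row["image"], row["gtv"], row["rec"]
        else:
            image = read_volume(row["image_path"])
            gtv = read_mask(row["gtv_path"], image)
            rec = read_mask(row["rec_path"], image)
        patients.append(
            PatientData(
                patient_id=str(row["patient_id"]),
                cohort=str(row.get("cohort", "train")),
                image=image,
                gtv=gtv,
                rec=rec,
            )
        )
    return patients


def prepare_patient(patient: PatientData, config: RunConfig) -> PreparedPatient:
    """Resample to the analysis grid, window, and derive the region pair.

    Artifact slices are cleared from the masks on the native grid, the image
    is resampled trilinearly and masks nearest-neighbour, then the HU window
    is applied over the GTV.  The analysable GTV (``gtv``) is the set of
    non-missing voxels — window-excluded voxels count as outside the ROI
    everywhere downstream.
    """
    gtv, rec = patient.gtv, patient.rec
    if patient.artifact_slices:
        gtv = remove_artifact_slices(gtv, patient.artifact_slices)
        rec = remove_artifact_slices(rec, patient.artifact_slices)
    image = resample_isotropic(patient.image, config.target_spacing)
    gtv = resample_mask_isotropic(gtv, config.target_spacing)
    rec = resample_mask_isotropic(rec, config.target_spacing)
    volume = apply_hu_window(image, gtv, config.window_low, config.window_high)
    analysable = volume.roi_mask()
    gtvrec, gtvcontrol = derive_region_pair(analysable, rec)
    return PreparedPatient(
        patient_id=patient.patient_id,
        cohort=patient.cohort,
        volume=volume,
        gtv=analysable,
        gtvrec=gtvrec,
        gtvcontrol=gtvcontrol,
    )


def _region_row(prep: PreparedPatient, mask: ROIMask, region_id: str, label: str, config: RunConfig):
    data = np.where(mask.data, prep.volume.data, np.nan)
    mv = MaskedVolume(data, prep.volume.spacing, prep.volume.window, prep.volume.origin)
    feats = extract_feature_vector(mv, config.bin_width, min_voxels=config.min_voxels)
    row = {
        "patient_id": prep.patient_id,
        "cohort": prep.cohort,
        "region_id": region_id,
        "label": label,
        "roi_voxel_count": mv.roi_voxel_count,
        "overlap_fraction": 1.0 if label == "recurrent" else 0.0,
    }
    row.update(feats)
    return row


def extract_biregional_table(patients, config: RunConfig) -> pd.DataFrame:
    """Two labelled rows (GTVrec, GTVcontrol) per patient.

    A patient whose GTVrec or GTVcontrol fails the 27-voxel minimum is
    dropped entirely (both rows), with a logged reason — mirroring the
    study's exclusion accounting.
    """
    rows = []
    for patient in patients:
        prep = prepare_patient(patient, config)
        try:
            pair = [
                _region_row(prep, prep.gtvrec, "gtvrec", "recurrent", config),
                _region_row(prep, prep.gtvcontrol, "gtvcontrol", "control", config),
            ]
        except SmallRegionError as exc:
            logger.info("patient %s dropped from bi-regional analysis: %s", patient.patient_id, exc)
            continue
        rows.extend(pair)
    meta = ["patient_id", "cohort", "region_id", "label", "roi_voxel_count", "overlap_fraction"]
    return pd.DataFrame(rows, columns=meta + list(FEATURE_NAMES))


def extract_local_table(patients, config: RunConfig, scheme: str) -> pd.DataFrame:
    """Sub-region feature table for one local scheme (fixed_count/fixed_size)."""
    tables = []
    for patient in patients:
        prep = prepare_patient(patient, config)
        if prep.gtv.voxel_count == 0:
            logger.info("patient %s dropped: empty analysable GTV", patient.patient_id)
            continue
        try:
            if scheme == "fixed_count":
                part = partition_fixed_count(prep.gtv, config.scheme_k)
            elif scheme == "fixed_size":
                part = partition_fixed_size(
                    prep.gtv, config.grid_size, config.grid_shift, config.grid_min_voxels
                )
            else:
                raise ValueError(f"unknown scheme {scheme!r}")
        except ValueError as exc:
            logger.info("patient %s dropped: %s", patient.patient_id, exc)
            continue
        part = label_subregions(part, prep.gtvrec, config.label_threshold)
        table = build_feature_table(
            prep.volume, part, patient_id=patient.patient_id, bin_width=config.bin_width
        )
        table.insert(1, "cohort", patient.cohort)
        tables.append(table)
    return pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()


def _evaluate_split(table, cascade: CascadeResult, config, rng) -> dict:
    from .model_selection import EvaluationResult

    y = (table["label"] == "recurrent").to_numpy()
    preds = apply_model(cascade.model, table)
    if 0 < y.sum() < y.size:
        ev = bootstrap_auc_ci(y, preds, config.bootstrap_replicates, rng=rng)
    else:
        logger.warning("split has a single class: AUC undefined, reported as NaN")
        nan = float("nan")
        ev = EvaluationResult(auc=nan, ci_low=nan, ci_high=nan)
    decided = preds >= cascade.cutoff
    pos, neg = y, ~y
    return {
        "auc": ev.auc,
        "ci_low": ev.ci_low,
        "ci_high": ev.ci_high,
        "sensitivity": float(decided[pos].mean()) if pos.any() else float("nan"),
        "specificity": float((~decided[neg]).mean()) if neg.any() else float("nan"),
        "n_rows": int(len(table)),
        "n_recurrent": int(y.sum()),
    }


def _split(table: pd.DataFrame):
    return (
        table[table["cohort"] == "train"].reset_index(drop=True),
        table[table["cohort"] == "validation"].reset_index(drop=True),
    )


def _model_dict(cascade: CascadeResult) -> dict:
    return {
        "features": list(cascade.model.features),
        "coefficients": list(cascade.model.coefficients),
        "intercept": cascade.model.intercept,
        "classification_cutoff": cascade.cutoff,
        "aic_path": cascade.aic_path,
        "retained_pc_count": cascade.selection.retained_pc_count,
        "n_excluded_by_voxel_correlation": len(
            cascade.selection.excluded_by_voxel_correlation
        ),
    }


def run_biregional(patients, config: RunConfig) -> dict:
    """Bi-regional differentiation: GTVrec vs GTVcontrol."""
    rng = np.random.default_rng(config.seed)
    table = extract_biregional_table(patients, config)
    train, val = _split(table)
    cascade = run_cascade(
        train, FEATURE_NAMES, config.r_max, config.p_max, config.cutoff_percentile, rng=rng
    )
    report = {
        "design": "biregional",
        "config": config.to_dict(),
        "model": _model_dict(cascade),
        "train": _evaluate_split(train, cascade, config, rng),
    }
    if len(val):
        report["validation"] = _evaluate_split(val, cascade, config, rng)
    return report


def _detection_summary(val: pd.DataFrame, preds: np.ndarray, cutoff: float) -> list[dict]:
    """Per validation patient: was any truly recurrent sub-region detected,
    and what fraction of the recurrence volume do the detections cover."""
    val = val.assign(_pred=preds)
    out = []
    for pid, grp in val.groupby("patient_id"):
        truly = grp["label"] == "recurrent"
        if not truly.any():
            continue
        detected = grp["_pred"] >= cutoff
        rec_voxels = grp["overlap_fraction"] * grp["roi_voxel_count"]
        total = float(rec_voxels.sum())
        covered = float(rec_voxels[detected].sum())
        out.append(
            {
                "patient_id": pid,
                "n_recurrent_subregions": int(truly.sum()),
                "any_detected": bool((detected & truly).any()),
                "detected_recurrence_fraction": covered / total if total > 0 else float("nan"),
            }
        )
    return out


def run_local_fixed_count(patients, config: RunConfig) -> dict:
    """Local detection with 8 octant sub-regions per patient."""
    rng = np.random.default_rng(config.seed)
    table = extract_local_table(patients, config, "fixed_count")
    train, val = _split(table)
    cascade = run_cascade(
        train, FEATURE_NAMES, config.r_max, config.p_max, config.cutoff_percentile, rng=rng
    )
    report = {
        "design": "local_fixed_count",
        "config": config.to_dict(),
        "model": _model_dict(cascade),
        "train": _evaluate_split(train, cascade, config, rng),
    }
    if len(val):
        report["validation"] = _evaluate_split(val, cascade, config, rng)
        preds = apply_model(cascade.model, val)
        report["detection"] = _detection_summary(val, preds, cascade.cutoff)
    return report


def run_local_fixed_size_loocv(patients, config: RunConfig) -> dict:
    """Local detection with fixed 5x5x5 cells, leave-one-patient-out CV."""
    rng = np.random.default_rng(config.seed)
    table = extract_local_table(patients, config, "fixed_size")
    result, folds = loocv_patient(
        table, FEATURE_NAMES, config.r_max, config.p_max, rng=rng
    )
    folds = folds.assign(
        small_fold=folds["n_subregions"] <= 2,
        high_involvement=folds["n_recurrent"] / folds["n_subregions"] > 0.25,
    )
    for _, row in folds[folds["small_fold"]].iterrows():
        logger.warning(
            "LOOCV fold %s: only %d held-out sub-volumes", row["patient_id"], row["n_subregions"]
        )
    return {
        "design": "local_fixed_size_loocv",
        "config": config.to_dict(),
        "mean_fold_auc": result.auc,
        "n_folds": int(len(folds)),
        "n_folds_below_chance": int((folds["auc"] < 0.5).sum()),
        "folds": folds.to_dict(orient="records"),
    }


def write_report(report: dict, path) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
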