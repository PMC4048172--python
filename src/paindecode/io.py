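"""Readers and writers for the pipeline's on-disk artifacts.

Volumes travel as NIfTI-1 (mask as an integer label volume with a JSON
sidecar for region names, contrasts as 3D float volumes), cohort tables as
CSV with the demographic column names of the study table, ground truth and
models/reports as JSON.  Affine agreement between a mask and any volume
read against it is enforced -- there is no silent resampling.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import GroundTruth, MaskVolume

__all__ = [
    "save_mask", "load_mask", "save_contrast", "load_contrast",
    "save_cohort", "load_cohort", "save_cohort_table", "load_cohort_table",
    "save_ground_truth", "load_ground_truth", "save_tmap",
    "save_json", "load_json",
]

#: external CSV column names (study-table style) <-> internal names
TABLE_COLUMNS = {
    "subject_id": "Sub ID",
    "group": "Group",
    "age": "Age",
    "sex": "Sex",
    "hand": "Hand",
    "ethnicity": "Ethnicity",
    "threshold_mA": "Pain Thresh Level",
    "duration_years": "Duration Since Onset of Condition",
}
_FROM_TABLE = {v: k for k, v in TABLE_COLUMNS.items()}


def _affines_match(a, b) -> bool:
    return np.allclose(a, b, atol=1e-4)


def save_mask(mask: MaskVolume, path) -> Path:
    """Write the mask as a NIfTI label volume (region id + 1, 0 outside)
    plus a JSON sidecar with the region names."""
    path = Path(path)
    labels = np.zeros(mask.grid.shape, dtype=np.int16)
    labels[mask.grid] = mask.region_ids + 1
    nib.save(nib.Nifti1Image(labels, mask.affine), str(path))
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.name.endswith(".nii.gz") else path.with_suffix(".json")
    sidecar.write_text(json.dumps({"region_names": list(mask.region_names)}))
    return path


def load_mask(path) -> MaskVolume:
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int16)
    grid = labels > 0
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.name.endswith(".nii.gz") else path.with_suffix(".json")
    if sidecar.exists():
        names = tuple(json.loads(sidecar.read_text())["region_names"])
    else:
        names = tuple(f"region{r}" for r in range(int(labels.max())))
    return MaskVolume(grid=grid, affine=np.asarray(img.affine),
                      region_ids=(labels[grid] - 1).astype(np.int16),
                      region_names=names)


def save_contrast(mask: MaskVolume, values, path) -> Path:
    """Write one subject's masked contrast vector as a 3D NIfTI volume."""
    path = Path(path)
    vol = mask.unmask(values).astype(np.float64)
    nib.save(nib.Nifti1Image(vol, mask.affine), str(path))
    return path


def load_contrast(path, mask: MaskVolume) -> np.ndarray:
    """Read a contrast volume back into the mask's per-voxel vector.

    Raises if the volume's affine does not match the mask's (no silent
    resampling is ever performed).
    """
    path = Path(path)
    img = nib.load(str(path))
    if not _affines_match(img.affine, mask.affine):
        raise ValueError(
            f"affine mismatch between contrast volume {path} and the mask; "
            "refusing to resample")
    if img.shape != mask.grid.shape:
        raise ValueError(
            f"grid shape mismatch between {path} and the mask")
    vol = np.asarray(img.dataobj, dtype=np.float64)
    return vol[mask.grid]


def save_cohort_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = table.rename(columns=TABLE_COLUMNS)
    out = out[[c for c in out.columns if c != "label"]]
    out.to_csv(path, index=False)
    return path


def load_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path).rename(columns=_FROM_TABLE)
    if "group" in df.columns:
        df["label"] = (df["group"] == "chronic").astype(int)
    return df


def save_ground_truth(truth: GroundTruth, path) -> Path:
    path = Path(path)
    path.write_text(truth.to_json())
    return path


def load_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def save_cohort(mask: MaskVolume, maps, table: pd.DataFrame,
                out_dir, truth: GroundTruth | None = None) -> dict:
    """Write a full synthetic cohort: mask, one contrast NIfTI per subject,
    the cohort CSV and (optionally) the ground-truth JSON.

    Returns a manifest of the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"mask": str(save_mask(mask, out_dir / "mask.nii"))}
    contrast_paths = []
    for row, values in zip(table.itertuples(index=False), maps):
        p = out_dir / f"contrast_{row.subject_id}.nii"
        save_contrast(mask, values, p)
        contrast_paths.append(str(p))
    manifest["contrasts"] = contrast_paths
    manifest["table"] = str(save_cohort_table(table, out_dir / "cohort.csv"))
    if truth is not None:
        manifest["ground_truth"] = str(
            save_ground_truth(truth, out_dir / "ground_truth.json"))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_cohort(cohort_dir):
    """Read back a cohort directory: (mask, maps, table, truth-or-None)."""
    cohort_dir = Path(cohort_dir)
    manifest_path = cohort_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(
            f"no cohort manifest at {manifest_path}; run the simulate step "
            "first or point at a directory written by save_cohort")
    manifest = json.loads(manifest_path.read_text())
    mask = load_mask(manifest["mask"])
    table = load_cohort_table(manifest["table"])
    maps = np.stack([load_contrast(p, mask) for p in manifest["contrasts"]])
    truth = None
    if manifest.get("ground_truth"):
        truth = load_ground_truth(manifest["ground_truth"])
    return mask, maps, table, truth


def save_tmap(mask: MaskVolume, tmap, stem) -> dict:
    """Write a voxelwise t-map as NIfTI plus a CSV peak table.

    The CSV lists suprathreshold voxels (largest |t| first) with voxel
    index, region label, MNI coordinates, t and p; when nothing survives
    correction the table holds the 10 largest |t| voxels flagged False, so
    the file always documents where the map peaks.
    """
    stem = Path(stem)
    t_clean = np.where(tmap.valid, tmap.t, 0.0)
    nib.save(nib.Nifti1Image(mask.unmask(t_clean), mask.affine),
             str(stem.with_suffix(".nii")))
    idx = np.flatnonzero(tmap.significant)
    flagged = True
    if idx.size == 0:
        order = np.argsort(-np.abs(t_clean))
        idx = order[:10]
        flagged = False
    else:
        idx = idx[np.argsort(-np.abs(t_clean[idx]))]
    coords = mask.coords_mm[idx]
    table = pd.DataFrame({
        "voxel_index": idx,
        "region": [mask.region_label(int(i)) for i in idx],
        "mni_x": coords[:, 0],
        "mni_y": coords[:, 1],
        "mni_z": coords[:, 2],
        "t": tmap.t[idx],
        "p": tmap.p[idx],
        "significant": tmap.significant[idx] if flagged else False,
    })
    csv_path = stem.parent / (stem.name + "_peaks.csv")
    table.to_csv(csv_path, index=False)
    return {"nifti": str(stem.with_suffix(".nii")), "peaks": str(csv_path)}


def save_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_jsonify))
    return path


def load_json(path):
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
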