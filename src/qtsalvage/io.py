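"""File interchange: per-lead ECG CSV, NIfTI volumes/masks, result tables.

ECG recordings travel as plain CSV (``time_s`` plus one mV column per
lead) with an optional JSON ground-truth sidecar; phantom volumes and
masks as NIfTI with the voxel spacing in the affine; quantification and
model outputs as CSV/JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cmr import CmrQuantification, CmrStudy
from .ecg import EcgRecording
from .errors import InvalidParameterError
from .simulate import CmrPhantom, EcgGroundTruth, LeadGroundTruth


# --------------------------------------------------------------------- ECG


def write_ecg_csv(rec: EcgRecording, path: str | Path) -> Path:
    path = Path(path)
    n = rec.n_samples
    df = pd.DataFrame({"time_s": np.arange(n) / rec.fs_hz})
    for lead, x in rec.signals.items():
        df[lead] = x
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_ecg_csv(
    path: str | Path, subject_id: str = "unknown", timepoint: str = "admission"
) -> EcgRecording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns or len(df) < 2:
        raise InvalidParameterError(f"{path}: expected a time_s column and >=2 rows")
    dt = np.diff(df["time_s"].to_numpy())
    if not np.allclose(dt, dt[0], rtol=1e-4):
        raise InvalidParameterError(f"{path}: non-uniform sampling")
    fs = 1.0 / float(dt[0])
    signals = {
        c: df[c].to_numpy(dtype=float) for c in df.columns if c != "time_s"
    }
    return EcgRecording(
        subject_id=subject_id, timepoint=timepoint, signals=signals, fs_hz=fs
    )


def write_ecg_truth_json(truth: EcgGroundTruth, path: str | Path) -> Path:
    path = Path(path)

    def encode(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if dataclasses.is_dataclass(obj):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        return obj

    payload = {
        "fs_hz": truth.fs_hz,
        "pq_level_mv": truth.pq_level_mv,
        "leads": {lead: encode(gt) for lead, gt in truth.leads.items()},
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_ecg_truth_json(path: str | Path) -> EcgGroundTruth:
    payload = json.loads(Path(path).read_text())
    leads = {}
    for lead, gt in payload["leads"].items():
        leads[lead] = LeadGroundTruth(
            qt_ms=gt["qt_ms"],
            qt_measurable_ms=gt["qt_measurable_ms"],
            rr_s=gt["rr_s"],
            qrs_onset_idx=np.asarray(gt["qrs_onset_idx"]),
            t_end_idx=np.asarray(gt["t_end_idx"]),
            t_peak_idx=np.asarray(gt["t_peak_idx"]),
            u_peak_idx=None
            if gt["u_peak_idx"] is None
            else np.asarray(gt["u_peak_idx"]),
        )
    return EcgGroundTruth(
        fs_hz=payload["fs_hz"], pq_level_mv=payload["pq_level_mv"], leads=leads
    )


# ------------------------------------------------------------------- NIfTI


def _affine(spacing_mm) -> np.ndarray:
    return np.diag([spacing_mm[0], spacing_mm[1], spacing_mm[2], 1.0])


def write_phantom_nifti(phantom: CmrPhantom, directory: str | Path) -> dict[str, Path]:
    """Write T2w/LGE volumes and all masks as NIfTI files in a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(phantom.spacing_mm)
    out: dict[str, Path] = {}
    volumes = {
        "t2w": phantom.t2w.astype(np.float32),
        "lge": phantom.lge.astype(np.float32),
        "myo_mask": phantom.myo_mask.astype(np.uint8),
        "remote_mask": phantom.remote_mask.astype(np.uint8),
        "truth_edema": phantom.truth_edema.astype(np.uint8),
        "truth_infarct": phantom.truth_infarct.astype(np.uint8),
        "truth_mvo": phantom.truth_mvo.astype(np.uint8),
    }
    for name, arr in volumes.items():
        p = directory / f"{name}.nii"
        nib.save(nib.Nifti1Image(arr, aff), p)
        out[name] = p
    return out


def read_study_nifti(
    t2w_path: str | Path,
    lge_path: str | Path,
    myo_path: str | Path,
    remote_path: str | Path,
    subject_id: str = "unknown",
) -> CmrStudy:
    t2 = nib.load(str(t2w_path))
    lge = nib.load(str(lge_path))
    myo = nib.load(str(myo_path))
    remote = nib.load(str(remote_path))
    spacing = tuple(float(z) for z in t2.header.get_zooms()[:3])
    return CmrStudy(
        subject_id=subject_id,
        t2w=np.asarray(t2.dataobj, dtype=float),
        lge=np.asarray(lge.dataobj, dtype=float),
        myo_mask=np.asarray(myo.dataobj) > 0,
        remote_mask=np.asarray(remote.dataobj) > 0,
        spacing_mm=spacing,  # type: ignore[arg-type]
    )


# ------------------------------------------------------------------ tables


def quantification_to_row(q: CmrQuantification) -> dict:
    return {
        "subject_id": q.subject_id,
        "lv_mass_g": q.lv_mass_g,
        "aar_g": q.aar_g,
        "aar_pct": q.aar_pct_lv,
        "lge_g": q.infarct_g,
        "lge_pct": q.infarct_pct_lv,
        "mvo_present": int(q.mvo_present),
        "mvo_g": q.mvo_g,
        "msi": q.msi,
    }


def write_quantifications_csv(
    quants: list[CmrQuantification], path: str | Path
) -> Path:
    path = Path(path)
    pd.DataFrame([quantification_to_row(q) for q in quants]).to_csv(
        path, index=False, float_format="%.6f"
    )
    return path


def write_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)

    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serialisable: {type(obj)}")

    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=default))
    return path
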