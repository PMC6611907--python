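"""On-disk formats: NIfTI volumes, EIT series, waveform CSV, JSON sidecars.

CT volumes and label masks travel as NIfTI (plain or gzipped) with a
diagonal affine carrying spacing and origin; EIT series as NIfTI with time
as the last axis plus a JSON sidecar for the frame rate; ventilator
waveforms as CSV with the header ``time_s,volume_ml,flow_ml_s,pressure_cmH2O``;
electrode sets, transforms and ground truth as JSON.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .belt_geometry import ElectrodeSet, SimilarityTransform
from .eit_analysis import EITSeries
from .grids import CTVolume, RegionLabelMask
from .phantom import GroundTruth

__all__ = [
    "read_ct",
    "write_ct",
    "read_mask",
    "write_mask",
    "read_eit",
    "write_eit",
    "read_waveform",
    "write_waveform",
    "read_ground_truth",
    "write_ground_truth",
    "write_geometry",
    "read_geometry",
    "RunConfig",
    "load_config",
]

WAVEFORM_COLUMNS = ("time_s", "volume_ml", "flow_ml_s", "pressure_cmH2O")


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_ct(path, ct: CTVolume) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(ct.hu, dtype=np.float32), _affine(ct.spacing_mm, ct.origin_mm))
    if ct.phase:
        img.header["descrip"] = f"phase={ct.phase}".encode()
    nib.save(img, str(path))


def read_ct(path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    aff = np.asarray(img.affine)
    # voxel spacing from the affine column norms (the authoritative geometry)
    spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
    if any(s <= 0 for s in spacing):
        raise ValueError(f"malformed NIfTI header: non-positive spacing {spacing}")
    origin = tuple(float(v) for v in aff[:3, 3])
    phase = None
    descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="ignore")
    if descrip.startswith("phase="):
        phase = descrip.split("=", 1)[1]
    return CTVolume(np.asarray(img.dataobj, dtype=np.float32), spacing, origin, phase=phase)


def write_mask(path, mask: RegionLabelMask) -> None:
    import nibabel as nib

    spacing = mask.spacing_mm or (1.0, 1.0, 1.0)
    origin = mask.origin_mm or (0.0, 0.0, 0.0)
    img = nib.Nifti1Image(np.asarray(mask.labels, dtype=np.uint8), _affine(spacing, origin))
    nib.save(img, str(path))


def read_mask(path) -> RegionLabelMask:
    import nibabel as nib

    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int8)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return RegionLabelMask(labels, spacing, origin)


def write_eit(path, series: EITSeries) -> None:
    """Write an EIT series as NIfTI (h, w, time) plus a JSON sidecar."""
    import nibabel as nib

    path = Path(path)
    data = np.moveaxis(np.asarray(series.frames, dtype=np.float32), 0, -1)
    nib.save(nib.Nifti1Image(data, np.eye(4)), str(path))
    sidecar = {
        "frame_rate_hz": series.frame_rate_hz,
        "grid_size": list(series.frames.shape[1:]),
        "n_frames": int(series.n_frames),
        "step_id": series.step_id,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_eit(path) -> EITSeries:
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    with open(_sidecar_path(path)) as fh:
        meta = json.load(fh)
    frames = np.moveaxis(np.asarray(img.dataobj, dtype=np.float32), -1, 0)
    return EITSeries(frames, float(meta["frame_rate_hz"]), step_id=meta.get("step_id"))


def write_waveform(path, waveform: pd.DataFrame) -> None:
    missing = [c for c in WAVEFORM_COLUMNS if c not in waveform.columns]
    if missing:
        raise ValueError(f"waveform is missing required column(s): {missing}")
    waveform.to_csv(path, index=False)


def read_waveform(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in WAVEFORM_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"waveform CSV is missing required column '{col}'")
    t = df["time_s"].to_numpy()
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ValueError(f"time_s is not strictly increasing at row {int(bad[0]) + 1}")
    return df


def write_ground_truth(path, truths: list[GroundTruth]) -> None:
    payload = {t.step_id: dataclasses.asdict(t) for t in truths}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def read_ground_truth(path) -> dict[str, GroundTruth]:
    with open(path) as fh:
        payload = json.load(fh)
    return {k: GroundTruth(**v) for k, v in payload.items()}


def write_geometry(path, electrodes: ElectrodeSet, transform: SimilarityTransform) -> None:
    payload = {
        "electrodes": {
            "positions_mm": electrodes.positions.tolist(),
            "labels": list(electrodes.labels),
            "space": electrodes.space,
        },
        "transform": {
            "rotation": transform.rotation.tolist(),
            "scale": transform.scale,
            "translation_mm": transform.translation.tolist(),
            "rms_residual_mm": transform.rms_residual,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def read_geometry(path) -> tuple[ElectrodeSet, SimilarityTransform]:
    with open(path) as fh:
        payload = json.load(fh)
    e = payload["electrodes"]
    t = payload["transform"]
    electrodes = ElectrodeSet(
        np.asarray(e["positions_mm"]), tuple(e["labels"]), space=e["space"]
    )
    transform = SimilarityTransform(
        np.asarray(t["rotation"]),
        float(t["scale"]),
        np.asarray(t["translation_mm"]),
        float(t["rms_residual_mm"]),
    )
    return electrodes, transform


@dataclasses.dataclass
class RunConfig:
    """Flat run configuration; CLI flags override file values override defaults."""

    n_electrodes: int = 16
    slab_mm: float = 120.0
    metal_hu_threshold: float = 2000.0
    min_breath_s: float = 1.5
    min_prominence_frac: float = 0.25
    nccf_max_lag_s: float = 2.0
    side_threshold_pct: float = 65.0
    noise_ct_hu: float = 20.0
    noise_eit_frac: float = 0.01
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load a TOML config file, rejecting unknown keys."""
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}")
    return RunConfig(**data)
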