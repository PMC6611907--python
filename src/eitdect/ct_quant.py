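"""Voxel-based lung CT densitometry.

Air content is taken to be linear in CT density: a voxel at -1000 HU is 100%
air, a voxel at or above 0 HU holds no air, and intermediate densities scale
linearly (so -500 HU is 50% air).  Regional air volumes are the sum of voxel
air fractions times the voxel volume; tidal volumes are end-inspiratory minus
end-expiratory regional air volumes of a breath-hold pair.

HU below -1000 are clamped to air fraction 1.0 (physical bound); regional
tidal volumes may be negative (air redistribution) and are reported signed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import (
    AirMap,
    CTVolume,
    DifferenceMap,
    LABEL_UNCLASSIFIED,
    PHASE_EXP,
    PHASE_INSP,
    RegionLabelMask,
)

__all__ = [
    "AirVolumeReport",
    "body_mask",
    "hu_to_air_fraction",
    "voxel_volume_mm3",
    "air_map",
    "region_air_volume",
    "tidal_volume",
    "difference_map",
    "lung_mask",
    "effective_dose_mSv",
    "alveoli_per_ct_unit",
]


@dataclass(frozen=True)
class AirVolumeReport:
    """Per-region air volumes (ml) for one respiratory phase.

    ``total_ml`` sums the named (classified) regions; air in unclassified
    voxels is reported separately and not part of the total.
    """

    region_ml: dict[str, float]
    unclassified_ml: float = 0.0
    phase: str | None = None

    @property
    def total_ml(self) -> float:
        return float(sum(self.region_ml.values()))


def hu_to_air_fraction(hu):
    """Map Hounsfield units to air fraction: clamp(-hu/1000, 0, 1).

    Works elementwise on arrays; scalars return Python floats.
    """
    arr = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("hu contains non-finite values")
    frac = np.clip(-arr / 1000.0, 0.0, 1.0) + 0.0  # "+ 0.0" normalizes -0.0
    if np.isscalar(hu) or arr.ndim == 0:
        return float(frac)
    return frac


def voxel_volume_mm3(spacing_mm) -> float:
    """Volume of one voxel, the product of the three edge lengths (mm^3)."""
    spacing = np.asarray(spacing_mm, dtype=float).reshape(-1)
    if spacing.size != 3:
        raise ValueError("spacing_mm must have 3 components")
    if np.any(spacing <= 0):
        raise ValueError(f"spacing_mm must be strictly positive, got {tuple(spacing)}")
    return float(np.prod(spacing))


def air_map(ct: CTVolume) -> AirMap:
    """Per-voxel air fraction of a CT volume."""
    return AirMap(hu_to_air_fraction(ct.hu), ct.spacing_mm)


def _check_same_grid(a, b, what: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what}: grid shapes differ, {a.shape} vs {b.shape}")


def region_air_volume(ct: CTVolume, mask) -> AirVolumeReport:
    """Air volume (ml) per labelled region of ``mask``.

    ``mask`` is a :class:`RegionLabelMask` or a boolean array (treated as one
    region named ``"all"``).  Volumes accumulate in mm^3 and are reported in
    ml (1 ml = 1000 mm^3).
    """
    frac = hu_to_air_fraction(ct.hu)
    vox_ml = voxel_volume_mm3(ct.spacing_mm) / 1000.0
    if isinstance(mask, RegionLabelMask):
        _check_same_grid(ct.hu, mask.labels, "region_air_volume")
        region_ml = {
            name: float(frac[reg].sum(dtype=np.float64) * vox_ml)
            for name, reg in mask.iter_regions()
        }
        uncls = float(frac[mask.labels == LABEL_UNCLASSIFIED].sum(dtype=np.float64) * vox_ml)
        return AirVolumeReport(region_ml, unclassified_ml=uncls, phase=ct.phase)
    m = np.asarray(mask)
    if m.dtype != bool:
        raise TypeError("mask must be a RegionLabelMask or a boolean array")
    _check_same_grid(ct.hu, m, "region_air_volume")
    vol = float(frac[m].sum(dtype=np.float64) * vox_ml)
    return AirVolumeReport({"all": vol}, phase=ct.phase)


def tidal_volume(insp: CTVolume, exp: CTVolume, mask) -> dict[str, float]:
    """Per-region and total tidal volume (ml): inspiratory minus expiratory.

    Negative regional values are legal and reported signed.  If the phase
    metadata looks swapped a warning is issued and the signed convention
    (first argument minus second) is applied regardless.
    """
    _check_same_grid(insp.hu, exp.hu, "tidal_volume")
    if insp.phase == PHASE_EXP and exp.phase == PHASE_INSP:
        warnings.warn(
            "tidal_volume: phase labels look swapped; computing first minus "
            "second argument as documented",
            stacklevel=2,
        )
    rep_i = region_air_volume(insp, mask)
    rep_e = region_air_volume(exp, mask)
    out = {k: rep_i.region_ml[k] - rep_e.region_ml[k] for k in rep_i.region_ml}
    out["total"] = float(sum(out.values()))
    return out


def difference_map(insp: CTVolume, exp: CTVolume) -> DifferenceMap:
    """Per-voxel air-fraction change, inspiration minus expiration."""
    _check_same_grid(insp.hu, exp.hu, "difference_map")
    delta = hu_to_air_fraction(insp.hu) - hu_to_air_fraction(exp.hu)
    return DifferenceMap(delta, insp.spacing_mm)


def body_mask(ct: CTVolume, hi_hu: float = -200.0) -> np.ndarray:
    """Body interior: largest component above ``hi_hu`` with holes filled.

    Restricting regional analyses to this mask excludes ambient air while
    keeping lungs (filled holes) and soft tissue, whose air content is ~0.
    """
    solid = ct.hu > hi_hu
    lab, n = ndimage.label(solid)
    if n == 0:
        raise ValueError("no body found above the tissue threshold")
    sizes = ndimage.sum_labels(solid, lab, index=np.arange(1, n + 1))
    return ndimage.binary_fill_holes(lab == (1 + int(np.argmax(sizes))))


def lung_mask(
    ct: CTVolume,
    lo_hu: float = -1000.0,
    hi_hu: float = -200.0,
    min_component_frac: float = 0.5,
) -> np.ndarray:
    """Threshold-based lung segmentation.

    Voxels with ``lo_hu <= HU <= hi_hu`` that lie inside the body outline
    (largest above ``hi_hu`` component, holes filled) are candidates; the
    connected components at least ``min_component_frac`` of the largest are
    kept, which retains both lungs while dropping airway specks.  An external
    mask can always be supplied downstream instead.
    """
    if lo_hu >= hi_hu:
        raise ValueError(f"lo_hu must be < hi_hu, got ({lo_hu}, {hi_hu})")
    hu = ct.hu
    body = hu > hi_hu
    lab, n = ndimage.label(body)
    if n == 0:
        warnings.warn("lung_mask: no body outline found; empty mask", stacklevel=2)
        return np.zeros(hu.shape, dtype=bool)
    sizes = ndimage.sum_labels(body, lab, index=np.arange(1, n + 1))
    body = ndimage.binary_fill_holes(lab == (1 + int(np.argmax(sizes))))
    cand = (hu >= lo_hu) & (hu <= hi_hu) & body
    lab, n = ndimage.label(cand)
    if n == 0:
        warnings.warn("lung_mask: empty mask at these thresholds", stacklevel=2)
        return np.zeros(hu.shape, dtype=bool)
    sizes = ndimage.sum_labels(cand, lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_component_frac * sizes.max()) + 1
    return np.isin(lab, keep)


def effective_dose_mSv(dlp_mGycm: float, k: float = 0.015) -> float:
    """Effective dose from a dose-length product, ``dose = DLP * k``.

    ``k`` is a conversion factor in mSv/(mGy*cm); the result is reported to
    one decimal, matching radiology reporting practice.
    """
    if dlp_mGycm < 0:
        raise ValueError(f"dlp_mGycm must be >= 0, got {dlp_mGycm}")
    return round(float(dlp_mGycm) * k, 1)


def alveoli_per_ct_unit(
    voxel_volume_mm3: float,
    acinus_volume_mm3: float = 20.0,
    alveoli_per_acinus: float = 2000.0,
) -> int:
    """Alveoli contained in one voxel (the "CT pulmonary unit").

    Under an acinus model of ~2000 alveoli per ~20 mm^3 acinus, a voxel of
    0.42 mm^3 contains about 42 alveoli.
    """
    if voxel_volume_mm3 <= 0 or acinus_volume_mm3 <= 0 or alveoli_per_acinus <= 0:
        raise ValueError("all arguments must be positive")
    return int(round(alveoli_per_acinus * voxel_volume_mm3 / acinus_volume_mm3))
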