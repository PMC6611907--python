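"""Shared grid containers and the world-coordinate convention.

All volumes live on regular axis-aligned grids. Array axes map to world axes
``(x, y, z)`` with

* ``+x`` = patient-left,
* ``+y`` = ventral (anterior),
* ``+z`` = cranial,

world coordinates in millimetres, and the centre of voxel ``(i, j, k)`` at
``origin_mm + (i, j, k) * spacing_mm``.  Quadrant labels are small integer
codes shared by 3-D CT masks and 2-D EIT-pixel masks.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

#: Label codes for the four belt quadrants (ventral/dorsal x left/right).
LABEL_UNCLASSIFIED = 0
LABEL_VL = 1
LABEL_VR = 2
LABEL_DL = 3
LABEL_DR = 4

#: Canonical quadrant order used everywhere a 4-vector is exchanged.
QUADRANTS = ("VL", "VR", "DL", "DR")
LABEL_CODES = {"VL": LABEL_VL, "VR": LABEL_VR, "DL": LABEL_DL, "DR": LABEL_DR}
LABEL_NAMES = {v: k for k, v in LABEL_CODES.items()}

PHASE_INSP = "end-inspiratory"
PHASE_EXP = "end-expiratory"


def _as_tuple3(value, name: str) -> tuple[float, float, float]:
    arr = np.asarray(value, dtype=float).reshape(-1)
    if arr.size != 3:
        raise ValueError(f"{name} must have 3 components, got {arr.size}")
    return tuple(float(v) for v in arr)


@dataclass(frozen=True)
class CTVolume:
    """A single breath-hold CT volume in Hounsfield units."""

    hu: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase: str | None = None

    def __post_init__(self):
        hu = np.asarray(self.hu)
        if hu.ndim != 3:
            raise ValueError(f"hu must be a 3-D array, got ndim={hu.ndim}")
        if not np.all(np.isfinite(hu)):
            raise ValueError("hu contains non-finite values")
        object.__setattr__(self, "hu", hu)
        spacing = _as_tuple3(self.spacing_mm, "spacing_mm")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing_mm must be strictly positive, got {spacing}")
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", _as_tuple3(self.origin_mm, "origin_mm"))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    def world_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-centre coordinates, broadcastable to the grid shape."""
        out = []
        for ax in range(3):
            c = self.origin_mm[ax] + np.arange(self.shape[ax]) * self.spacing_mm[ax]
            shape = [1, 1, 1]
            shape[ax] = -1
            out.append(c.reshape(shape))
        return tuple(out)


@dataclass(frozen=True)
class AirMap:
    """Per-voxel air fraction in [0, 1] derived from a CT volume."""

    air_fraction: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        f = np.asarray(self.air_fraction)
        if np.nanmin(f) < 0 or np.nanmax(f) > 1:
            raise ValueError("air_fraction outside [0, 1]")
        object.__setattr__(self, "air_fraction", f)
        object.__setattr__(self, "spacing_mm", _as_tuple3(self.spacing_mm, "spacing_mm"))


@dataclass(frozen=True)
class DifferenceMap:
    """Per-voxel inspiratory-minus-expiratory air-fraction change."""

    delta_air_fraction: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        d = np.asarray(self.delta_air_fraction)
        if np.nanmin(d) < -1 or np.nanmax(d) > 1:
            raise ValueError("delta_air_fraction outside [-1, 1]")
        object.__setattr__(self, "delta_air_fraction", d)
        object.__setattr__(self, "spacing_mm", _as_tuple3(self.spacing_mm, "spacing_mm"))


@dataclass(frozen=True)
class RegionLabelMask:
    """Quadrant label grid (3-D for CT, 2-D for EIT pixel space).

    ``labels`` holds the codes ``LABEL_UNCLASSIFIED``/``LABEL_VL``/.../``LABEL_DR``.
    """

    labels: np.ndarray
    spacing_mm: tuple[float, float, float] | None = None
    origin_mm: tuple[float, float, float] | None = None
    slab_thickness_mm: float | None = None

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim not in (2, 3):
            raise ValueError(f"labels must be 2-D or 3-D, got ndim={lab.ndim}")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if lab.min() < 0 or lab.max() > LABEL_DR:
            raise ValueError("labels contain codes outside 0..4")
        object.__setattr__(self, "labels", lab)

    @property
    def shape(self):
        return self.labels.shape

    def region(self, name: str) -> np.ndarray:
        """Boolean mask of one quadrant by name ('VL', 'VR', 'DL', 'DR')."""
        return self.labels == LABEL_CODES[name]

    def iter_regions(self) -> Iterator[tuple[str, np.ndarray]]:
        for name in QUADRANTS:
            yield name, self.region(name)

    def restrict(self, keep: np.ndarray) -> "RegionLabelMask":
        """Copy with voxels outside ``keep`` relabelled unclassified."""
        from dataclasses import replace

        labels = np.where(np.asarray(keep, bool), self.labels, 0).astype(self.labels.dtype)
        return replace(self, labels=labels)
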