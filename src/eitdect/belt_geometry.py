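"""Belt-electrode geometry: detection, reference registration, quadrant masks.

The EIT belt carries ``n`` electrodes around the thorax.  They are located in
CT as metal (high-HU) blobs, ordered circumferentially, and registered to an
ideal reference geometry (``n`` equidistant points on the unit circle in the
belt plane of a canonical frame: ventral = +y, patient-left = +x) by a
closed-form least-squares similarity transform (rotation + isotropic scale +
translation, reflections rejected).  The transformed reference frame defines
a slab of configurable thickness (default 12 cm) centred on the belt plane,
split into four quadrants (ventral/dorsal x left/right); the same quadrant
definition is applied in EIT pixel space so that CT and EIT regional values
are computed over one shared segmentation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import (
    CTVolume,
    LABEL_DL,
    LABEL_DR,
    LABEL_VL,
    LABEL_VR,
    RegionLabelMask,
)

__all__ = [
    "ElectrodeSet",
    "ReferenceGeometry",
    "SimilarityTransform",
    "detect_electrodes",
    "fit_reference_transform",
    "build_quadrant_mask",
    "eit_quadrant_mask",
]


@dataclass(frozen=True)
class ElectrodeSet:
    """Ordered electrode landmark positions (mm) in CT or EIT space.

    Ordering is circumferential with consistent winding: counterclockwise
    viewed from cranial, starting from the most ventral-left electrode.
    """

    positions: np.ndarray
    labels: tuple[int, ...]
    space: str = "CT"

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError(f"positions must be (n, 3), got {pos.shape}")
        if pos.shape[0] < 3:
            raise ValueError(f"need >= 3 electrodes, got {pos.shape[0]}")
        if np.linalg.matrix_rank(pos - pos.mean(axis=0), tol=1e-9) < 2:
            raise ValueError("electrode positions are collinear")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", tuple(int(v) for v in self.labels))

    @property
    def n(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class ReferenceGeometry:
    """Ideal virtual belt: n equidistant electrodes on the unit circle.

    Electrode i sits at angle ``pi/2 + (i + 0.5) * 2*pi/n`` in the canonical
    belt plane (z = 0), i.e. the ring starts just patient-left of the ventral
    midline and winds counterclockwise viewed from cranial -- matching the
    ordering contract of :func:`detect_electrodes`.  The quadrant splitting
    planes are the canonical x = 0 (left/right) and y = 0 (ventral/dorsal)
    planes through the circle centre.
    """

    n_electrodes: int = 16

    def __post_init__(self):
        if self.n_electrodes < 3:
            raise ValueError("reference geometry needs >= 3 electrodes")

    @property
    def angles(self) -> np.ndarray:
        n = self.n_electrodes
        return np.pi / 2 + (np.arange(n) + 0.5) * 2 * np.pi / n

    @property
    def positions(self) -> np.ndarray:
        a = self.angles
        return np.column_stack([np.cos(a), np.sin(a), np.zeros_like(a)])


@dataclass(frozen=True)
class SimilarityTransform:
    """p -> scale * rotation @ p + translation, with det(rotation) = +1."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    rms_residual: float = 0.0

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflections (det -1) are not similarity rotations here")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return self.scale * pts @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3), 1.0, np.zeros(3), 0.0)


def _fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through ``points``, oriented +z."""
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    n = vt[-1]
    if n[2] < 0:
        n = -n
    return n / np.linalg.norm(n)


def detect_electrodes(
    ct: CTVolume,
    metal_hu_threshold: float = 2000.0,
    n_expected: int = 16,
    exclude_indicators: bool = True,
    min_component_frac: float = 0.25,
) -> ElectrodeSet:
    """Locate belt electrodes as metal blobs and order them circumferentially.

    Connected components above ``metal_hu_threshold`` are reduced to world
    centroids (size-gated against the median component to drop specks).  If
    ``exclude_indicators`` and exactly ``n_expected + 2`` blobs are found, the
    two closest in angle to the ventral midline (the sternal indicator
    electrodes) are dropped.  Ordering starts at the most ventral-left
    electrode and proceeds counterclockwise viewed from cranial.
    """
    from scipy import ndimage

    hot = ct.hu > metal_hu_threshold
    lab, n = ndimage.label(hot)
    if n == 0:
        raise ValueError("0 electrodes found above the metal threshold")
    sizes = ndimage.sum_labels(hot, lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_component_frac * np.median(sizes)) + 1
    cent_idx = np.array(ndimage.center_of_mass(hot, lab, index=keep))
    pos = np.asarray(ct.origin_mm) + cent_idx * np.asarray(ct.spacing_mm)

    centre = pos.mean(axis=0)
    normal = _fit_plane_normal(pos)
    tilt = np.degrees(np.arccos(min(1.0, abs(normal[2]))))
    if tilt > 30:
        warnings.warn(
            f"detect_electrodes: belt plane tilted {tilt:.1f} deg from axial; "
            "ordering may be ambiguous",
            stacklevel=2,
        )
    # In-plane axes: world x/y projected onto the belt plane.
    u = np.array([1.0, 0.0, 0.0]) - normal[0] * normal
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    d = pos - centre
    ang = np.mod(np.arctan2(d @ v, d @ u), 2 * np.pi)
    order = np.argsort(ang)
    pos, ang = pos[order], ang[order]

    if exclude_indicators and pos.shape[0] == n_expected + 2:
        # Indicator electrodes sit immediately left/right of the sternal
        # (ventral) midline, i.e. nearest in angle to +y.
        gap = np.abs(np.angle(np.exp(1j * (ang - np.pi / 2))))
        drop = np.argsort(gap)[:2]
        keep_idx = np.setdiff1d(np.arange(pos.shape[0]), drop)
        pos, ang = pos[keep_idx], ang[keep_idx]

    if pos.shape[0] != n_expected:
        raise ValueError(
            f"expected {n_expected} electrodes, found {pos.shape[0]} "
            f"above {metal_hu_threshold} HU"
        )
    # Start from the most ventral-left electrode: the first one
    # counterclockwise past the ventral midline (+y), matching the reference
    # ring's first electrode just patient-left of the sternum.
    start = int(np.argmin(np.mod(ang - np.pi / 2, 2 * np.pi)))
    roll = np.roll(np.arange(n_expected), -start)
    return ElectrodeSet(pos[roll], labels=tuple(range(1, n_expected + 1)), space="CT")


def _umeyama(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Closed-form least-squares similarity mapping src onto dst."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    cs, cd = src - mu_s, dst - mu_d
    cov = cd.T @ cs / src.shape[0]
    U, S, Vt = np.linalg.svd(cov)
    sgn = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    D = np.diag([1.0, 1.0, sgn])
    R = U @ D @ Vt
    var_s = float(np.mean(np.sum(cs**2, axis=1)))
    if var_s <= 0:
        raise ValueError("degenerate source configuration (zero variance)")
    scale = float(np.trace(np.diag(S) @ D)) / var_s
    if scale <= 0:
        raise ValueError("degenerate configuration: non-positive fitted scale")
    t = mu_d - scale * R @ mu_s
    res = scale * src @ R.T + t - dst
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return SimilarityTransform(R, scale, t, rms)


def fit_reference_transform(
    detected: ElectrodeSet,
    ref: ReferenceGeometry | None = None,
    max_offset: int | None = 0,
) -> SimilarityTransform:
    """Fit the similarity transform mapping the reference belt onto ``detected``.

    Correspondence is by label; cyclic offsets within ``+-max_offset`` slots
    (smaller offsets tried first) and, for ``max_offset=None``, all offsets
    and both windings are searched for the lowest RMS residual.  For an
    equidistant belt the residual is rotation-degenerate -- every cyclic
    offset of an equi-angular ring fits a (scaled) circle equally well -- so
    residual alone cannot recover the anatomical orientation; the default
    ``max_offset=0`` therefore trusts the anatomically anchored ordering of
    :func:`detect_electrodes`, and wider searches only help for irregular
    belts.  Solutions whose belt normal opposes the detected, cranially
    oriented normal are rejected (they correspond to a flipped winding).
    """
    if ref is None:
        ref = ReferenceGeometry(detected.n)
    if ref.n_electrodes != detected.n:
        raise ValueError(
            f"electrode count mismatch: reference {ref.n_electrodes}, detected {detected.n}"
        )
    n = detected.n
    ref_pts = ref.positions
    det_pts = detected.positions
    # Winding-aware ring normal: for an ordered ring this equals the
    # transformed reference normal, so it rejects flipped-winding fits
    # without assuming any world orientation.
    c = det_pts.mean(axis=0)
    d = det_pts - c
    det_normal = np.cross(d, np.roll(d, -1, axis=0)).sum(axis=0)
    det_normal /= np.linalg.norm(det_normal)

    if max_offset is None:
        offsets = sorted(range(-(n // 2), n - n // 2), key=abs)
        windings = (1, -1)
    else:
        w = min(int(max_offset), n // 2)
        offsets = sorted(range(-w, w + 1), key=abs)
        windings = (1,)
    offsets = [o % n for o in offsets]

    best: SimilarityTransform | None = None
    for winding in windings:
        for off in offsets:
            idx = (off + winding * np.arange(n)) % n
            try:
                tf = _umeyama(ref_pts, det_pts[idx])
            except ValueError:
                continue
            if (tf.rotation @ np.array([0.0, 0.0, 1.0])) @ det_normal <= 0:
                continue  # belt normal flipped: wrong winding branch
            if best is None or tf.rms_residual < best.rms_residual:
                best = tf
    if best is None:
        raise ValueError("degenerate electrode configuration: no similarity fit found")
    return best


def build_quadrant_mask(
    transform: SimilarityTransform,
    grid: CTVolume,
    slab_thickness_mm: float = 120.0,
) -> RegionLabelMask:
    """Quadrant label mask on a CT grid from the fitted belt transform.

    Voxels within ``slab_thickness_mm / 2`` of the belt plane (perpendicular
    distance) are split by the transformed left/right and ventral/dorsal
    planes through the reference-circle centre; everything else is
    unclassified.  Boundary voxels (signed distance exactly 0) go to the
    left/ventral side.
    """
    labels = np.zeros(grid.shape, dtype=np.int8)
    if slab_thickness_mm <= 0:
        warnings.warn("build_quadrant_mask: non-positive slab; all unclassified", stacklevel=2)
        return RegionLabelMask(labels, grid.spacing_mm, grid.origin_mm, slab_thickness_mm)

    centre = transform.translation
    ex = transform.rotation[:, 0]  # patient-left axis
    ey = transform.rotation[:, 1]  # ventral axis
    ez = transform.rotation[:, 2]  # belt-plane normal (cranial)
    X, Y, Z = grid.world_axes()
    dx, dy, dz = X - centre[0], Y - centre[1], Z - centre[2]
    dist = dx * ez[0] + dy * ez[1] + dz * ez[2]
    in_slab = np.abs(dist) <= slab_thickness_mm / 2.0
    if not in_slab.any():
        warnings.warn("build_quadrant_mask: slab lies outside the grid", stacklevel=2)
        return RegionLabelMask(labels, grid.spacing_mm, grid.origin_mm, slab_thickness_mm)
    u = dx * ex[0] + dy * ex[1] + dz * ex[2]
    v = dx * ey[0] + dy * ey[1] + dz * ey[2]
    left = u >= 0
    ventral = v >= 0
    labels[in_slab & left & ventral] = LABEL_VL
    labels[in_slab & ~left & ventral] = LABEL_VR
    labels[in_slab & left & ~ventral] = LABEL_DL
    labels[in_slab & ~left & ~ventral] = LABEL_DR
    return RegionLabelMask(labels, grid.spacing_mm, grid.origin_mm, slab_thickness_mm)


def eit_quadrant_mask(
    ref: ReferenceGeometry | None = None,
    grid_size: int = 32,
    transform2d: SimilarityTransform | None = None,
) -> RegionLabelMask:
    """Quadrant labels on the EIT pixel grid, sharing the CT quadrant planes.

    The EIT image is displayed with the ventral side in the first rows and
    patient-left in the later columns; pixel (row, col) maps to canonical
    coordinates ``x = 2*(col + 0.5)/N - 1`` (left positive) and
    ``y = 1 - 2*(row + 0.5)/N`` (ventral positive).  A 2-D similarity
    transform from EIT space to the reference frame can be supplied; the
    default is the identity (canonical device orientation).
    """
    if grid_size < 2:
        raise ValueError(f"grid_size must be >= 2, got {grid_size}")
    if ref is None:
        ref = ReferenceGeometry()
    N = grid_size
    cols = (np.arange(N) + 0.5) / N * 2 - 1
    rows = 1 - (np.arange(N) + 0.5) / N * 2
    x = np.broadcast_to(cols[None, :], (N, N))
    y = np.broadcast_to(rows[:, None], (N, N))
    if transform2d is not None:
        pts = np.column_stack([x.ravel(), y.ravel(), np.zeros(N * N)])
        mapped = transform2d.apply(pts)
        x = mapped[:, 0].reshape(N, N)
        y = mapped[:, 1].reshape(N, N)
    labels = np.zeros((N, N), dtype=np.int8)
    left = x >= 0
    ventral = y >= 0
    labels[left & ventral] = LABEL_VL
    labels[~left & ventral] = LABEL_VR
    labels[left & ~ventral] = LABEL_DL
    labels[~left & ~ventral] = LABEL_DR
    return RegionLabelMask(labels)
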