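"""Synthetic thorax phantom: co-registered CT pairs, EIT series, ventilator curves.

The phantom is an ellipsoidal soft-tissue thorax containing two ellipsoidal
lung compartments, with metal belt-electrode markers on the body surface in
the belt plane.  Lung voxels carry ``HU = -1000 * air_fraction``; air
fractions are piecewise constant per quadrant (ventral/dorsal x left/right)
and per respiratory phase, so every regional quantity has an exact ground
truth.  Matched EIT frame series deposit per-quadrant impedance blobs whose
summed intensity is proportional to the quadrant air volume over the breath
cycle, and volume-controlled ventilator curves share the same breath shape.

Geometrically the phantom is a scaled-down thorax: the default grid spans a
96 mm cube at the CT protocol's 0.75 mm isotropic voxel pitch.  Protocol
tidal volumes are specified nominally in ml/kg of a real animal; the
realized air-fraction swing is nominal TV divided by a reference total
capacity (80 ml/kg), which keeps CT, EIT and spirometry mutually consistent
and leaves every correlation-based analysis scale-invariant.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eit_analysis import EITSeries
from .grids import (
    CTVolume,
    PHASE_EXP,
    PHASE_INSP,
    QUADRANTS,
    RegionLabelMask,
)

__all__ = [
    "PhantomSpec",
    "ProtocolStep",
    "GroundTruth",
    "StepData",
    "generate_ct_pair",
    "generate_eit_series",
    "generate_ventilator_waveform",
    "generate_protocol",
    "protocol_steps",
]

#: Reference total lung capacity used to convert nominal tidal volumes into
#: air-fraction swings (ml per kg body weight; porcine TLC scale).
CAPACITY_ML_PER_KG = 80.0

MODES = ("two-lung", "one-lung-left", "one-lung-right", "lavage")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, materials and noise of the synthetic thorax.

    Lengths in mm, HU in Hounsfield units.  ``belt_z_mm`` is the axial offset
    of the belt plane from the grid centre.  ``lung_centers_mm`` are offsets
    of the (patient-left, patient-right) lung centres from the body centre.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: tuple[float, float, float] = (0.75, 0.75, 0.75)
    body_axes_mm: tuple[float, float, float] = (42.0, 34.0, 44.0)
    lung_centers_mm: tuple[tuple[float, float, float], ...] = (
        (18.0, 0.0, 0.0),
        (-18.0, 0.0, 0.0),
    )
    lung_axes_mm: tuple[float, float, float] = (13.0, 20.0, 36.0)
    hu_tissue: float = 40.0
    hu_metal: float = 3000.0
    n_electrodes: int = 16
    include_indicators: bool = True
    electrode_radius_mm: float = 2.25
    belt_z_mm: float = 0.0
    slab_thickness_mm: float = 120.0
    noise_sd_hu: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be strictly positive, got {self.spacing_mm}")
        if any(n < 2 for n in self.grid_shape):
            raise ValueError("grid_shape axes must be >= 2")
        if self.n_electrodes < 3:
            raise ValueError("n_electrodes must be >= 3 (transform fit needs non-collinear landmarks)")
        if len(self.lung_centers_mm) != 2:
            raise ValueError("exactly two lung compartments (left, right) expected")
        B = np.asarray(self.body_axes_mm, float)
        a = np.asarray(self.lung_axes_mm, float)
        # Sampled-direction containment check: lung surface inside the body.
        phi = np.pi * (3 - np.sqrt(5)) * np.arange(256)
        zc = 1 - 2 * (np.arange(256) + 0.5) / 256
        rc = np.sqrt(1 - zc**2)
        dirs = np.column_stack([rc * np.cos(phi), rc * np.sin(phi), zc])
        for c in self.lung_centers_mm:
            pts = np.asarray(c, float) + dirs * a
            if np.any(np.sum((pts / B) ** 2, axis=1) > 1.0):
                raise ValueError(
                    f"lung compartment at {c} is not strictly inside the body ellipsoid"
                )

    @property
    def origin_mm(self) -> tuple[float, float, float]:
        return tuple(
            -(n - 1) / 2.0 * s for n, s in zip(self.grid_shape, self.spacing_mm)
        )

    def electrode_positions(self, include_indicators: bool | None = None) -> np.ndarray:
        """World positions of belt markers (regular ring, then indicators).

        Regular electrodes sit equidistant in angle on the body-surface
        ellipse in the belt plane, starting just patient-left of the ventral
        midline and winding counterclockwise viewed from cranial.  The two
        indicator electrodes flank the sternal midline.
        """
        if include_indicators is None:
            include_indicators = self.include_indicators
        Bx, By, Bz = self.body_axes_mm
        zb = self.belt_z_mm
        shrink = np.sqrt(max(0.0, 1.0 - (zb / Bz) ** 2))
        n = self.n_electrodes
        theta = np.pi / 2 + (np.arange(n) + 0.5) * 2 * np.pi / n
        z = np.full_like(theta, zb)
        if include_indicators:
            # Parasternal indicator electrodes flank the ventral midline,
            # slightly cranial of the belt ring so the markers stay separable.
            theta = np.concatenate([theta, [np.pi / 2 - 0.12, np.pi / 2 + 0.12]])
            z = np.concatenate([z, [zb + 8.0, zb + 8.0]])
        return np.column_stack(
            [Bx * shrink * np.cos(theta), By * shrink * np.sin(theta), z]
        )


@dataclass(frozen=True)
class ProtocolStep:
    """One ventilation condition: pressures, volumes, quadrant air fractions.

    Quadrant air fractions are ordered (VL, VR, DL, DR).
    """

    step_id: str
    peep_cmH2O: float
    tv_ml: float
    mode: str = "two-lung"
    quadrant_air_fraction_exp: tuple[float, float, float, float] = (0.3, 0.3, 0.3, 0.3)
    quadrant_air_fraction_insp: tuple[float, float, float, float] = (0.5, 0.5, 0.5, 0.5)
    tv_ml_per_kg: float | None = None
    rr_per_min: float = 15.0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        fe = np.asarray(self.quadrant_air_fraction_exp, float)
        fi = np.asarray(self.quadrant_air_fraction_insp, float)
        if fe.shape != (4,) or fi.shape != (4,):
            raise ValueError("quadrant air fractions must have 4 components (VL, VR, DL, DR)")
        if np.any(fe < 0) or np.any(fi > 1):
            raise ValueError("air fractions must lie in [0, 1]")
        if np.any(fi + 1e-12 < fe):
            raise ValueError("inspiratory air fraction must be >= expiratory per quadrant")

    @property
    def ventilated_side(self) -> str:
        if self.mode == "one-lung-left":
            return "left"
        if self.mode == "one-lung-right":
            return "right"
        return "bilateral"


@dataclass(frozen=True)
class GroundTruth:
    """Exact regional volumes of one phantom step (noise-free, in ml).

    Quadrant dictionaries are keyed VL/VR/DL/DR and refer to the belt slab;
    ``tv_total_ml``/``eelv_ml`` are whole-lung.  ``analytic_*`` values come
    from closed-form ellipsoid geometry, the others from voxel summation of
    the generating (pre-noise) air-fraction field.
    """

    step_id: str
    quadrant_exp_ml: dict[str, float]
    quadrant_insp_ml: dict[str, float]
    tv_total_ml: float
    eelv_ml: float
    tv_out_of_slab_ml: float
    ventilated_side: str
    analytic_tv_total_ml: float
    analytic_eelv_ml: float
    analytic_quadrant_tv_ml: dict[str, float] | None = None

    @property
    def quadrant_tv_ml(self) -> dict[str, float]:
        return {
            q: self.quadrant_insp_ml[q] - self.quadrant_exp_ml[q] for q in QUADRANTS
        }

    def __post_init__(self):
        for d in (self.quadrant_exp_ml, self.quadrant_insp_ml):
            if any(v < -1e-9 for v in d.values()):
                raise ValueError("ground-truth volumes must be >= 0")


def _phantom_fields(spec: PhantomSpec):
    """Broadcastable world coordinates, body mask, lung masks, quadrant index."""
    origin = spec.origin_mm
    coords = []
    for ax in range(3):
        c = origin[ax] + np.arange(spec.grid_shape[ax]) * spec.spacing_mm[ax]
        shape = [1, 1, 1]
        shape[ax] = -1
        coords.append(c.reshape(shape))
    X, Y, Z = coords
    B = spec.body_axes_mm
    body = (X / B[0]) ** 2 + (Y / B[1]) ** 2 + (Z / B[2]) ** 2 <= 1.0
    a = spec.lung_axes_mm
    lungs = []
    for c in spec.lung_centers_mm:
        lungs.append(
            ((X - c[0]) / a[0]) ** 2 + ((Y - c[1]) / a[1]) ** 2 + ((Z - c[2]) / a[2]) ** 2
            <= 1.0
        )
    return X, Y, Z, body, lungs


def _quadrant_masks(spec: PhantomSpec, X, Y, Z, restrict_slab: bool):
    """Boolean quadrant membership (VL, VR, DL, DR) by the generator's planes."""
    left = X >= 0
    ventral = Y >= 0
    if restrict_slab:
        in_slab = np.abs(Z - spec.belt_z_mm) <= spec.slab_thickness_mm / 2.0
    else:
        in_slab = np.ones_like(left)
    return {
        "VL": in_slab & left & ventral,
        "VR": in_slab & ~left & ventral,
        "DL": in_slab & left & ~ventral,
        "DR": in_slab & ~left & ~ventral,
    }


def generator_quadrant_mask(spec: PhantomSpec) -> RegionLabelMask:
    """The generator's own quadrant labelling (oracle for registration tests)."""
    from .grids import LABEL_CODES

    X, Y, Z, _, _ = _phantom_fields(spec)
    labels = np.zeros(spec.grid_shape, dtype=np.int8)
    for name, m in _quadrant_masks(spec, X, Y, Z, restrict_slab=True).items():
        labels[m] = LABEL_CODES[name]
    return RegionLabelMask(labels, spec.spacing_mm, spec.origin_mm, spec.slab_thickness_mm)


def _fraction_field(spec: PhantomSpec, lungs, quad_masks, fractions) -> np.ndarray:
    f = np.zeros(spec.grid_shape, dtype=np.float32)
    lung_any = lungs[0] | lungs[1]
    for q, frac in zip(QUADRANTS, fractions):
        f[lung_any & quad_masks[q]] = frac
    return f


def generate_ct_pair(
    spec: PhantomSpec, step: ProtocolStep, seed: int | None = None
) -> tuple[CTVolume, CTVolume, GroundTruth]:
    """Generate an end-inspiratory/end-expiratory CT pair with ground truth.

    Lung voxels carry ``HU = -1000 * air_fraction`` (then additive Gaussian
    noise of ``spec.noise_sd_hu``); soft tissue is ``spec.hu_tissue``; belt
    markers are spheres at ``spec.hu_metal``.  Ground truth is evaluated on
    the noise-free fraction fields and, in closed form, from the ellipsoid
    geometry.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    X, Y, Z, body, lungs = _phantom_fields(spec)
    quad_all = _quadrant_masks(spec, X, Y, Z, restrict_slab=False)
    quad_slab = _quadrant_masks(spec, X, Y, Z, restrict_slab=True)
    lung_any = lungs[0] | lungs[1]

    f_exp = _fraction_field(spec, lungs, quad_all, step.quadrant_air_fraction_exp)
    f_insp = _fraction_field(spec, lungs, quad_all, step.quadrant_air_fraction_insp)

    vox_ml = float(np.prod(spec.spacing_mm)) / 1000.0
    q_exp, q_insp = {}, {}
    for q in QUADRANTS:
        m = lung_any & quad_slab[q]
        q_exp[q] = float(f_exp[m].sum(dtype=np.float64) * vox_ml)
        q_insp[q] = float(f_insp[m].sum(dtype=np.float64) * vox_ml)
    tv_total = float((f_insp.astype(np.float64) - f_exp).sum() * vox_ml)
    eelv = float(f_exp.sum(dtype=np.float64) * vox_ml)
    tv_slab = sum(q_insp[q] - q_exp[q] for q in QUADRANTS)

    # Closed-form truth: each lung is bisected by the ventral/dorsal plane
    # (lung centres lie at y = 0) and sits wholly on one side of x = 0.
    half_ml = 4.0 / 3.0 * np.pi * float(np.prod(spec.lung_axes_mm)) / 2.0 / 1000.0
    fe = dict(zip(QUADRANTS, step.quadrant_air_fraction_exp))
    fi = dict(zip(QUADRANTS, step.quadrant_air_fraction_insp))
    analytic_q_tv = {q: half_ml * (fi[q] - fe[q]) for q in QUADRANTS}
    analytic_tv = sum(analytic_q_tv.values())
    analytic_eelv = sum(half_ml * fe[q] for q in QUADRANTS)

    def build(frac, phase):
        hu = np.where(lung_any, -1000.0 * frac, np.where(body, spec.hu_tissue, -1000.0))
        hu = hu.astype(np.float32)
        r = spec.electrode_radius_mm
        for centre in spec.electrode_positions():
            ball = (X - centre[0]) ** 2 + (Y - centre[1]) ** 2 + (Z - centre[2]) ** 2 <= r**2
            hu[ball] = spec.hu_metal
            idx = tuple(
                int(round((centre[ax] - spec.origin_mm[ax]) / spec.spacing_mm[ax]))
                for ax in range(3)
            )
            if all(0 <= idx[ax] < spec.grid_shape[ax] for ax in range(3)):
                hu[idx] = spec.hu_metal  # guarantee the marker survives coarse grids
        if spec.noise_sd_hu > 0:
            hu = hu + rng.normal(0.0, spec.noise_sd_hu, hu.shape).astype(np.float32)
        return CTVolume(hu, spec.spacing_mm, spec.origin_mm, phase=phase)

    ct_exp = build(f_exp, PHASE_EXP)
    ct_insp = build(f_insp, PHASE_INSP)
    truth = GroundTruth(
        step_id=step.step_id,
        quadrant_exp_ml=q_exp,
        quadrant_insp_ml=q_insp,
        tv_total_ml=tv_total,
        eelv_ml=eelv,
        tv_out_of_slab_ml=tv_total - tv_slab,
        ventilated_side=step.ventilated_side,
        analytic_tv_total_ml=analytic_tv,
        analytic_eelv_ml=analytic_eelv,
        analytic_quadrant_tv_ml=analytic_q_tv,
    )
    return ct_insp, ct_exp, truth


def _breath_cycle(
    t: np.ndarray, period_s: float, insp_frac: float = 1.0 / 3.0
) -> np.ndarray:
    """Normalized lung-volume shape in [0, 1]: linear rise, exponential decay.

    Constant-flow volume-controlled inspiration over ``insp_frac`` of the
    cycle, then passive exponential expiration (time constant Te/5) rescaled
    to reach exactly 0 at end-expiration.
    """
    ti = insp_frac * period_s
    te = period_s - ti
    tau = te / 5.0
    tc = np.mod(t, period_s)
    shape = np.where(
        tc < ti,
        tc / ti,
        (np.exp(-(tc - ti) / tau) - np.exp(-te / tau)) / (1.0 - np.exp(-te / tau)),
    )
    return shape


def generate_eit_series(
    truth: GroundTruth,
    frame_rate_hz: float = 50.0,
    n_breaths: int = 5,
    noise_sd: float | None = None,
    seed: int = 0,
    grid_size: int = 32,
    rr_per_min: float = 15.0,
    gain: float = 1.0,
    noise_frac: float = 0.01,
) -> EITSeries:
    """Synthesize an EIT frame series matching a phantom step's ground truth.

    Each quadrant deposits a smooth Gaussian blob (confined to its quadrant
    of the pixel grid); the blob's summed intensity is
    ``gain * (EELV_q + TV_q * s(t))`` with ``s`` the shared breath shape, so
    regional impedance is exactly proportional to regional air volume.
    Per-pixel additive Gaussian noise defaults to ``noise_frac`` (1%) of the
    peak per-pixel tidal amplitude; pass ``noise_sd`` to set it absolutely.
    Reproducible under ``seed``.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be > 0")
    if n_breaths < 1:
        raise ValueError("n_breaths must be >= 1")
    rng = np.random.default_rng(seed)
    period = 60.0 / rr_per_min
    n_frames = int(round(n_breaths * period * frame_rate_hz)) + 1
    t = np.arange(n_frames) / frame_rate_hz
    s = _breath_cycle(t, period)

    N = grid_size
    rows = np.arange(N)[:, None]
    cols = np.arange(N)[None, :]
    centres = {  # (row, col) blob centres; rows run ventral->dorsal, cols right->left
        "VL": (0.25 * N - 0.5, 0.75 * N - 0.5),
        "VR": (0.25 * N - 0.5, 0.25 * N - 0.5),
        "DL": (0.75 * N - 0.5, 0.75 * N - 0.5),
        "DR": (0.75 * N - 0.5, 0.25 * N - 0.5),
    }
    half = N // 2
    windows = {
        "VL": (rows < half) & (cols >= half),
        "VR": (rows < half) & (cols < half),
        "DL": (rows >= half) & (cols >= half),
        "DR": (rows >= half) & (cols < half),
    }
    sigma = max(N / 10.0, 1.0)
    blobs = {}
    for q in QUADRANTS:
        r0, c0 = centres[q]
        g = np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * sigma**2))
        g = np.where(windows[q], g, 0.0)
        blobs[q] = g / g.sum()

    tv_q = truth.quadrant_tv_ml
    frames = np.zeros((n_frames, N, N), dtype=np.float64)
    for q in QUADRANTS:
        amp = gain * (truth.quadrant_exp_ml[q] + tv_q[q] * s)
        frames += amp[:, None, None] * blobs[q][None, :, :]
    if noise_sd is None:
        peak_pixel_tidal = gain * max(
            abs(tv_q[q]) * float(blobs[q].max()) for q in QUADRANTS
        )
        noise_sd = noise_frac * peak_pixel_tidal
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    return EITSeries(frames.astype(np.float32), frame_rate_hz, step_id=truth.step_id)


def generate_ventilator_waveform(
    tv_ml: float,
    rr_per_min: float = 15.0,
    peep_cmH2O: float = 5.0,
    frame_rate_hz: float = 50.0,
    n_breaths: int = 5,
    seed: int = 0,
    insp_frac: float = 1.0 / 3.0,
    compliance_ml_per_cmH2O: float = 50.0,
    resistance_cmH2O_s_per_l: float = 10.0,
    noise_sd_ml: float = 0.0,
) -> pd.DataFrame:
    """Volume-controlled ventilator curves: time, volume, flow, pressure.

    The volume curve rises linearly during inspiration (constant flow) and
    decays exponentially during expiration, with peak-to-trough amplitude
    exactly ``tv_ml``.  Pressure is ``PEEP + V/C + R*flow`` during
    inspiration (single-compartment model).
    """
    if tv_ml <= 0:
        raise ValueError("tv_ml must be > 0")
    if rr_per_min <= 0:
        raise ValueError("rr_per_min must be > 0")
    rng = np.random.default_rng(seed)
    period = 60.0 / rr_per_min
    n = int(round(n_breaths * period * frame_rate_hz)) + 1
    t = np.arange(n) / frame_rate_hz
    shape = _breath_cycle(t, period, insp_frac)
    # The sampling grid need not hit the end-inspiratory instant exactly;
    # rescale so the peak-to-trough amplitude is exactly tv_ml.
    vol = tv_ml * shape / shape.max()
    flow = np.gradient(vol, t)
    insp = np.mod(t, period) < insp_frac * period
    pressure = (
        peep_cmH2O
        + vol / compliance_ml_per_cmH2O
        + np.where(insp, resistance_cmH2O_s_per_l * flow / 1000.0, 0.0)
    )
    if noise_sd_ml > 0:
        vol = vol + rng.normal(0.0, noise_sd_ml, n)
    return pd.DataFrame(
        {
            "time_s": t,
            "volume_ml": vol,
            "flow_ml_s": flow,
            "pressure_cmH2O": pressure,
        }
    )


def _recruit_fraction(peep: float, lo: float = 0.05, hi: float = 0.55) -> float:
    """Dorsal expiratory air fraction of the lavaged lung vs PEEP (sigmoid).

    Logistic in PEEP (centre 12 cmH2O, width 4), rescaled to run exactly from
    ``lo`` at PEEP 0 to ``hi`` at PEEP 25 -- a qualitative model of
    gravity-dependent recruitment.
    """

    def sig(p):
        return 1.0 / (1.0 + np.exp(-(p - 12.0) / 4.0))

    return lo + (hi - lo) * (sig(peep) - sig(0.0)) / (sig(25.0) - sig(0.0))


def protocol_steps(
    weight_kg: float = 66.0,
    ventilated_side: str = "right",
    capacity_ml_per_kg: float = CAPACITY_ML_PER_KG,
) -> list[ProtocolStep]:
    """The 18-step ventilation protocol (quadrant order VL, VR, DL, DR).

    Part 1 (D11-D19): PEEP 15/10/5 cmH2O, each at TV 12/10/8 ml/kg.
    Part 2 (D21): one-lung ventilation at PEEP 5, TV 8; D22 restores two-lung.
    Part 3 (D31-D37): post-lavage recruitment, PEEP 0, 25, 20, 15, 10, 5, 0,
    with the dorsal expiratory air fraction rising sigmoidally with PEEP.
    """
    if weight_kg <= 0:
        raise ValueError("weight_kg must be > 0")
    capacity_ml = capacity_ml_per_kg * weight_kg
    steps: list[ProtocolStep] = []

    def healthy_exp(peep):
        fv = 0.32 + 0.008 * peep
        fd = 0.28 + 0.008 * peep
        return np.array([fv, fv, fd, fd])

    i = 0
    for peep in (15, 10, 5):
        for tvkg in (12, 10, 8):
            i += 1
            tv = tvkg * weight_kg
            df = tv / capacity_ml
            fe = healthy_exp(peep)
            steps.append(
                ProtocolStep(
                    step_id=f"D1{i}",
                    peep_cmH2O=peep,
                    tv_ml=tv,
                    tv_ml_per_kg=tvkg,
                    mode="two-lung",
                    quadrant_air_fraction_exp=tuple(fe),
                    quadrant_air_fraction_insp=tuple(fe + df),
                )
            )

    tv = 8 * weight_kg
    df = tv / capacity_ml
    fe = healthy_exp(5)
    vent_left = ventilated_side == "left"
    # Ventilated side receives the whole tidal volume (fraction swing doubles);
    # the contralateral side is apnoeic with reduced expiratory aeration.
    fe_ol = fe.copy()
    dfi = np.zeros(4)
    if vent_left:
        fe_ol[[1, 3]] = 0.15
        dfi[[0, 2]] = 2 * df
    else:
        fe_ol[[0, 2]] = 0.15
        dfi[[1, 3]] = 2 * df
    steps.append(
        ProtocolStep(
            step_id="D21",
            peep_cmH2O=5,
            tv_ml=tv,
            tv_ml_per_kg=8,
            mode="one-lung-left" if vent_left else "one-lung-right",
            quadrant_air_fraction_exp=tuple(fe_ol),
            quadrant_air_fraction_insp=tuple(fe_ol + dfi),
        )
    )
    steps.append(
        ProtocolStep(
            step_id="D22",
            peep_cmH2O=5,
            tv_ml=tv,
            tv_ml_per_kg=8,
            mode="two-lung",
            quadrant_air_fraction_exp=tuple(fe),
            quadrant_air_fraction_insp=tuple(fe + df),
        )
    )

    tv = 8 * weight_kg
    df = tv / capacity_ml
    for j, peep in enumerate((0, 25, 20, 15, 10, 5, 0), start=1):
        fd = _recruit_fraction(peep)
        fe = np.array([0.35, 0.35, fd, fd])
        # Aerated lung ventilates: the fraction swing scales with regional
        # expiratory aeration while preserving the volume-weighted mean.
        dfq = df * fe / fe.mean()
        steps.append(
            ProtocolStep(
                step_id=f"D3{j}",
                peep_cmH2O=peep,
                tv_ml=tv,
                tv_ml_per_kg=8,
                mode="lavage",
                quadrant_air_fraction_exp=tuple(fe),
                quadrant_air_fraction_insp=tuple(np.minimum(fe + dfq, 1.0)),
            )
        )
    return steps


@dataclass(frozen=True)
class StepData:
    """Everything generated for one protocol step."""

    step: ProtocolStep
    ct_insp: CTVolume
    ct_exp: CTVolume
    eit: EITSeries
    waveform: pd.DataFrame
    truth: GroundTruth


def generate_protocol(
    spec: PhantomSpec,
    weight_kg: float = 66.0,
    seed: int | None = None,
    ventilated_side: str = "right",
    frame_rate_hz: float = 50.0,
    n_breaths: int = 5,
    eit_noise_frac: float = 0.01,
    eit_grid_size: int = 32,
    steps: list[ProtocolStep] | None = None,
) -> list[StepData]:
    """Generate the full 18-step protocol for one phantom animal.

    All randomness fans out from ``seed`` (default ``spec.seed``) through
    per-step substreams, so a fixed seed reproduces the run bit-for-bit.
    """
    if steps is None:
        steps = protocol_steps(weight_kg, ventilated_side=ventilated_side)
    root = np.random.default_rng(spec.seed if seed is None else seed)
    out = []
    for step in steps:
        s_ct, s_eit, s_wave = (int(v) for v in root.integers(0, 2**31 - 1, 3))
        ct_insp, ct_exp, truth = generate_ct_pair(spec, step, seed=s_ct)
        eit = generate_eit_series(
            truth,
            frame_rate_hz=frame_rate_hz,
            n_breaths=n_breaths,
            noise_frac=eit_noise_frac,
            seed=s_eit,
            grid_size=eit_grid_size,
            rr_per_min=step.rr_per_min,
        )
        wave = generate_ventilator_waveform(
            tv_ml=max(truth.tv_total_ml, 1e-9),
            rr_per_min=step.rr_per_min,
            peep_cmH2O=step.peep_cmH2O,
            frame_rate_hz=frame_rate_hz,
            n_breaths=n_breaths,
            seed=s_wave,
        )
        out.append(StepData(step, ct_insp, ct_exp, eit, wave, truth))
    return out
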