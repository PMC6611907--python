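"""EIT signal analysis: waveforms, breaths, tidal images, regional values.

An EIT recording is a time-ordered stack of relative-impedance pixel maps.
The global waveform (per-frame pixel sum) tracks lung air content; its local
maxima/minima segment breaths; the mean end-inspiratory minus end-expiratory
frame is the tidal image; quadrant sums of the tidal image yield regional
ventilation percentages.  End-expiratory impedance levels between two
recordings give regional dEELI, the EIT analogue of end-expiratory lung
volume change.  Waveform agreement with the ventilator volume curve is
measured by the normalized cross-correlation function (NCCF): both curves
are z-normalized and the Pearson correlation is maximized over integer-frame
phase shifts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .grids import QUADRANTS, RegionLabelMask

__all__ = [
    "EITSeries",
    "BreathSegmentation",
    "global_waveform",
    "detect_breaths",
    "tidal_image",
    "regional_percentages",
    "side_shares",
    "detect_ventilated_side",
    "delta_eeli",
    "nccf",
]


@dataclass(frozen=True)
class EITSeries:
    """Time-ordered relative-impedance frames at a fixed frame rate."""

    frames: np.ndarray
    frame_rate_hz: float
    step_id: str | None = None

    def __post_init__(self):
        fr = np.asarray(self.frames)
        if fr.ndim != 3:
            raise ValueError(f"frames must be (n_frames, h, w), got shape {fr.shape}")
        if self.frame_rate_hz <= 0:
            raise ValueError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        object.__setattr__(self, "frames", fr)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass(frozen=True)
class BreathSegmentation:
    """Frame indices of end-inspiration (peaks) and end-expiration (troughs)."""

    end_inspiratory: np.ndarray
    end_expiratory: np.ndarray

    def __post_init__(self):
        for name in ("end_inspiratory", "end_expiratory"):
            idx = np.asarray(getattr(self, name), dtype=int)
            if idx.size > 1 and np.any(np.diff(idx) <= 0):
                raise ValueError(f"{name} indices must be strictly increasing")
            object.__setattr__(self, name, idx)

    @property
    def n_breaths(self) -> int:
        """Complete breaths: end-inspirations with a preceding end-expiration."""
        return len(self.pairs())

    def pairs(self) -> list[tuple[int, int]]:
        """(end-expiratory, end-inspiratory) index pairs, one per breath."""
        out = []
        for insp in self.end_inspiratory:
            prev = self.end_expiratory[self.end_expiratory < insp]
            if prev.size:
                out.append((int(prev[-1]), int(insp)))
        return out


def global_waveform(series: EITSeries) -> np.ndarray:
    """Per-frame sum over all pixels (the EIT plethysmogram)."""
    if series.n_frames == 0:
        raise ValueError("empty EIT series")
    return series.frames.sum(axis=(1, 2), dtype=np.float64)


def detect_breaths(
    waveform: np.ndarray,
    frame_rate_hz: float,
    min_breath_s: float = 1.5,
    min_prominence_frac: float = 0.25,
) -> BreathSegmentation:
    """Segment breaths from a respiratory waveform.

    Local maxima are end-inspiratory, local minima end-expiratory, subject to
    a minimum separation of ``min_breath_s`` and a prominence of at least
    ``min_prominence_frac`` of the global peak-to-trough range.  Boundary
    minima before the first / after the last peak are recovered so that a
    recording starting at end-expiration yields complete breaths.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 2 * min_breath_s * frame_rate_hz:
        raise ValueError(
            f"waveform too short: {w.size} samples < "
            f"2 * {min_breath_s} s * {frame_rate_hz} Hz"
        )
    span = float(np.ptp(w))
    if span <= 0:
        warnings.warn("detect_breaths: constant waveform, no breaths found", stacklevel=2)
        return BreathSegmentation(np.array([], int), np.array([], int))
    dist = max(1, int(round(min_breath_s * frame_rate_hz)))
    prom = min_prominence_frac * span
    peaks, _ = find_peaks(w, distance=dist, prominence=prom)
    troughs, _ = find_peaks(-w, distance=dist, prominence=prom)
    if peaks.size == 0:
        warnings.warn("detect_breaths: no breaths found", stacklevel=2)
        return BreathSegmentation(np.array([], int), np.array([], int))
    ext = list(troughs)
    if troughs.size == 0 or troughs[0] > peaks[0]:
        ext.insert(0, int(np.argmin(w[: peaks[0]])))
    if troughs.size == 0 or troughs[-1] < peaks[-1]:
        tail = peaks[-1] + int(np.argmin(w[peaks[-1] :]))
        if tail > peaks[-1]:
            ext.append(tail)
    return BreathSegmentation(np.asarray(peaks, int), np.unique(np.asarray(ext, int)))


def tidal_image(series: EITSeries, seg: BreathSegmentation) -> np.ndarray:
    """Mean end-inspiratory minus preceding end-expiratory frame over breaths."""
    pairs = seg.pairs()
    if not pairs:
        raise ValueError("no complete breath in segmentation")
    acc = np.zeros(series.frames.shape[1:], dtype=np.float64)
    for exp_i, insp_i in pairs:
        acc += series.frames[insp_i].astype(np.float64) - series.frames[exp_i]
    return acc / len(pairs)


def _quadrant_sums(image: np.ndarray, mask: RegionLabelMask) -> np.ndarray:
    if image.shape != mask.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs mask {mask.shape}")
    return np.array(
        [float(image[reg].sum(dtype=np.float64)) for _, reg in mask.iter_regions()]
    )


def regional_percentages(tidal_map: np.ndarray, mask: RegionLabelMask) -> dict[str, float]:
    """Quadrant percentages of the four-quadrant tidal-image total.

    Negative pixels (noise) are retained so percentages stay unbiased; the
    four values sum to 100.
    """
    sums = _quadrant_sums(np.asarray(tidal_map), mask)
    total = sums.sum()
    if total <= 0:
        raise ValueError("four-quadrant tidal total is <= 0; percentages undefined")
    return dict(zip(QUADRANTS, (sums / total * 100.0).tolist()))


def side_shares(percentages: dict[str, float]) -> tuple[float, float]:
    """(left %, right %) from quadrant percentages: L = VL+DL, R = VR+DR."""
    left = percentages["VL"] + percentages["DL"]
    right = percentages["VR"] + percentages["DR"]
    return float(left), float(right)


def detect_ventilated_side(
    left_pct: float, right_pct: float, threshold: float = 65.0
) -> str:
    """Classify ventilation as 'left', 'right' or 'bilateral' by side share."""
    if left_pct > threshold:
        return "left"
    if right_pct > threshold:
        return "right"
    return "bilateral"


def end_expiratory_levels(
    series: EITSeries, mask: RegionLabelMask, seg: BreathSegmentation | None = None
) -> np.ndarray:
    """Mean end-expiratory quadrant impedance levels (VL, VR, DL, DR)."""
    if seg is None:
        seg = detect_breaths(global_waveform(series), series.frame_rate_hz)
    if seg.end_expiratory.size == 0:
        raise ValueError("series is not segmentable: no end-expiratory frames")
    frames = series.frames[seg.end_expiratory].mean(axis=0, dtype=np.float64)
    return _quadrant_sums(frames, mask)


def delta_eeli(
    series_a: EITSeries, series_b: EITSeries, mask: RegionLabelMask
) -> dict[str, float]:
    """Per-quadrant end-expiratory impedance change, series_b minus series_a.

    Sign convention: positive values mean the later (``series_b``) recording
    holds more end-expiratory impedance, i.e. recruitment.
    """
    lev_a = end_expiratory_levels(series_a, mask)
    lev_b = end_expiratory_levels(series_b, mask)
    return dict(zip(QUADRANTS, (lev_b - lev_a).tolist()))


def nccf(
    curve_a: np.ndarray,
    curve_b: np.ndarray,
    max_lag_s: float = 2.0,
    frame_rate_hz: float = 50.0,
    frame_rate_b_hz: float | None = None,
    min_overlap: int = 10,
) -> tuple[float, float]:
    """Normalized cross-correlation function maximum and its lag.

    Both curves are z-normalized (mean subtracted, unit standard deviation)
    on their overlap and the Pearson correlation is evaluated at every
    integer-frame lag within ``+-max_lag_s``; the maximum and its lag in
    seconds are returned.  A positive lag means ``curve_b`` trails
    ``curve_a``.  If ``frame_rate_b_hz`` differs, ``curve_b`` is linearly
    resampled onto the common rate first.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if frame_rate_b_hz is not None and frame_rate_b_hz != frame_rate_hz:
        t_b = np.arange(b.size) / frame_rate_b_hz
        t_new = np.arange(0, t_b[-1] + 0.5 / frame_rate_hz, 1.0 / frame_rate_hz)
        b = np.interp(t_new, t_b, b)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance curve: NCCF undefined")
    max_lag = int(round(max_lag_s * frame_rate_hz))
    best_r, best_lag = -np.inf, 0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            seg_a, seg_b = a[: a.size - lag] if lag else a, b[lag:]
        else:
            seg_a, seg_b = a[-lag:], b[: b.size + lag]
        m = min(seg_a.size, seg_b.size)
        if m < min_overlap:
            continue
        seg_a, seg_b = seg_a[:m], seg_b[:m]
        sa, sb = np.std(seg_a), np.std(seg_b)
        if sa == 0 or sb == 0:
            continue
        za = (seg_a - seg_a.mean()) / sa
        zb = (seg_b - seg_b.mean()) / sb
        r = float(np.mean(za * zb))
        if r > best_r:
            best_r, best_lag = r, lag
    if not np.isfinite(best_r):
        raise ValueError("no lag with sufficient overlap")
    return best_r, best_lag / frame_rate_hz
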