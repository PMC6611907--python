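"""EIT waveforms, breath segmentation, regional percentages, NCCF."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import eitdect as e
from eitdect.eit_analysis import BreathSegmentation, EITSeries, end_expiratory_levels
from eitdect.grids import QUADRANTS


def _series_from_wave(wave, shape=(4, 4), fs=50.0):
    frames = np.asarray(wave, float)[:, None, None] * np.ones(shape)[None] / np.prod(shape)
    return EITSeries(frames, fs)


def test_global_waveform_equals_pixel_trace():
    wave = np.sin(np.linspace(0, 6 * np.pi, 300))
    series = EITSeries(wave[:, None, None], 50.0)
    assert np.allclose(e.global_waveform(series), wave)


def test_global_waveform_rejects_empty():
    with pytest.raises(ValueError):
        e.global_waveform(EITSeries(np.zeros((0, 4, 4)), 50.0))


def test_detect_breaths_counts_peaks():
    t = np.arange(0, 20, 0.02)
    wave = 1 - np.cos(2 * np.pi * t / 4)  # 5 breaths of 4 s
    seg = e.detect_breaths(wave, 50.0)
    assert len(seg.end_inspiratory) == 5
    assert len(seg.end_expiratory) in (5, 6)
    assert seg.n_breaths == 5


def test_detect_breaths_constant_waveform_empty():
    with pytest.warns(UserWarning):
        seg = e.detect_breaths(np.ones(500), 50.0)
    assert seg.n_breaths == 0


def test_detect_breaths_robust_to_noise():
    t = np.arange(0, 40, 0.02)
    clean = 1 - np.cos(2 * np.pi * t / 4)  # 10 breaths
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        noisy = clean + rng.normal(0, 0.02, t.size)
        if len(e.detect_breaths(noisy, 50.0).end_inspiratory) == 10:
            hits += 1
    assert hits >= 9


def test_tidal_image_exact_difference():
    frames = np.zeros((3, 2, 2))
    frames[1] = [[2.0, 1.0], [0.5, 0.0]]
    series = EITSeries(frames, 50.0)
    seg = BreathSegmentation(np.array([1]), np.array([0]))
    assert np.allclose(e.tidal_image(series, seg), frames[1])


def test_tidal_image_requires_complete_breath():
    series = EITSeries(np.zeros((10, 2, 2)), 50.0)
    seg = BreathSegmentation(np.array([2]), np.array([5]))  # no exp before insp
    with pytest.raises(ValueError, match="complete breath"):
        e.tidal_image(series, seg)


def test_regional_percentages_uniform_and_concentrated():
    mask = e.eit_quadrant_mask(grid_size=8)
    pct = e.regional_percentages(np.ones((8, 8)), mask)
    assert all(pct[q] == pytest.approx(25.0, abs=1e-9) for q in QUADRANTS)
    img = np.zeros((8, 8))
    img[mask.region("VR")] = 3.0
    pct = e.regional_percentages(img, mask)
    assert pct["VR"] == pytest.approx(100.0)
    assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)


def test_regional_percentages_reject_nonpositive_total():
    mask = e.eit_quadrant_mask(grid_size=4)
    with pytest.raises(ValueError, match="undefined"):
        e.regional_percentages(np.zeros((4, 4)), mask)


@pytest.mark.parametrize(
    "pct,expected",
    [((25, 25, 25, 25), (50, 50)), ((10, 40, 15, 35), (25, 75))],
)
def test_side_shares_arithmetic(pct, expected):
    d = dict(zip(QUADRANTS, pct))
    assert e.side_shares(d) == pytest.approx(expected)


@pytest.mark.parametrize(
    "left,right,call",
    [(74.78, 25.22, "left"), (25.22, 74.78, "right"), (50, 50, "bilateral"), (65, 35, "bilateral")],
)
def test_detect_ventilated_side(left, right, call):
    assert e.detect_ventilated_side(left, right) == call


def test_side_detection_invariant_to_intensity_scaling():
    mask = e.eit_quadrant_mask(grid_size=8)
    img = np.zeros((8, 8))
    img[mask.region("VR")] = 1.0
    img[mask.region("DR")] = 2.0
    for scale in (1.0, 17.3):
        pct = e.regional_percentages(img * scale, mask)
        assert e.detect_ventilated_side(*e.side_shares(pct)) == "right"


def test_delta_eeli_zero_and_offset_linearity():
    t = np.arange(0, 12, 0.02)
    wave = 1 - np.cos(2 * np.pi * t / 4)
    series = _series_from_wave(wave)
    mask = e.eit_quadrant_mask(grid_size=4)
    d0 = e.delta_eeli(series, series, mask)
    assert all(abs(v) <= 1e-12 for v in d0.values())
    offset = EITSeries(series.frames + 2.0, 50.0)
    d = e.delta_eeli(series, offset, mask)
    for q in QUADRANTS:
        assert d[q] == pytest.approx(2.0 * int(mask.region(q).sum()), rel=1e-9)


def test_delta_eeli_rejects_unsegmentable():
    flat = EITSeries(np.ones((400, 4, 4)), 50.0)
    mask = e.eit_quadrant_mask(grid_size=4)
    with pytest.warns(UserWarning):
        with pytest.raises(ValueError):
            e.delta_eeli(flat, flat, mask)


def test_nccf_self_and_shifted_copy():
    rng = np.random.default_rng(0)
    x = np.cumsum(rng.normal(size=600))
    r, lag = e.nccf(x, x, max_lag_s=1.0, frame_rate_hz=50.0)
    assert r == pytest.approx(1.0, abs=1e-12)
    assert lag == 0.0
    k = 17
    trailing = np.concatenate([np.zeros(k), x])[: x.size]  # trailing[t] = x[t-k]
    r, lag = e.nccf(x[k:], trailing[k:], max_lag_s=1.0, frame_rate_hz=50.0)
    assert r == pytest.approx(1.0, abs=1e-12)
    assert lag == pytest.approx(k / 50.0)  # positive lag: second curve trails


def test_nccf_white_noise_null_level():
    rs = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=1000), rng.normal(size=1000)
        rs.append(e.nccf(a, b, max_lag_s=2.0, frame_rate_hz=50.0)[0])
    assert np.mean(rs) <= 0.15


def test_nccf_rejects_zero_variance():
    with pytest.raises(ValueError, match="zero-variance"):
        e.nccf(np.ones(100), np.arange(100.0), frame_rate_hz=50.0)


def test_nccf_resamples_other_rate():
    t50 = np.arange(0, 12, 0.02)
    t25 = np.arange(0, 12, 0.04)
    a = np.sin(2 * np.pi * t50 / 4)
    b = np.sin(2 * np.pi * t25 / 4)
    r, lag = e.nccf(a, b, max_lag_s=1.0, frame_rate_hz=50.0, frame_rate_b_hz=25.0)
    assert r >= 0.999 and abs(lag) <= 0.02


@given(
    scale=st.floats(0.1, 50),
    offset=st.floats(-10, 10),
    seed=st.integers(0, 50),
)
def test_nccf_bounded_and_affine_invariant(scale, offset, seed):
    rng = np.random.default_rng(seed)
    a = np.cumsum(rng.normal(size=200))
    b = np.cumsum(rng.normal(size=200))
    r, _ = e.nccf(a, b, max_lag_s=0.5, frame_rate_hz=50.0)
    assert -1.0 - 1e-9 <= r <= 1.0 + 1e-9
    r2, _ = e.nccf(a, scale * b + offset, max_lag_s=0.5, frame_rate_hz=50.0)
    assert r2 == pytest.approx(r, abs=1e-9)


def test_end_expiratory_levels_track_baseline():
    t = np.arange(0, 12, 0.02)
    wave = 5.0 + (1 - np.cos(2 * np.pi * t / 4))
    series = _series_from_wave(wave)
    mask = e.eit_quadrant_mask(grid_size=4)
    levels = end_expiratory_levels(series, mask)
    assert np.allclose(levels.sum(), 5.0, atol=0.05)
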