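"""Synthetic phantom: forward model, ground truth, protocol, waveforms."""
import numpy as np
import pytest

import eitdect as e
from eitdect.grids import QUADRANTS
from eitdect.phantom import _phantom_fields


def test_lung_voxels_carry_forward_model_hu(small_spec, uniform_step, phantom_pair):
    insp, exp, _ = phantom_pair
    X, Y, Z, body, lungs = _phantom_fields(small_spec)
    lung = lungs[0] | lungs[1]
    # keep clear of the electrode markers (on the body surface)
    assert np.allclose(exp.hu[lung], -300.0, atol=1e-3)
    assert np.allclose(insp.hu[lung], -500.0, atol=1e-3)
    tissue = body & ~lung
    assert np.median(np.abs(exp.hu[tissue] - small_spec.hu_tissue)) <= 1e-3


def test_ground_truth_matches_bruteforce_voxel_count(small_spec, uniform_step, phantom_pair):
    """TV = delta_fraction x lung voxel count x voxel volume (closed form)."""
    _, _, truth = phantom_pair
    X, Y, Z, body, lungs = _phantom_fields(small_spec)
    n_lung = int((lungs[0] | lungs[1]).sum())
    vox_ml = e.voxel_volume_mm3(small_spec.spacing_mm) / 1000.0
    assert truth.tv_total_ml == pytest.approx(0.2 * n_lung * vox_ml, rel=1e-6)
    assert truth.eelv_ml == pytest.approx(0.3 * n_lung * vox_ml, rel=1e-6)


def test_hu_mapping_and_phantom_are_mutual_inverses(phantom_pair, small_spec):
    insp, _, _ = phantom_pair
    X, Y, Z, body, lungs = _phantom_fields(small_spec)
    lung = lungs[0] | lungs[1]
    recovered = e.hu_to_air_fraction(insp.hu)[lung]
    assert np.abs(recovered - 0.5).max() <= 1e-6


def test_ground_truth_invariant_under_grid_refinement(uniform_step):
    coarse = e.PhantomSpec(grid_shape=(96,) * 3, spacing_mm=(1.0,) * 3, noise_sd_hu=0)
    fine = e.PhantomSpec(grid_shape=(192,) * 3, spacing_mm=(0.5,) * 3, noise_sd_hu=0)
    _, _, t_c = e.generate_ct_pair(coarse, uniform_step, seed=0)
    _, _, t_f = e.generate_ct_pair(fine, uniform_step, seed=0)
    assert t_c.analytic_tv_total_ml == pytest.approx(t_f.analytic_tv_total_ml, rel=1e-12)
    assert t_c.tv_total_ml == pytest.approx(t_f.tv_total_ml, rel=0.01)
    assert t_f.tv_total_ml == pytest.approx(t_f.analytic_tv_total_ml, rel=0.01)


def test_one_lung_mode_freezes_contralateral_side(small_spec):
    steps = {s.step_id: s for s in e.protocol_steps(66, ventilated_side="right")}
    _, _, truth = e.generate_ct_pair(small_spec, steps["D21"], seed=5)
    assert truth.ventilated_side == "right"
    for q in ("VL", "DL"):  # left quadrants do not ventilate
        assert truth.quadrant_insp_ml[q] == pytest.approx(truth.quadrant_exp_ml[q], abs=1e-9)
    for q in ("VR", "DR"):
        assert truth.quadrant_insp_ml[q] > truth.quadrant_exp_ml[q]


def test_ct_pair_deterministic_under_seed(uniform_step):
    spec = e.PhantomSpec(grid_shape=(32,) * 3, spacing_mm=(3.0,) * 3, noise_sd_hu=20)
    a_i, a_e, _ = e.generate_ct_pair(spec, uniform_step, seed=7)
    b_i, b_e, _ = e.generate_ct_pair(spec, uniform_step, seed=7)
    assert np.array_equal(a_i.hu, b_i.hu)
    assert np.array_equal(a_e.hu, b_e.hu)


def test_phantom_rejects_lung_outside_body():
    with pytest.raises(ValueError, match="inside the body"):
        e.PhantomSpec(lung_centers_mm=((35.0, 0.0, 0.0), (-18.0, 0.0, 0.0)))


def test_phantom_rejects_nonpositive_spacing():
    with pytest.raises(ValueError, match="spacing"):
        e.PhantomSpec(spacing_mm=(0.75, -0.75, 0.75))


def test_protocol_defines_18_steps_with_stated_settings():
    steps = e.protocol_steps(weight_kg=66.0)
    assert len(steps) == 18
    assert [s.step_id for s in steps[:9]] == [f"D1{i}" for i in range(1, 10)]
    assert steps[0].tv_ml == pytest.approx(792.0)  # 12 ml/kg x 66 kg
    assert steps[0].peep_cmH2O == 15
    d21 = steps[9]
    assert d21.step_id == "D21" and d21.ventilated_side in ("left", "right")
    assert [s.peep_cmH2O for s in steps[11:]] == [0, 25, 20, 15, 10, 5, 0]
    assert all(s.mode == "lavage" for s in steps[11:])


def test_lavage_dorsal_recruitment_increases_with_peep():
    steps = [s for s in e.protocol_steps(66) if s.mode == "lavage"]
    by_peep = sorted(steps, key=lambda s: s.peep_cmH2O)
    dorsal = [s.quadrant_air_fraction_exp[2] for s in by_peep]
    assert all(b >= a for a, b in zip(dorsal, dorsal[1:]))
    assert dorsal[0] == pytest.approx(0.05, abs=1e-9)
    assert max(dorsal) == pytest.approx(0.55, abs=1e-9)


def test_waveform_amplitude_and_columns():
    wf = e.generate_ventilator_waveform(tv_ml=600.0, n_breaths=5)
    assert list(wf.columns) == ["time_s", "volume_ml", "flow_ml_s", "pressure_cmH2O"]
    vol = wf["volume_ml"].to_numpy()
    assert np.ptp(vol) == pytest.approx(600.0, rel=1e-12)
    seg = e.detect_breaths(vol, 50.0)
    assert len(seg.end_inspiratory) == 5


def test_waveform_ie_ratio_timing():
    """I:E of 1:2 at 15/min puts end-inspiration at 4/3 s into the cycle."""
    wf = e.generate_ventilator_waveform(tv_ml=500.0, rr_per_min=15.0, n_breaths=1)
    t_peak = wf["time_s"].to_numpy()[np.argmax(wf["volume_ml"].to_numpy())]
    assert t_peak == pytest.approx(4.0 / 3.0, abs=0.02)


def test_eit_series_symmetry_and_reproducibility(phantom_pair):
    _, _, truth = phantom_pair
    series = e.generate_eit_series(truth, noise_sd=0.0, seed=1, n_breaths=3)
    mask = e.eit_quadrant_mask(grid_size=32)
    seg = e.detect_breaths(e.global_waveform(series), series.frame_rate_hz)
    tmap = e.tidal_image(series, seg)
    sums = np.array([tmap[mask.region(q)].sum() for q in QUADRANTS])
    # equal quadrant tidal volumes -> equal quadrant tidal intensities
    assert np.allclose(sums, sums[0], rtol=1e-4)
    a = e.generate_eit_series(truth, seed=3, n_breaths=2)
    b = e.generate_eit_series(truth, seed=3, n_breaths=2)
    assert np.array_equal(a.frames, b.frames)


def test_eit_waveform_tracks_generating_volume_curve(phantom_pair):
    _, _, truth = phantom_pair
    series = e.generate_eit_series(truth, noise_sd=0.0, seed=1, n_breaths=4)
    wf = e.generate_ventilator_waveform(tv_ml=truth.tv_total_ml, n_breaths=4)
    r, lag = e.nccf(
        e.global_waveform(series), wf["volume_ml"].to_numpy(), frame_rate_hz=50.0
    )
    assert r == pytest.approx(1.0, abs=1e-9)
    assert lag == 0.0


def test_zero_ventilation_yields_flat_series(phantom_pair, small_spec, uniform_step):
    step = e.ProtocolStep(
        "FLAT", 5.0, 1.0,
        quadrant_air_fraction_exp=(0.3,) * 4, quadrant_air_fraction_insp=(0.3,) * 4,
    )
    _, _, truth = e.generate_ct_pair(small_spec, step, seed=2)
    series = e.generate_eit_series(truth, seed=0, n_breaths=2)
    wave = e.global_waveform(series)
    assert np.ptp(wave) <= 1e-6 * max(1.0, abs(wave[0]))
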