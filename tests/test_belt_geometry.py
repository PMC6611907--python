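"""Electrode detection, similarity registration, quadrant masks."""
import numpy as np
import pytest

import eitdect as e
from eitdect.belt_geometry import ReferenceGeometry, SimilarityTransform, _umeyama
from eitdect.grids import CTVolume, LABEL_CODES, QUADRANTS


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def test_reference_geometry_equidistant():
    ref = ReferenceGeometry(16)
    gaps = np.diff(ref.angles)
    assert np.allclose(gaps, 2 * np.pi / 16)
    assert np.allclose(np.linalg.norm(ref.positions, axis=1), 1.0)


def test_detect_electrodes_on_phantom(small_spec, phantom_pair):
    _, exp, _ = phantom_pair
    det = e.detect_electrodes(exp, n_expected=small_spec.n_electrodes)
    assert det.n == 16
    true_pos = small_spec.electrode_positions(include_indicators=False)
    # match detected centroids to generating positions within one voxel
    for p in det.positions:
        d = np.linalg.norm(true_pos - p, axis=1).min()
        assert d <= max(small_spec.spacing_mm) * np.sqrt(3)


def test_detect_electrodes_excludes_indicators(small_spec, phantom_pair):
    _, exp, _ = phantom_pair
    with pytest.raises(ValueError, match="18"):
        e.detect_electrodes(exp, n_expected=16, exclude_indicators=False)


def test_detect_electrodes_errors_without_metal():
    ct = CTVolume(np.zeros((8, 8, 8)), (1, 1, 1))
    with pytest.raises(ValueError, match="0 electrodes"):
        e.detect_electrodes(ct)


def test_fit_identity_on_reference_points():
    ref = ReferenceGeometry(16)
    det = e.ElectrodeSet(ref.positions, labels=tuple(range(1, 17)))
    tf = e.fit_reference_transform(det, ref)
    assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)
    assert tf.scale == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(tf.translation, 0, atol=1e-9)
    assert tf.rms_residual <= 1e-9


@pytest.mark.parametrize("seed", range(5))
def test_fit_recovers_constructed_similarity(seed):
    """Exact recovery of rotation, scale, translation to 1e-6."""
    rng = np.random.default_rng(seed)
    ref = ReferenceGeometry(16)
    R = _random_rotation(rng)
    s = float(rng.uniform(50, 200))
    t = rng.uniform(-100, 100, 3)
    det = e.ElectrodeSet(s * ref.positions @ R.T + t, labels=tuple(range(1, 17)))
    tf = e.fit_reference_transform(det, ref)
    assert np.allclose(tf.rotation, R, atol=1e-6)
    assert tf.scale == pytest.approx(s, abs=1e-6)
    assert np.allclose(tf.translation, t, atol=1e-6)
    assert tf.rms_residual <= 1e-6


def test_fit_90deg_scale_translation_case():
    ref = ReferenceGeometry(16)
    Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    det = e.ElectrodeSet(140.0 * ref.positions @ Rz.T + (10, 20, 30), tuple(range(1, 17)))
    tf = e.fit_reference_transform(det, ref, max_offset=0)
    assert np.allclose(tf.rotation, Rz, atol=1e-6)
    assert tf.scale == pytest.approx(140.0, abs=1e-6)
    assert np.allclose(tf.translation, (10, 20, 30), atol=1e-6)


def test_fit_residual_with_jitter_bounded():
    ref = ReferenceGeometry(16)
    residuals = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        noisy = 100 * ref.positions + rng.normal(0, 1.0, (16, 3))
        tf = e.fit_reference_transform(e.ElectrodeSet(noisy, tuple(range(1, 17))), ref)
        residuals.append(tf.rms_residual)
    assert all(r > 0 for r in residuals)
    assert np.mean(residuals) <= 2.0


def test_fit_residual_invariant_under_relabeling():
    """Full cyclic search: rolling the detected labels leaves the residual."""
    rng = np.random.default_rng(3)
    ref = ReferenceGeometry(16)
    base = 100 * ref.positions + rng.normal(0, 0.5, (16, 3))
    r0 = e.fit_reference_transform(
        e.ElectrodeSet(base, tuple(range(1, 17))), ref, max_offset=None
    ).rms_residual
    for k in (1, 5, 9):
        rolled = np.roll(base, k, axis=0)
        rk = e.fit_reference_transform(
            e.ElectrodeSet(rolled, tuple(range(1, 17))), ref, max_offset=None
        ).rms_residual
        assert rk == pytest.approx(r0, abs=1e-9)


def test_fit_rejects_collinear():
    pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ValueError, match="collinear"):
        e.ElectrodeSet(pts, tuple(range(1, 6)))


def _symmetric_grid(n=16, spacing=1.0):
    origin = tuple(-(n - 1) / 2 * spacing for _ in range(3))
    return CTVolume(np.zeros((n, n, n)), (spacing,) * 3, origin)


def test_quadrant_mask_symmetric_counts():
    grid = _symmetric_grid(16)
    mask = e.build_quadrant_mask(SimilarityTransform.identity(), grid, slab_thickness_mm=8)
    counts = [int(mask.region(q).sum()) for q in QUADRANTS]
    assert len(set(counts)) == 1 and counts[0] > 0
    # partition: label counts sum to the voxel total
    assert sum(counts) + int((mask.labels == 0).sum()) == 16**3


def test_quadrant_mask_zero_slab_all_unclassified():
    grid = _symmetric_grid(8)
    with pytest.warns(UserWarning):
        mask = e.build_quadrant_mask(SimilarityTransform.identity(), grid, 0.0)
    assert (mask.labels == 0).all()


def test_quadrant_mask_mirror_swaps_left_right():
    """Mirroring across the sagittal plane exchanges L/R label totals."""
    grid = _symmetric_grid(16)
    tf = SimilarityTransform(np.eye(3), 1.0, np.array([0.3, -0.2, 0.1]))
    mask = e.build_quadrant_mask(tf, grid, slab_thickness_mm=10)
    mirrored_tf = SimilarityTransform(np.eye(3), 1.0, np.array([-0.3, -0.2, 0.1]))
    mirrored = e.build_quadrant_mask(mirrored_tf, grid, slab_thickness_mm=10)
    flipped = mirrored.labels[::-1, :, :]
    for a, b in (("VL", "VR"), ("DL", "DR")):
        assert (mask.labels == LABEL_CODES[a]).sum() == (flipped == LABEL_CODES[b]).sum()


def test_quadrant_mask_matches_generator(small_spec, phantom_pair):
    _, exp, _ = phantom_pair
    det = e.detect_electrodes(exp, n_expected=16)
    tf = e.fit_reference_transform(det)
    mask = e.build_quadrant_mask(tf, exp, slab_thickness_mm=small_spec.slab_thickness_mm)
    gen = e.phantom.generator_quadrant_mask(small_spec)
    lung = exp.hu < -150  # lung voxels only (tissue/air outside is irrelevant)
    assert (mask.labels[lung] == gen.labels[lung]).mean() >= 0.999


def test_eit_quadrant_mask_blocks():
    mask = e.eit_quadrant_mask(grid_size=32)
    for q in QUADRANTS:
        assert int(mask.region(q).sum()) == 16 * 16
    tiny = e.eit_quadrant_mask(grid_size=2)
    assert sorted(tiny.labels.ravel().tolist()) == [1, 2, 3, 4]
    # orientation: ventral rows first, patient-left in later columns
    assert tiny.labels[0, 1] == LABEL_CODES["VL"]
    assert tiny.labels[1, 0] == LABEL_CODES["DR"]


def test_shared_quadrant_definition_ct_vs_eit():
    """The same regional pattern yields identical percentages in both spaces."""
    fractions = {"VL": 0.1, "VR": 0.2, "DL": 0.3, "DR": 0.4}
    grid = _symmetric_grid(16)
    mask3d = e.build_quadrant_mask(SimilarityTransform.identity(), grid, slab_thickness_mm=16)
    hu = np.zeros(grid.shape)
    for q, f in fractions.items():
        hu[mask3d.region(q)] = -1000.0 * f
    ct = CTVolume(hu, grid.spacing_mm, grid.origin_mm)
    rep = e.region_air_volume(ct, mask3d)
    ct_pct = np.array([rep.region_ml[q] for q in QUADRANTS])
    ct_pct = ct_pct / ct_pct.sum() * 100

    mask2d = e.eit_quadrant_mask(grid_size=16)
    img = np.zeros((16, 16))
    for q, f in fractions.items():
        img[mask2d.region(q)] = f
    eit_pct = e.regional_percentages(img, mask2d)
    eit_vec = np.array([eit_pct[q] for q in QUADRANTS])
    assert np.allclose(ct_pct, eit_vec, atol=1e-9)
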