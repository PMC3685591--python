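import numpy as np
import pytest

import thermocover as tc
from thermocover.geometry import rotated_square_mask
from thermocover.preprocessing import RoiMask
from thermocover.pulse_geometry import AngleEstimationError, NoPulsesError
from conftest import circular_angle_error, config_for, make_grid_scene


def square_image(side=40, angle=0.0, shape=(120, 120), elevation=2.5):
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    mask = rotated_square_mask(shape, center, side, angle)
    values = np.full(shape, 33.0)
    values[mask] += elevation
    return values, RoiMask(mask=mask)


def square_ring(side, angle, shape=(120, 120), width=2):
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    outer = rotated_square_mask(shape, center, side, angle)
    inner = rotated_square_mask(shape, center, side - 2 * width, angle)
    return outer & ~inner


# --- Canny edges -----------------------------------------------------------


def test_canny_finds_square_contour_of_expected_length():
    values, roi = square_image(side=40)
    edges = tc.canny_edges(values, roi)
    perimeter = 4 * 40
    assert 0.8 * perimeter <= edges.n_edge_pixels <= 1.2 * perimeter


def test_canny_constant_roi_yields_no_edges_with_warning():
    values = np.full((60, 60), 34.0)
    roi = RoiMask(mask=rotated_square_mask((60, 60), (30, 30), 20, 0.0))
    with pytest.warns(UserWarning, match="constant"):
        edges = tc.canny_edges(values, roi)
    assert edges.n_edge_pixels == 0


def test_canny_lowering_high_threshold_only_grows_edge_set():
    values, roi = square_image(side=40)
    strict = tc.canny_edges(values, roi, low=0.05, high=0.4)
    loose = tc.canny_edges(values, roi, low=0.05, high=0.2)
    assert not np.any(strict.mask & ~loose.mask)
    with pytest.raises(ValueError, match="high > low"):
        tc.canny_edges(values, roi, low=0.3, high=0.1)


# --- Radon transform -------------------------------------------------------


def test_radon_line_concentrates_into_single_bin():
    edges = np.zeros((80, 80), bool)
    edges[15:65, 40] = True  # 50-px line along the rows
    sino = tc.radon_transform(tc.EdgeImage(mask=edges), 1.0)
    assert sino.values.max() == 50
    # direct-summation oracle: mass per angle equals the pixel count exactly
    np.testing.assert_array_equal(sino.values.sum(axis=0), np.full(90, 50.0))
    assert tc.estimate_grid_angle(sino) == 0.0


def test_radon_point_conserves_unit_mass_and_is_unidentifiable():
    edges = np.zeros((40, 40), bool)
    edges[20, 20] = True
    sino = tc.radon_transform(tc.EdgeImage(mask=edges), 1.0)
    np.testing.assert_array_equal(sino.values.sum(axis=0), np.ones(90))
    with pytest.raises(AngleEstimationError, match="identifiable"):
        tc.estimate_grid_angle(sino)


def test_radon_peak_shifts_with_square_rotation():
    sino0 = tc.radon_transform(tc.EdgeImage(mask=square_ring(40, 0.0)), 1.0)
    sino30 = tc.radon_transform(tc.EdgeImage(mask=square_ring(40, 30.0)), 1.0)
    a0 = tc.estimate_grid_angle(sino0)
    a30 = tc.estimate_grid_angle(sino30)
    assert circular_angle_error(a30, a0 + 30.0) <= 1.0


def test_radon_empty_edge_image_raises():
    with pytest.raises(AngleEstimationError, match="no edges"):
        tc.radon_transform(tc.EdgeImage(mask=np.zeros((20, 20), bool)), 1.0)


def test_radon_peak_angle_agrees_with_skimage_transform():
    # independent implementation cross-check on the same edge image
    from skimage.transform import radon as sk_radon

    edges = square_ring(40, 20.0)
    sino = tc.radon_transform(tc.EdgeImage(mask=edges), 1.0)
    ours = tc.estimate_grid_angle(sino)
    theta = np.arange(0.0, 90.0)
    sk = sk_radon(edges.astype(float), theta=theta, circle=False)
    sk_peak = float(theta[int(np.argmax(sk.max(axis=0)))])
    assert circular_angle_error(ours, (90.0 - sk_peak) % 90.0) <= 1.0


# --- angle estimation on full scenes --------------------------------------


@pytest.mark.parametrize("angle", [0.0, 17.0, 107.0])
def test_grid_angle_recovered_modulo_ninety(angle):
    scene = make_grid_scene(angle_deg=angle, noise_sd_c=0.05, seed=2)
    img, _ = tc.generate_scene(scene)
    cfg = config_for(scene)
    roi, stack = tc.extract_roi(img, cfg)
    edges = tc.canny_edges(stack.l_med, roi, cfg.canny_low, cfg.canny_high, cfg.canny_sigma)
    est = tc.estimate_grid_angle(tc.radon_transform(edges, cfg.radon_angle_step_deg))
    assert circular_angle_error(est, angle) <= 1.0


# --- derotation ------------------------------------------------------------


def test_derotate_zero_is_identity():
    mask = square_ring(30, 12.0)
    np.testing.assert_array_equal(tc.derotate(mask, 0.0), mask)


@pytest.mark.parametrize("angle", [10.0, 30.0, 45.0])
def test_derotate_roundtrip_preserves_mask(angle):
    mask = rotated_square_mask((120, 120), (60.0, 60.0), 30, 0.0)
    rotated = tc.derotate(mask, -angle, (60.0, 60.0))
    back = tc.derotate(rotated, angle, (60.0, 60.0))
    jaccard = (back & mask).sum() / (back | mask).sum()
    assert jaccard >= 0.95
    assert abs(int(back.sum()) - int(mask.sum())) <= 0.05 * mask.sum()


def test_derotate_aligns_rotated_square_with_axes():
    m17 = rotated_square_mask((100, 100), (50.0, 50.0), 30, 17.0)
    m0 = rotated_square_mask((100, 100), (50.0, 50.0), 30, 0.0)
    aligned = tc.derotate(m17, 17.0, (50.0, 50.0))
    jaccard = (aligned & m0).sum() / (aligned | m0).sum()
    assert jaccard >= 0.9


def test_rotate_points_inverts():
    pts = np.array([[10.0, 20.0], [55.5, 42.0]])
    there = tc.rotate_points(pts, 33.0, (30.0, 30.0))
    back = tc.rotate_points(there, -33.0, (30.0, 30.0))
    np.testing.assert_allclose(back, pts, atol=1e-9)


# --- constant-component removal -------------------------------------------


def test_detrend_constant_image_is_zero_over_roi():
    roi = RoiMask(mask=rotated_square_mask((80, 80), (40, 40), 30, 0.0))
    out = tc.remove_constant_component(np.full((80, 80), 35.0), roi)
    assert np.allclose(out[roi.mask], 0.0, atol=1e-9)


def test_detrend_is_invariant_to_global_offset():
    scene = make_grid_scene(noise_sd_c=0.0)
    img, _ = tc.generate_scene(scene)
    roi, stack = tc.extract_roi(img, config_for(scene))
    out1 = tc.remove_constant_component(stack.l_med, roi)
    out2 = tc.remove_constant_component(stack.l_med + 5.0, roi)
    np.testing.assert_allclose(out1, out2, atol=1e-9)
    assert abs(out1[roi.mask].mean()) <= 0.1


def test_detrend_preserves_relative_peak_heights():
    scene = make_grid_scene(noise_sd_c=0.0)
    img, _ = tc.generate_scene(scene)
    # smooth linear trend across the frame, well below the pulse elevation
    rows = np.arange(240)[:, None] / 240.0
    tilted = tc.ThermalImage(values=img.values + 0.5 * rows)
    roi, stack = tc.extract_roi(img, config_for(scene))
    det_flat = tc.remove_constant_component(img.values, roi)
    det_tilt = tc.remove_constant_component(tilted.values, roi)
    peaks_flat = [det_flat[int(r), int(c)] for r, c, *_ in scene.pulses]
    peaks_tilt = [det_tilt[int(r), int(c)] for r, c, *_ in scene.pulses]
    rel_flat = np.array(peaks_flat) - np.mean(peaks_flat)
    rel_tilt = np.array(peaks_tilt) - np.mean(peaks_tilt)
    assert np.max(np.abs(rel_flat - rel_tilt)) <= 0.05 * 2.5


# --- watershed segmentation ------------------------------------------------


def test_watershed_separates_two_plateaus():
    values = np.full((40, 60), 0.0)
    values[10:30, 8:24] = 1.0
    values[10:30, 36:52] = 1.0
    roi = RoiMask(mask=np.pad(np.ones((24, 50), bool), ((8, 8), (5, 5))))
    labels = tc.watershed_pulses(values, roi, h_maxima_c=0.3)
    assert labels.max() == 2


def test_watershed_partition_equals_roi(plain_scene):
    scene, img, truth = plain_scene
    cfg = config_for(scene)
    roi, stack = tc.extract_roi(img, cfg)
    det = tc.remove_constant_component(stack.l_med, roi)
    labels = tc.watershed_pulses(det, roi, cfg.h_maxima_c)
    assert 11 <= labels.max() <= 13  # 12-pulse grid, +/- 1
    np.testing.assert_array_equal(labels > 0, roi.mask)


def test_watershed_without_maxima_raises():
    roi = RoiMask(mask=rotated_square_mask((40, 40), (20, 20), 16, 0.0))
    flat = np.zeros((40, 40))
    flat[roi.mask] = -np.arange(roi.n_pixels) * 0  # exactly flat
    with pytest.raises(NoPulsesError):
        tc.watershed_pulses(flat, roi, h_maxima_c=0.3)


# --- square fitting --------------------------------------------------------


def test_fit_single_square_label_recovers_geometry():
    labels = rotated_square_mask((60, 60), (30.0, 30.0), 20, 0.0).astype(int)
    [pulse] = tc.fit_squares(labels, 0.0)
    assert pulse.side_px == pytest.approx(20.0, abs=1.0)
    assert pulse.center[0] == pytest.approx(29.5, abs=0.51)
    assert pulse.center[1] == pytest.approx(29.5, abs=0.51)


def test_fit_discards_speck_regions():
    labels = np.zeros((200, 260), int)
    k = 1
    for i in range(3):
        for j in range(4):
            labels[rotated_square_mask(labels.shape, (40.0 + 50 * i, 40.0 + 60 * j), 30, 0.0)] = k
            k += 1
    labels[5, 5:8] = k  # 3-px speck
    with pytest.warns(UserWarning, match="discarded 1"):
        pulses = tc.fit_squares(labels, 0.0)
    assert len(pulses) == 12


def test_fit_centroids_match_ground_truth(dropout_scene):
    scene, img, truth = dropout_scene
    _, _, _, pulses = tc.detect_pulses(img, config_for(scene))
    assert len(pulses) == len(scene.pulses)
    found = np.array([p.center for p in pulses])
    true_centers = np.array([(p[0], p[1]) for p in scene.pulses])
    dists = np.linalg.norm(found[:, None, :] - true_centers[None, :, :], axis=2)
    assert dists.min(axis=1).mean() <= 2.0


def test_fit_requires_labels():
    with pytest.raises(NoPulsesError):
        tc.fit_squares(np.zeros((10, 10), int), 0.0)


# --- end-to-end equivariance ----------------------------------------------


def test_recovered_centers_rotate_with_the_scene():
    beta = 10.0
    scene0 = make_grid_scene(angle_deg=0.0, noise_sd_c=0.0)
    scene1 = make_grid_scene(angle_deg=beta, noise_sd_c=0.0)
    img0, _ = tc.generate_scene(scene0)
    img1, _ = tc.generate_scene(scene1)
    _, _, _, pulses0 = tc.detect_pulses(img0, config_for(scene0))
    _, _, _, pulses1 = tc.detect_pulses(img1, config_for(scene1))
    c0 = np.array([p.center for p in pulses0])
    c1 = np.array([p.center for p in pulses1])
    center = ((scene0.shape[0] - 1) / 2.0, (scene0.shape[1] - 1) / 2.0)
    mapped = tc.rotate_points(c0, beta, center)
    # match rotated centres to their nearest recovered counterpart
    dists = np.linalg.norm(mapped[:, None, :] - c1[None, :, :], axis=2)
    assert dists.min(axis=1).max() <= 2.0
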