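import pytest

import thermocover as tc

FRAME = (240, 320)
SIDE = 34.0
GAP = 2.0


def make_grid_scene(**kwargs):
    """Standard 3x4 pulse grid in a 240x320 frame used across the suite."""
    defaults = dict(
        n_rows=3,
        n_cols=4,
        side_px=SIDE,
        gap_px=GAP,
        angle_deg=8.0,
        shape=FRAME,
        noise_sd_c=0.0,
        seed=0,
    )
    defaults.update(kwargs)
    return tc.grid_scene(**defaults)


def config_for(scene, gap_px=GAP, **overrides):
    side = scene.pulses[0][2] if scene.pulses else SIDE
    return tc.RunConfig.for_pulse_side(side, gap_px, shape=scene.shape, **overrides)


@pytest.fixture
def dropout_scene():
    """Noiseless grid with two interior/edge pulses omitted (known delta_o)."""
    scene = make_grid_scene(dropout=((1, 1), (1, 2)))
    img, truth = tc.generate_scene(scene)
    return scene, img, truth


@pytest.fixture
def overlap_scene():
    """Noiseless grid with two pulses shifted into their neighbours."""
    shifts = {(0, 1): (6.0, 0.0), (2, 2): (-6.0, 0.0)}
    scene = make_grid_scene(shifts=shifts)
    img, truth = tc.generate_scene(scene)
    return scene, img, truth


@pytest.fixture
def plain_scene():
    """Noiseless complete grid."""
    scene = make_grid_scene()
    img, truth = tc.generate_scene(scene)
    return scene, img, truth


def circular_angle_error(est, true):
    """Angular distance modulo the 90-degree symmetry of a square grid."""
    d = abs(est - true % 90.0) % 90.0
    return min(d, 90.0 - d)
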