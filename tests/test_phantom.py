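"""Phantom generator: determinism, analytic truth, cross-module consistency."""

import math

import numpy as np
import pytest

import atriu
from atriu.frame_detection import ValveStateSequence, select_es_frame
from atriu.phantom import ANNULAR_OFFSET_FRACTION


def test_sphere_truth_volume_is_analytic():
    spec = atriu.PhantomSpec(ellipsoid_semi_axes_mm=(20.0, 20.0, 20.0))
    assert atriu.generate_study(spec).truth_volume_ml == pytest.approx(33.5103, abs=1e-3)


def test_ellipsoid_truth_volume_is_analytic():
    spec = atriu.PhantomSpec(ellipsoid_semi_axes_mm=(15.0, 20.0, 30.0))
    assert atriu.generate_study(spec).truth_volume_ml == pytest.approx(37.699, abs=1e-3)


def test_same_seed_is_bit_identical_different_seed_differs():
    a = atriu.generate_study(atriu.PhantomSpec(seed=1))
    b = atriu.generate_study(atriu.PhantomSpec(seed=1))
    c = atriu.generate_study(atriu.PhantomSpec(seed=2))
    assert np.array_equal(a.cine_2ch.frames, b.cine_2ch.frames)
    assert np.array_equal(a.cine_4ch.frames, b.cine_4ch.frames)
    assert not np.array_equal(a.cine_2ch.frames, c.cine_2ch.frames)


@pytest.mark.parametrize(
    "kwargs, match",
    [
        (dict(ellipsoid_semi_axes_mm=(0.0, 20.0, 30.0)), "semi_axes"),
        (dict(volume_amplitude=1.0), "volume_amplitude"),
        (dict(es_frame_index=25), "es_frame_index"),
        (dict(image_size=32), "margin"),
        (dict(noise_sd=-0.1), "noise_sd"),
    ],
)
def test_invalid_spec_rejected_naming_field(kwargs, match):
    with pytest.raises(ValueError, match=match):
        atriu.PhantomSpec(**kwargs)


def test_es_rule_applied_to_truth_states_recovers_truth_index():
    """Cross-module consistency: the frame-detection selection rule applied to
    the truth valve states yields the ground-truth ES index."""
    for spec in atriu.sample_specs(10, seed=42):
        study = atriu.generate_study(spec)
        states = ValveStateSequence.from_labels(study.truth_valve_states)
        assert select_es_frame(states) == study.truth_es_index


def test_valve_rendered_closed_exactly_on_closed_frames():
    """The bright chord spans the gap region only on frames labeled closed."""
    spec = atriu.PhantomSpec(noise_sd=0.0)
    study = atriu.generate_study(spec)
    size = spec.image_size
    for t, closed in enumerate(study.truth_valve_states):
        frame = study.cine_4ch.frames[t]
        center_col = size // 2
        has_center_valve = (frame[:, center_col] == 1.0).any()
        assert has_center_valve == bool(closed)


def test_atrial_area_is_maximal_at_es():
    study = atriu.generate_study(atriu.PhantomSpec())
    areas = [m.n_pixels for m in study.truth_masks["2ch"]]
    # rasterization can tie neighbouring frames; the ES frame attains the max
    assert areas[study.truth_es_index] == max(areas)


def test_raster_area_matches_analytic_ellipse_under_2pct():
    spec = atriu.PhantomSpec(pixel_spacing_mm=1.0, ellipsoid_semi_axes_mm=(20.0, 24.0, 32.0))
    study = atriu.generate_study(spec)
    for view, horiz in (("2ch", 20.0), ("4ch", 24.0)):
        area = atriu.mask_area(study.truth_masks[view][study.truth_es_index])
        analytic = math.pi * horiz * 32.0
        assert abs(area - analytic) / analytic < 0.02


def test_landmarks_lie_on_the_ellipse_boundary_chord():
    spec = atriu.PhantomSpec(noise_sd=0.0)
    study = atriu.generate_study(spec)
    lm = study.truth_landmarks["2ch"][study.truth_es_index]
    a, _, c = spec.ellipsoid_semi_axes_mm
    p = spec.pixel_spacing_mm
    r0 = c0 = spec.image_size // 2
    # on-ellipse check in continuous coordinates
    for pt in (lm.p_left, lm.p_right):
        x = (pt[1] - c0) / (a / p)
        y = (pt[0] - r0) / (c / p)
        assert x * x + y * y == pytest.approx(1.0, abs=1e-9)
    assert lm.p_left[0] == pytest.approx(r0 + ANNULAR_OFFSET_FRACTION * c / p)


def test_3d_stack_slice_sum_converges_to_analytic_volume():
    spec = atriu.PhantomSpec(
        ellipsoid_semi_axes_mm=(20.0, 20.0, 20.0), pixel_spacing_mm=0.8, noise_sd=0.0
    )
    study = atriu.generate_3d_stack(spec, 200, 0.2)
    v = atriu.volume_3d([atriu.mask_area(m) for m in study.truth_stack_masks], 0.2)
    assert v == pytest.approx(33.51, rel=0.01)


def test_3d_stack_preconditions():
    spec = atriu.PhantomSpec(ellipsoid_semi_axes_mm=(20.0, 20.0, 20.0))
    with pytest.raises(ValueError, match="at least 3 slices"):
        atriu.generate_3d_stack(spec, 1, 50.0)
    with pytest.raises(ValueError, match="cover"):
        atriu.generate_3d_stack(spec, 4, 2.0)  # extent 8 mm << 40 mm
    with pytest.raises(ValueError, match="margin"):
        # ellipsoid larger than the field of view
        atriu.PhantomSpec(ellipsoid_semi_axes_mm=(80.0, 80.0, 80.0))


def test_tilted_views_change_inplane_width():
    flat = atriu.generate_study(atriu.PhantomSpec(noise_sd=0.0))
    tilt = atriu.generate_study(atriu.PhantomSpec(noise_sd=0.0, view_tilt_deg=20.0))
    es = flat.truth_es_index
    # a < b by default, so tilting widens the 2ch section toward b
    assert tilt.truth_masks["2ch"][es].n_pixels > flat.truth_masks["2ch"][es].n_pixels


def test_study_roundtrip_through_disk(tmp_path):
    study = atriu.generate_study(atriu.PhantomSpec(seed=5))
    atriu.phantom.write_study(study, tmp_path / "s0")
    back = atriu.phantom.read_study(tmp_path / "s0")
    assert back.truth_es_index == study.truth_es_index
    assert back.truth_volume_ml == pytest.approx(study.truth_volume_ml)
    assert np.allclose(back.cine_2ch.frames, study.cine_2ch.frames, atol=1e-6)
    assert np.array_equal(
        back.truth_masks["4ch"][0].pixels, study.truth_masks["4ch"][0].pixels
    )
    assert back.truth_landmarks["2ch"][3].p_left == pytest.approx(
        study.truth_landmarks["2ch"][3].p_left
    )
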