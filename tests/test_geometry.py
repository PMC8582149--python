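"""Areas, centroids, longitudinal diameters and the biplane volume."""

import math

import numpy as np
import pytest

import atriu
from atriu.geometry import (
    biplane_volume,
    bsa_m2,
    construct_diameter_centroid,
    construct_diameter_perpendicular,
    index_volume,
    mask_area,
    mask_centroid,
    volume_3d,
)
from atriu.landmarks import LandmarkPair
from atriu.segmentation import MaskImage

DISK_LANDMARKS = LandmarkPair((70.0, 30.0), (70.0, 70.0))


def test_mask_area_scales_with_spacing():
    ones = np.ones((10, 10), dtype=bool)
    assert mask_area(MaskImage(ones, (1.0, 1.0))) == pytest.approx(100.0)
    assert mask_area(MaskImage(ones, (2.0, 2.0))) == pytest.approx(400.0)
    rng = np.random.default_rng(1)
    rand = rng.random((20, 20)) > 0.5
    assert mask_area(MaskImage(rand, (1.5, 0.5))) == pytest.approx(
        int(rand.sum()) * 0.75
    )


def test_mask_centroid_cases():
    px = np.zeros((10, 11), dtype=bool)
    px[5, 5] = True
    assert mask_centroid(MaskImage(px, (1, 1))) == (5.0, 5.0)
    px = np.zeros((3, 12), dtype=bool)
    px[0, 0] = px[0, 10] = True
    assert mask_centroid(MaskImage(px, (1, 1))) == (0.0, 5.0)
    with pytest.raises(ValueError, match="empty"):
        mask_centroid(MaskImage(np.zeros((4, 4)), (1, 1)))


def test_disk_centroid_diameter_length(disk_mask):
    """Rasterized-circle oracle: the disk's continuous support reaches half a
    pixel beyond the boundary pixel centers, so the ray from the annular
    midpoint (70, 50) through the centroid (50, 50) exits at row 29.5:
    length 40.5 mm at 1 mm spacing."""
    d = construct_diameter_centroid(disk_mask, DISK_LANDMARKS)
    assert d.length_mm == pytest.approx(40.5, abs=0.1)
    assert mask_centroid(disk_mask) == pytest.approx((50.0, 50.0))
    assert d.annular_midpoint == pytest.approx((70.0, 50.0))
    assert d.direction == pytest.approx((-1.0, 0.0))


def test_disk_diameter_scales_with_spacing(disk_mask):
    coarse = MaskImage(disk_mask.pixels, (2.0, 2.0))
    d = construct_diameter_centroid(coarse, DISK_LANDMARKS)
    assert d.length_mm == pytest.approx(81.0, abs=0.2)


def test_disk_perpendicular_matches_centroid_variant(disk_mask):
    """Both variants pass through the disk center by symmetry."""
    dc = construct_diameter_centroid(disk_mask, DISK_LANDMARKS)
    dp = construct_diameter_perpendicular(disk_mask, DISK_LANDMARKS)
    assert dp.length_mm == pytest.approx(dc.length_mm, rel=0.01)
    assert dp.variant == "perpendicular"


def test_degenerate_direction_rejected(disk_mask):
    center_landmarks = LandmarkPair((50.0, 30.0), (50.0, 70.0))  # midpoint == centroid
    with pytest.raises(ValueError, match="degenerate"):
        construct_diameter_centroid(disk_mask, center_landmarks)


def test_empty_mask_rejected():
    empty = MaskImage(np.zeros((10, 10)), (1, 1))
    with pytest.raises(ValueError, match="empty"):
        construct_diameter_centroid(empty, DISK_LANDMARKS)
    with pytest.raises(ValueError, match="empty"):
        construct_diameter_perpendicular(empty, DISK_LANDMARKS)


def test_ray_missing_mask_rejected():
    px = np.zeros((20, 20), dtype=bool)
    px[0, 0] = px[0, 10] = True  # centroid (0, 5) lies outside the mask
    mask = MaskImage(px, (1, 1))
    lm = LandmarkPair((10.0, 4.0), (10.0, 6.0))
    with pytest.raises(ValueError, match="never enters"):
        construct_diameter_centroid(mask, lm)


def test_biplane_volume_formula_and_errors():
    assert biplane_volume(0.0, 0.0, 10.0) == 0.0
    with pytest.raises(ValueError, match="positive"):
        biplane_volume(100.0, 100.0, 0.0)
    with pytest.raises(ValueError, match="non-negative"):
        biplane_volume(-1.0, 100.0, 10.0)


def test_biplane_exact_for_sphere():
    area = math.pi * 20.0**2
    assert biplane_volume(area, area, 40.0) == pytest.approx(
        4.0 / 3.0 * math.pi * 20.0**3 / 1000.0, rel=1e-9
    )


def test_biplane_exact_for_coaxial_ellipsoid():
    a2 = math.pi * 15.0 * 30.0
    a4 = math.pi * 20.0 * 30.0
    assert biplane_volume(a2, a4, 60.0) == pytest.approx(37.699, abs=1e-3)


def test_lmin_selection_invariant_to_view_permutation():
    a2, a4 = 1200.0, 1500.0
    l2, l4 = 55.0, 48.0
    assert biplane_volume(a2, a4, min(l2, l4)) == biplane_volume(
        a4, a2, min(l4, l2)
    )


def test_volume_3d_sum_and_errors():
    assert volume_3d([1000.0] * 5, 8.0) == pytest.approx(40.0)
    assert volume_3d([0.0, 0.0], 5.0) == 0.0
    with pytest.raises(ValueError, match="non-negative"):
        volume_3d([-1.0], 1.0)
    with pytest.raises(ValueError, match="thickness"):
        volume_3d([10.0], 0.0)


def test_bsa_mosteller_and_indexing():
    assert bsa_m2(170.0, 70.0) == pytest.approx(1.8181, abs=1e-4)
    assert index_volume(60.0, 2.0) == pytest.approx(30.0)
    assert index_volume(0.0, 1.7) == 0.0
    with pytest.raises(ValueError):
        bsa_m2(0.0, 70.0)
    with pytest.raises(ValueError):
        index_volume(10.0, 0.0)


def test_scale_covariance_of_areas_diameters_volume(disk_mask):
    """Uniform spacing scale s multiplies areas by s², lengths by s, volume by s³."""
    s = 1.7
    scaled = MaskImage(disk_mask.pixels, (s, s))
    a1 = mask_area(disk_mask)
    a2 = mask_area(scaled)
    assert a2 == pytest.approx(a1 * s**2)
    l1 = construct_diameter_centroid(disk_mask, DISK_LANDMARKS).length_mm
    l2 = construct_diameter_centroid(scaled, DISK_LANDMARKS).length_mm
    # equal up to the 0.01-px bisection tolerance at either scale
    assert l2 == pytest.approx(l1 * s, abs=0.05)
    v1 = biplane_volume(a1, a1, l1)
    v2 = biplane_volume(a2, a2, l2)
    assert v2 == pytest.approx(v1 * s**3, rel=1e-3)


def test_oracle_masks_end_to_end_volume_within_3pct():
    """With ground-truth masks and landmarks on zero-tilt phantoms, the full
    area-length chain recovers the analytic ellipsoid volume to within 3%."""
    study = atriu.generate_study(atriu.PhantomSpec(noise_sd=0.0))
    es = study.truth_es_index
    res = atriu.compute_volume_result(
        study.truth_masks["2ch"][es],
        study.truth_masks["4ch"][es],
        study.truth_landmarks["2ch"][es],
        study.truth_landmarks["4ch"][es],
    )
    err = abs(res.lav_max_ml - study.truth_volume_ml) / study.truth_volume_ml
    assert err < 0.03
    assert res.l_min_mm == min(res.diameter_2ch.length_mm, res.diameter_4ch.length_mm)
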