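"""Segmentation: overlap metrics vs brute-force oracles, post-processing,
and the trained per-pixel segmenter on phantoms."""

import numpy as np
import pytest

import atriu
from atriu.segmentation import (
    SegModelConfig,
    dice,
    hausdorff_max,
    postprocess_mask,
    segment_la,
    segment_stack,
    train_segmenter,
)


def mask_of(pixels, spacing=(1.0, 1.0)):
    return atriu.MaskImage(np.asarray(pixels, dtype=bool), spacing)


def brute_force_dice(a, b):
    inter = sum(
        1
        for r in range(a.shape[0])
        for c in range(a.shape[1])
        if a[r, c] and b[r, c]
    )
    na, nb = int(a.sum()), int(b.sum())
    return 1.0 if na + nb == 0 else 2 * inter / (na + nb)


def brute_force_hausdorff(a, b, spacing):
    """Exhaustive pairwise max-min distance over 8-connected inner boundaries."""

    def boundary(m):
        pts = []
        for r in range(m.shape[0]):
            for c in range(m.shape[1]):
                if not m[r, c]:
                    continue
                nbrs = [
                    m[rr, cc] if 0 <= rr < m.shape[0] and 0 <= cc < m.shape[1] else False
                    for rr in (r - 1, r, r + 1)
                    for cc in (c - 1, c, c + 1)
                ]
                if not all(nbrs):
                    pts.append((r * spacing[0], c * spacing[1]))
        return pts

    pa, pb = boundary(a), boundary(b)

    def directed(ps, qs):
        return max(min(np.hypot(p[0] - q[0], p[1] - q[1]) for q in qs) for p in ps)

    return max(directed(pa, pb), directed(pb, pa))


def test_dice_identical_disjoint_and_half_overlap():
    a = np.zeros((20, 20), bool)
    a[0:10, 0:10] = True  # 100 px
    b = np.zeros((20, 20), bool)
    b[5:15, 0:10] = True  # 100 px, 50 px overlap
    assert dice(mask_of(a), mask_of(a)) == 1.0
    assert dice(mask_of(a), mask_of(~a)) == 0.0
    assert dice(mask_of(a), mask_of(b)) == pytest.approx(0.5)
    assert dice(mask_of(np.zeros((4, 4))), mask_of(np.zeros((4, 4)))) == 1.0


def test_dice_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape"):
        dice(mask_of(np.zeros((4, 4))), mask_of(np.zeros((5, 5))))


def test_hausdorff_simple_cases():
    a = np.zeros((10, 10), bool)
    a[2, 2] = True
    b = np.zeros((10, 10), bool)
    b[2, 5] = True
    assert hausdorff_max(mask_of(a), mask_of(a)) == 0.0
    assert hausdorff_max(mask_of(a), mask_of(b)) == pytest.approx(3.0)
    with pytest.raises(ValueError, match="empty"):
        hausdorff_max(mask_of(a), mask_of(np.zeros((10, 10))))


def test_hausdorff_shifted_square_matches_brute_force():
    a = np.zeros((30, 30), bool)
    a[5:15, 5:15] = True
    b = np.zeros((30, 30), bool)
    b[9:19, 5:15] = True  # shifted 4 px along rows
    expected = brute_force_hausdorff(a, b, (2.0, 2.0))
    got = hausdorff_max(mask_of(a, (2.0, 2.0)), mask_of(b, (2.0, 2.0)))
    assert got == pytest.approx(expected)


def test_metrics_match_brute_force_on_random_masks():
    rng = np.random.default_rng(11)
    for _ in range(25):
        a = rng.random((12, 12)) > 0.6
        b = rng.random((12, 12)) > 0.6
        ma, mb = mask_of(a), mask_of(b)
        assert dice(ma, mb) == pytest.approx(brute_force_dice(a, b))
        assert dice(ma, mb) == pytest.approx(dice(mb, ma))
        assert 0.0 <= dice(ma, mb) <= 1.0
        if a.any() and b.any():
            expected = brute_force_hausdorff(a, b, (1.0, 1.0))
            assert hausdorff_max(ma, mb) == pytest.approx(expected)
            assert hausdorff_max(mb, ma) == pytest.approx(expected)


def test_hausdorff_scales_with_anisotropic_spacing():
    a = np.zeros((10, 10), bool)
    a[2, 2] = True
    b = np.zeros((10, 10), bool)
    b[5, 2] = True  # 3 rows apart
    c = np.zeros((10, 10), bool)
    c[2, 5] = True  # 3 cols apart
    assert hausdorff_max(mask_of(a, (2.0, 3.0)), mask_of(b, (2.0, 3.0))) == pytest.approx(6.0)
    assert hausdorff_max(mask_of(a, (2.0, 3.0)), mask_of(c, (2.0, 3.0))) == pytest.approx(9.0)


def test_postprocess_keeps_largest_component_fills_holes_idempotent():
    px = np.zeros((30, 30), bool)
    px[2:12, 2:12] = True  # 100 px blob with a hole
    px[5:8, 5:8] = False
    px[20:22, 20:24] = True  # 8 px blob
    out = postprocess_mask(mask_of(px))
    assert out.n_pixels == 100  # hole filled, small blob dropped
    assert not out.pixels[20, 20]
    again = postprocess_mask(out)
    assert np.array_equal(again.pixels, out.pixels)
    empty = postprocess_mask(mask_of(np.zeros((5, 5))))
    assert empty.n_pixels == 0


def test_postprocess_never_increases_beyond_filled_component(heldout_studies):
    study = heldout_studies[0]
    m = study.truth_masks["2ch"][0]
    assert postprocess_mask(m).n_pixels == m.n_pixels  # convex truth: unchanged


def test_config_rejects_nonpositive_hyperparameters():
    with pytest.raises(ValueError, match="epochs"):
        SegModelConfig(epochs=0)
    with pytest.raises(ValueError, match="empty"):
        train_segmenter([], SegModelConfig())


def test_segment_la_on_phantom_es_frames(trained_models, heldout_studies):
    """Held-out Dice on ES frames of noisy phantoms; spacing passthrough."""
    dices = []
    for study in heldout_studies[:10]:
        es = study.truth_es_index
        for view in ("2ch", "4ch"):
            frame = getattr(study, f"cine_{view}").frames[es]
            spacing = (study.spec.pixel_spacing_mm,) * 2
            m = segment_la(frame, trained_models.segmenter, spacing)
            assert m.pixel_spacing_mm == spacing
            dices.append(dice(m, study.truth_masks[view][es]))
    assert np.median(dices) >= 0.95
    assert min(dices) >= 0.90


def test_segment_la_memorizes_training_study(trained_models, train_studies):
    study = train_studies[0]
    es = study.truth_es_index
    frame = study.cine_2ch.frames[es]
    m = segment_la(frame, trained_models.segmenter, (study.spec.pixel_spacing_mm,) * 2)
    assert dice(m, study.truth_masks["2ch"][es]) >= 0.98


def test_segment_la_flags_empty_prediction(trained_models):
    rng = np.random.default_rng(3)
    frame = rng.normal(0.0, 1.0, (96, 96))  # pure noise, no anatomy
    m = segment_la(frame, trained_models.segmenter, (1.0, 1.0))
    assert isinstance(m, atriu.MaskImage)
    if m.n_pixels == 0:
        assert m.flagged


def test_segment_stack_requires_three_slices(trained_models):
    stack = atriu.CineSequence(np.zeros((2, 16, 16)), (1.0, 1.0), "axial")
    with pytest.raises(ValueError, match="3 slices"):
        segment_stack(stack, trained_models.segmenter)


@pytest.fixture(scope="module")
def stack_model():
    specs = atriu.sample_specs(4, seed=50)
    stacks = [atriu.generate_3d_stack(s, 16, 2 * s.ellipsoid_semi_axes_mm[2] / 15) for s in specs]
    cfg = SegModelConfig(seed=7, context_3d=True, samples_per_frame=800)
    return train_segmenter(stacks, cfg)


def test_segment_stack_with_3d_context(stack_model):
    spec = atriu.sample_specs(1, seed=99)[0]
    held = atriu.generate_3d_stack(spec, 16, 2 * spec.ellipsoid_semi_axes_mm[2] / 15)
    masks = segment_stack(held.stack_3d, stack_model)
    assert len(masks) == 16
    scores = [
        dice(m, t)
        for m, t in zip(masks, held.truth_stack_masks)
        if t.n_pixels or m.n_pixels
    ]
    assert np.median(scores) >= 0.9
    # slices beyond the atrium may legitimately be empty
    assert all(isinstance(m, atriu.MaskImage) for m in masks)
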