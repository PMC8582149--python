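"""Left-atrial segmentation on long-axis frames plus overlap metrics.

The segmenter is a per-pixel classifier (random forest on multiscale
intensity/edge/texture features plus normalized image coordinates), the
ilastik-style trainable-segmentation approach.  A ``context_3d`` variant adds
the mean of the neighbouring slices as an extra feature channel so axial
stacks can be segmented slice-wise with through-plane context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import binary_erosion, binary_fill_holes
from scipy.spatial.distance import cdist
from skimage.measure import label as cc_label
from sklearn.ensemble import RandomForestClassifier

from ._features import pixel_feature_stack

__all__ = [
    "MaskImage",
    "SegModelConfig",
    "SegmentationModel",
    "train_segmenter",
    "segment_la",
    "segment_stack",
    "postprocess_mask",
    "dice",
    "hausdorff_max",
]


@dataclass
class MaskImage:
    """Binary left-atrial region on one frame, with physical pixel spacing."""

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    flagged: bool = False  # True when the prediction needs human review

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask pixels must be a 2-D array")
        sr, sc = self.pixel_spacing_mm
        if not (sr > 0 and sc > 0):
            raise ValueError("pixel_spacing_mm must be positive")
        self.pixel_spacing_mm = (float(sr), float(sc))

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


@dataclass
class SegModelConfig:
    """Desk-scale segmenter hyperparameters.

    sigma_min/sigma_max bound the multiscale feature pyramid (pixels);
    n_trees/max_depth size the per-pixel forest; samples_per_frame bounds the
    number of training pixels drawn per frame; frames_per_study limits how
    many frames of each cine contribute training pixels.
    """

    sigma_min: float = 0.5
    sigma_max: float = 4.0
    n_trees: int = 30
    max_depth: int | None = 14
    epochs: int = 1
    learning_rate: float = 1.0
    samples_per_frame: int = 2500
    frames_per_study: int = 3
    context_3d: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_min", "sigma_max", "n_trees", "epochs",
                     "learning_rate", "samples_per_frame", "frames_per_study"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class SegmentationModel:
    """Trained per-pixel atrium classifier; returned by :func:`train_segmenter`."""

    def __init__(self, forest: RandomForestClassifier, config: SegModelConfig):
        self.forest = forest
        self.config = config

    def probability_map(self, frame: np.ndarray,
                        context: np.ndarray | None = None) -> np.ndarray:
        frame = np.asarray(frame, dtype=float)
        extra = ()
        if self.config.context_3d:
            ctx = frame if context is None else np.asarray(context, dtype=float)
            extra = (ctx,)
        feats = self._features(frame, extra)
        proba = self.forest.predict_proba(feats)[:, 1]
        return proba.reshape(frame.shape)

    def _features(self, frame: np.ndarray,
                  extra: tuple[np.ndarray, ...]) -> np.ndarray:
        return pixel_feature_stack(
            frame,
            sigma_min=self.config.sigma_min,
            sigma_max=self.config.sigma_max,
            extra_channels=extra,
        )


def _training_frames(study, n_frames_used: int):
    """Yield (frame, truth mask pixels, context) triples from one phantom study."""
    for view in ("2ch", "4ch"):
        cine = getattr(study, f"cine_{view}")
        masks = study.truth_masks[view]
        n = len(cine.frames)
        # ES frame first, then frames spread across the cycle
        order = [study.truth_es_index] + [
            int(round(i * (n - 1) / max(1, n_frames_used - 1)))
            for i in range(n_frames_used)
        ]
        seen: list[int] = []
        for idx in order:
            if idx not in seen:
                seen.append(idx)
            if len(seen) >= n_frames_used:
                break
        for idx in seen:
            yield cine.frames[idx], masks[idx].pixels, None


def _stack_training_frames(study):
    cine = study.stack_3d
    masks = study.truth_stack_masks
    n = len(cine.frames)
    for i in range(n):
        ctx = _neighbour_mean(cine.frames, i)
        yield cine.frames[i], masks[i].pixels, ctx


def _neighbour_mean(frames: Sequence[np.ndarray], i: int) -> np.ndarray:
    lo, hi = max(0, i - 1), min(len(frames) - 1, i + 1)
    return (np.asarray(frames[lo], float) + np.asarray(frames[hi], float)) / 2.0


def train_segmenter(studies: Iterable, config: SegModelConfig | None = None) -> SegmentationModel:
    """Train the per-pixel atrium classifier on labeled phantom studies.

    With ``config.context_3d`` the training pixels are drawn from the studies'
    axial stacks (which must be present) instead of the long-axis cines.
    Deterministic given ``config.seed``.
    """
    config = config or SegModelConfig()
    studies = list(studies)
    if not studies:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    xs, ys = [], []
    for study in studies:
        if config.context_3d:
            if getattr(study, "stack_3d", None) is None:
                raise ValueError("context_3d training requires studies with a 3-D stack")
            frame_iter = _stack_training_frames(study)
        else:
            if not getattr(study, "truth_masks", None):
                raise ValueError("training studies must carry truth masks")
            frame_iter = _training_frames(study, config.frames_per_study)
        for frame, mask, ctx in frame_iter:
            extra = (ctx if ctx is not None else frame,) if config.context_3d else ()
            feats = pixel_feature_stack(
                frame, config.sigma_min, config.sigma_max, extra_channels=extra
            )
            labels = np.asarray(mask, bool).ravel()
            take = _stratified_sample(labels, config.samples_per_frame, rng)
            xs.append(feats[take])
            ys.append(labels[take])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(x, y)
    return SegmentationModel(forest, config)


def _stratified_sample(labels: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample pixel indices with both classes represented when available."""
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    n_pos = min(len(pos), n // 2) if len(pos) else 0
    n_neg = min(len(neg), n - n_pos)
    parts = []
    if n_pos:
        parts.append(rng.choice(pos, size=n_pos, replace=False))
    if n_neg:
        parts.append(rng.choice(neg, size=n_neg, replace=False))
    return np.sort(np.concatenate(parts))


def segment_la(
    frame: np.ndarray,
    model: SegmentationModel,
    pixel_spacing_mm: tuple[float, float],
    context: np.ndarray | None = None,
) -> MaskImage:
    """Segment the left atrium on one frame.

    The probability map is thresholded at 0.5 and post-processed
    (largest component, hole filling).  An empty prediction is returned as an
    empty mask with ``flagged=True`` so the pipeline can request correction.
    """
    proba = model.probability_map(frame, context=context)
    raw = MaskImage(proba >= 0.5, pixel_spacing_mm)
    mask = postprocess_mask(raw)
    if mask.n_pixels == 0:
        mask.flagged = True
    return mask


def segment_stack(stack, model: SegmentationModel) -> list[MaskImage]:
    """Slice-wise segmentation of an axial cine stack (>= 3 slices)."""
    frames = stack.frames
    if len(frames) < 3:
        raise ValueError("stack segmentation requires at least 3 slices")
    out = []
    for i, frame in enumerate(frames):
        ctx = _neighbour_mean(frames, i) if model.config.context_3d else None
        out.append(segment_la(frame, model, stack.pixel_spacing_mm, context=ctx))
    return out


def postprocess_mask(raw: MaskImage) -> MaskImage:
    """Keep the largest 4-connected component and fill enclosed holes.

    Idempotent; an empty mask maps to an empty mask.
    """
    px = raw.pixels
    if not px.any():
        return MaskImage(np.zeros_like(px), raw.pixel_spacing_mm, flagged=raw.flagged)
    lab = cc_label(px, connectivity=1)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    keep = lab == int(np.argmax(counts))
    filled = binary_fill_holes(keep)
    return MaskImage(filled, raw.pixel_spacing_mm, flagged=raw.flagged)


def dice(a: MaskImage, b: MaskImage) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    if a.pixels.shape != b.pixels.shape:
        raise ValueError("dice requires masks of identical shape")
    inter = int(np.logical_and(a.pixels, b.pixels).sum())
    total = a.n_pixels + b.n_pixels
    if total == 0:
        return 1.0
    return 2.0 * inter / total


def boundary_points_mm(mask: MaskImage) -> np.ndarray:
    """Inner-boundary pixel centers (8-connected definition) in mm coordinates."""
    px = mask.pixels
    # a mask pixel is inner-boundary when any 8-neighbour (or the image
    # border) is background
    inner = px & ~binary_erosion(px, structure=np.ones((3, 3), bool), border_value=0)
    coords = np.argwhere(inner).astype(float)
    coords[:, 0] *= mask.pixel_spacing_mm[0]
    coords[:, 1] *= mask.pixel_spacing_mm[1]
    return coords


def hausdorff_max(a: MaskImage, b: MaskImage) -> float:
    """Symmetric maximum Hausdorff distance between mask boundaries, in mm.

    Boundaries are the 8-connected inner-boundary pixel centers scaled by the
    pixel spacing.  Undefined (error) for empty masks.
    """
    if a.pixels.shape != b.pixels.shape:
        raise ValueError("hausdorff_max requires masks of identical shape")
    if a.pixel_spacing_mm != b.pixel_spacing_mm:
        raise ValueError("hausdorff_max requires identical pixel spacing")
    if a.n_pixels == 0 or b.n_pixels == 0:
        raise ValueError("hausdorff_max is undefined for empty masks")
    pa = boundary_points_mm(a)
    pb = boundary_points_mm(b)
    d = cdist(pa, pb)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))
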