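"""Mitral annular hinge-point localization and landmark comparison metrics.

The localizer regresses two Gaussian heatmaps (one per hinge point) with a
per-pixel random-forest regressor on multiscale appearance features plus
normalized image coordinates; the sub-pixel peak of each predicted heatmap is
extracted by a local center of mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from ._features import pixel_feature_stack
from .segmentation import SegModelConfig

__all__ = [
    "LandmarkPair",
    "LocalizerModel",
    "train_localizer",
    "localize_landmarks",
    "landmark_distance_sum",
    "annular_angle_deviation",
]


@dataclass
class LandmarkPair:
    """The two mitral annular hinge points on one long-axis view.

    Points are sub-pixel (row, col) coordinates, 0-based, pixel centers at
    integers.  Canonical ordering: ``p_left`` has the smaller column.
    """

    p_left: tuple[float, float]
    p_right: tuple[float, float]
    view_label: str = "4ch"

    def __post_init__(self) -> None:
        self.p_left = (float(self.p_left[0]), float(self.p_left[1]))
        self.p_right = (float(self.p_right[0]), float(self.p_right[1]))
        if self.p_left[1] > self.p_right[1]:
            self.p_left, self.p_right = self.p_right, self.p_left

    def validate_within(self, shape: tuple[int, int]) -> None:
        for p in (self.p_left, self.p_right):
            if not (0 <= p[0] <= shape[0] - 1 and 0 <= p[1] <= shape[1] - 1):
                raise ValueError(f"landmark {p} outside image bounds {shape}")

    def midpoint(self) -> tuple[float, float]:
        return (
            (self.p_left[0] + self.p_right[0]) / 2.0,
            (self.p_left[1] + self.p_right[1]) / 2.0,
        )


class LocalizerModel:
    """Trained two-heatmap hinge-point regressor."""

    def __init__(self, forest: RandomForestRegressor, config: SegModelConfig,
                 heatmap_sigma_px: float):
        self.forest = forest
        self.config = config
        self.heatmap_sigma_px = heatmap_sigma_px

    def heatmaps(self, frame: np.ndarray) -> np.ndarray:
        frame = np.asarray(frame, dtype=float)
        feats = pixel_feature_stack(frame, self.config.sigma_min, self.config.sigma_max)
        pred = self.forest.predict(feats)  # (n_pixels, 2)
        return pred.T.reshape((2,) + frame.shape)


def _gaussian_heatmap(shape: tuple[int, int], point: tuple[float, float],
                      sigma: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (rr - point[0]) ** 2 + (cc - point[1]) ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


def train_localizer(
    studies: Iterable,
    config: SegModelConfig | None = None,
    heatmap_sigma_px: float = 3.0,
) -> LocalizerModel:
    """Train the hinge-point heatmap regressor on labeled phantom ES frames.

    Training pixels are drawn densely near the annulus (where the target
    heatmaps are non-zero) and sparsely elsewhere.  Deterministic given
    ``config.seed``.
    """
    config = config or SegModelConfig()
    studies = list(studies)
    if not studies:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    xs, ys = [], []
    for study in studies:
        if not getattr(study, "truth_landmarks", None):
            raise ValueError("training studies must carry truth landmarks")
        es = study.truth_es_index
        for view in ("2ch", "4ch"):
            frame = getattr(study, f"cine_{view}").frames[es]
            lm = study.truth_landmarks[view][es]
            target = np.stack(
                [
                    _gaussian_heatmap(frame.shape, lm.p_left, heatmap_sigma_px),
                    _gaussian_heatmap(frame.shape, lm.p_right, heatmap_sigma_px),
                ]
            )
            feats = pixel_feature_stack(frame, config.sigma_min, config.sigma_max)
            flat = target.reshape(2, -1).T
            near = np.flatnonzero(flat.max(axis=1) > 0.01)
            far = np.flatnonzero(flat.max(axis=1) <= 0.01)
            n_far = min(len(far), config.samples_per_frame)
            take = np.sort(
                np.concatenate([near, rng.choice(far, size=n_far, replace=False)])
            )
            xs.append(feats[take])
            ys.append(flat[take])
    forest = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(np.concatenate(xs), np.concatenate(ys))
    return LocalizerModel(forest, config, heatmap_sigma_px)


def _subpixel_peak(heatmap: np.ndarray, min_peak: float = 0.05) -> tuple[float, float]:
    peak = float(heatmap.max())
    if peak < min_peak or peak - float(heatmap.min()) < min_peak:
        raise ValueError("landmark not found: flat heatmap")
    r0, c0 = np.unravel_index(int(np.argmax(heatmap)), heatmap.shape)
    r_lo, r_hi = max(0, r0 - 2), min(heatmap.shape[0], r0 + 3)
    c_lo, c_hi = max(0, c0 - 2), min(heatmap.shape[1], c0 + 3)
    win = np.clip(heatmap[r_lo:r_hi, c_lo:c_hi], 0.0, None)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    w = win.sum()
    return (float((rr * win).sum() / w), float((cc * win).sum() / w))


def localize_landmarks(frame: np.ndarray, model: LocalizerModel,
                       view_label: str = "4ch") -> LandmarkPair:
    """Localize the two hinge points on one frame (sub-pixel, canonical order).

    Raises ``ValueError`` when a predicted heatmap is flat (no confident
    peak), in which case the pipeline falls back to manual points.
    """
    maps = model.heatmaps(frame)
    p_a = _subpixel_peak(maps[0])
    p_b = _subpixel_peak(maps[1])
    return LandmarkPair(p_a, p_b, view_label=view_label)


def _to_mm(p: tuple[float, float], spacing: tuple[float, float]) -> np.ndarray:
    return np.array([p[0] * spacing[0], p[1] * spacing[1]])


def landmark_distance_sum(
    a: LandmarkPair, b: LandmarkPair, pixel_spacing_mm: tuple[float, float]
) -> float:
    """Sum of Euclidean distances between matched hinge points, in mm.

    Points are matched by canonical (column) order.
    """
    if a.view_label != b.view_label:
        raise ValueError(f"view mismatch: {a.view_label} vs {b.view_label}")
    d_left = np.linalg.norm(_to_mm(a.p_left, pixel_spacing_mm) - _to_mm(b.p_left, pixel_spacing_mm))
    d_right = np.linalg.norm(_to_mm(a.p_right, pixel_spacing_mm) - _to_mm(b.p_right, pixel_spacing_mm))
    return float(d_left + d_right)


def annular_angle_deviation(
    a: LandmarkPair, b: LandmarkPair,
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Acute angle (degrees, 0-90) between the two mitral annular lines.

    Computed in physical mm coordinates so anisotropic spacing cannot bias it.
    """
    out = []
    for pair in (a, b):
        v = _to_mm(pair.p_right, pixel_spacing_mm) - _to_mm(pair.p_left, pixel_spacing_mm)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("annular line undefined: coincident points in a pair")
        out.append(v / n)
    cosang = abs(float(np.dot(out[0], out[1])))
    return math.degrees(math.acos(min(1.0, cosang)))
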