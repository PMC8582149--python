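"""Shared image helpers: model-input resampling and per-pixel feature stacks."""

from __future__ import annotations

import numpy as np
from skimage.feature import multiscale_basic_features
from skimage.transform import resize


def to_square_input(frame: np.ndarray, size: int) -> np.ndarray:
    """Resample a 2-D frame to ``size``x``size`` with aspect-preserving padding.

    Non-square frames are padded symmetrically with the frame minimum
    (background) before resizing, so anatomy is never stretched.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    if h != w:
        side = max(h, w)
        pad_r = side - h
        pad_c = side - w
        frame = np.pad(
            frame,
            ((pad_r // 2, pad_r - pad_r // 2), (pad_c // 2, pad_c - pad_c // 2)),
            mode="constant",
            constant_values=float(frame.min()),
        )
    if frame.shape[0] != size:
        frame = resize(frame, (size, size), anti_aliasing=True, preserve_range=True)
    return frame


def pixel_feature_stack(
    frame: np.ndarray,
    sigma_min: float = 0.5,
    sigma_max: float = 4.0,
    extra_channels: tuple[np.ndarray, ...] = (),
) -> np.ndarray:
    """Per-pixel feature matrix for trainable segmentation/localization.

    Combines multiscale intensity/edge/texture features with normalized
    (row, col) coordinate channels; returns an (H*W, n_features) array.
    """
    frame = np.asarray(frame, dtype=float)
    feats = multiscale_basic_features(
        frame,
        intensity=True,
        edges=True,
        texture=True,
        sigma_min=sigma_min,
        sigma_max=sigma_max,
    )
    h, w = frame.shape
    rr, cc = np.meshgrid(
        np.linspace(0.0, 1.0, h), np.linspace(0.0, 1.0, w), indexing="ij"
    )
    channels = [feats.reshape(h * w, -1), rr.reshape(-1, 1), cc.reshape(-1, 1)]
    for ch in extra_channels:
        channels.append(np.asarray(ch, dtype=float).reshape(h * w, -1))
    return np.concatenate(channels, axis=1)
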