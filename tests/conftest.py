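"""Shared fixtures: phantom suites and desk-scale trained models.

The trained models are session-scoped because three trainings (~1 min) feed
many tests; all phantom generation is seeded and deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import atriu

warnings.filterwarnings("ignore", message=".*Maximum iterations.*")

TRAIN_SEED = 100
HELDOUT_SEED = 200
NOISELESS_EVAL_SEED = 300
MODEL_SEED = 7


@pytest.fixture(scope="session")
def train_studies():
    """20 noiseless phantom studies used to train all desk-scale models."""
    return [atriu.generate_study(s) for s in atriu.sample_specs(20, seed=TRAIN_SEED, noise_sd=0.0)]


@pytest.fixture(scope="session")
def heldout_studies():
    """20 held-out phantom studies at the default noise level."""
    return [atriu.generate_study(s) for s in atriu.sample_specs(20, seed=HELDOUT_SEED)]


@pytest.fixture(scope="session")
def noiseless_eval_studies():
    """20 held-out noiseless phantom studies."""
    return [
        atriu.generate_study(s)
        for s in atriu.sample_specs(20, seed=NOISELESS_EVAL_SEED, noise_sd=0.0)
    ]


@pytest.fixture(scope="session")
def trained_models(train_studies) -> atriu.ModelBundle:
    """All three models trained at a fixed seed on the noiseless suite."""
    return atriu.ModelBundle(
        frame_classifier=atriu.train_frame_classifier(
            train_studies, atriu.FrameClassifierConfig(seed=MODEL_SEED)
        ),
        segmenter=atriu.train_segmenter(
            train_studies, atriu.SegModelConfig(seed=MODEL_SEED)
        ),
        localizer=atriu.train_localizer(
            train_studies, atriu.SegModelConfig(seed=MODEL_SEED)
        ),
    )


@pytest.fixture()
def disk_mask():
    """Rasterized disk of radius 20 px centered at (50, 50), 1 mm spacing."""
    rr, cc = np.mgrid[0:101, 0:101]
    pixels = (rr - 50) ** 2 + (cc - 50) ** 2 <= 400
    return atriu.MaskImage(pixels, (1.0, 1.0))
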