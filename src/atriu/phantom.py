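"""Synthetic 2ch/4ch cine phantom with exact ground truth.

The phantom models the left atrium as one analytic ellipsoid with semi-axes
(a, b, c): the 2ch view is the plane through (a, c), the 4ch view the plane
through (b, c), sharing the long axis c (vertical in the image).  Over the
cardiac cycle the semi-axes follow a smooth cosine contraction that peaks at
the end-systolic frame.  The mitral annular plane sits near the caudal apex
of the ellipse; the two hinge-point landmarks are the ends of the ellipse
boundary chord on that plane.  The mitral valve is rendered as a bright line
on the annular plane: a continuous chord when closed, two separated leaflet
stubs when open.  Intensities are piecewise constant (background, myocardial
rim, blood pool, valve) plus optional Gaussian noise.

Every study carries per-view, per-frame truth masks and landmarks, per-frame
valve states, the true ES index and the analytic ellipsoid volume, so every
downstream module can be trained and tested without clinical data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .io_formats import (
    AnnotationSet,
    CineSequence,
    read_annotations,
    read_cine,
    write_annotations,
    write_cine,
)
from .landmarks import LandmarkPair
from .segmentation import MaskImage

__all__ = ["PhantomSpec", "PhantomStudy", "generate_study", "generate_3d_stack",
           "sample_specs", "write_study", "read_study"]

# fraction of the long semi-axis (below center) at which the annular plane sits;
# close to 1 so the longitudinal diameter spans nearly the full long axis, but
# strictly below 1 so the hinge points are distinct
ANNULAR_OFFSET_FRACTION = 0.985

# intensity model
I_BACKGROUND = 0.2
I_MYOCARDIUM = 0.45
I_BLOOD = 0.9
I_VALVE = 1.0
RIM_PX = 3.0
# horizontal half-extent of the rendered valve line, in units of the in-plane
# short semi-axis (wider than the in-mask chord: the leaflets span the annulus)
VALVE_HALF_EXTENT = 0.8
VALVE_GAP = 0.45  # open-state leaflet stubs end at this fraction of the extent


@dataclass
class PhantomSpec:
    """Parameters of one synthetic study; defaults are a typical adult LA."""

    image_size: int = 96
    pixel_spacing_mm: float = 1.4
    n_frames: int = 25
    ellipsoid_semi_axes_mm: tuple[float, float, float] = (20.0, 24.0, 32.0)
    volume_amplitude: float = 0.25
    es_frame_index: int = 10
    noise_sd: float = 0.02
    seed: int = 0
    view_tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        a, b, c = self.ellipsoid_semi_axes_mm
        if not (a > 0 and b > 0 and c > 0):
            raise ValueError("ellipsoid_semi_axes_mm must all be positive")
        if not 0 <= self.volume_amplitude < 1:
            raise ValueError("volume_amplitude must lie in [0, 1)")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0 <= self.es_frame_index < self.n_frames:
            raise ValueError("es_frame_index must lie in [0, n_frames)")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        sem_px = max(a, b, c) / self.pixel_spacing_mm
        center = self.image_size // 2
        margin = min(center, self.image_size - 1 - center)
        if sem_px + 2 > margin:
            raise ValueError(
                "image_size too small: the atrium needs a >= 2 pixel margin "
                f"(semi-axis {sem_px:.1f} px, margin {margin} px)"
            )

    @property
    def truth_volume_ml(self) -> float:
        a, b, c = self.ellipsoid_semi_axes_mm
        return 4.0 / 3.0 * math.pi * a * b * c / 1000.0


@dataclass
class PhantomStudy:
    """One synthetic study: paired cines plus exhaustive ground truth."""

    spec: PhantomSpec
    cine_2ch: CineSequence
    cine_4ch: CineSequence
    truth_masks: dict  # view -> list[MaskImage] per frame
    truth_landmarks: dict  # view -> list[LandmarkPair] per frame
    truth_valve_states: np.ndarray  # bool per frame, True = closed
    truth_es_index: int
    truth_volume_ml: float
    stack_3d: Optional[CineSequence] = None
    slice_thickness_mm: Optional[float] = None
    truth_stack_masks: Optional[list[MaskImage]] = None


def _cycle_scale(spec: PhantomSpec, t: int) -> float:
    phase = 2.0 * math.pi * (t - spec.es_frame_index) / spec.n_frames
    return 1.0 - spec.volume_amplitude * (1.0 - math.cos(phase)) / 2.0


def _inplane_semi_axes(spec: PhantomSpec, view: str) -> tuple[float, float]:
    """(horizontal, vertical) semi-axes in mm for one view, with optional tilt."""
    a, b, c = spec.ellipsoid_semi_axes_mm
    th = math.radians(spec.view_tilt_deg)
    if view == "2ch":
        horiz = math.hypot(a * math.cos(th), b * math.sin(th))
    else:
        horiz = math.hypot(b * math.cos(th), a * math.sin(th))
    return horiz, c


def _closed_block(spec: PhantomSpec) -> np.ndarray:
    states = np.zeros(spec.n_frames, dtype=bool)
    length = max(3, int(round(spec.n_frames / 3)))
    start = max(0, spec.es_frame_index - length + 1)
    states[start : spec.es_frame_index + 1] = True
    return states


def _render_view(spec: PhantomSpec, view: str, rng: np.random.Generator):
    size = spec.image_size
    p = spec.pixel_spacing_mm
    r0 = c0 = size // 2
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    horiz_mm, vert_mm = _inplane_semi_axes(spec, view)
    states = _closed_block(spec)

    frames, masks, lms = [], [], []
    for t in range(spec.n_frames):
        s = _cycle_scale(spec, t)
        ax = horiz_mm * s / p
        ay = vert_mm * s / p
        ellipse = ((cc - c0) / ax) ** 2 + ((rr - r0) / ay) ** 2 <= 1.0
        rim = ((cc - c0) / (ax + RIM_PX)) ** 2 + ((rr - r0) / (ay + RIM_PX)) ** 2 <= 1.0
        img = np.full((size, size), I_BACKGROUND)
        img[rim] = I_MYOCARDIUM
        img[ellipse] = I_BLOOD

        f = ANNULAR_OFFSET_FRACTION
        rv = r0 + f * ay
        half_chord = ax * math.sqrt(1.0 - f * f)
        lm = LandmarkPair((rv, c0 - half_chord), (rv, c0 + half_chord), view_label=view)

        _draw_valve(img, rv, c0, ax, closed=bool(states[t]))

        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        frames.append(img)
        masks.append(MaskImage(ellipse, (p, p)))
        lms.append(lm)
    cine = CineSequence(np.stack(frames), (p, p), view)
    return cine, masks, lms, states


def _draw_valve(img: np.ndarray, rv: float, c0: float, ax: float, closed: bool) -> None:
    size = img.shape[0]
    rows = [int(round(rv)), int(round(rv)) + 1]
    ext = VALVE_HALF_EXTENT * ax
    if closed:
        spans = [(c0 - ext, c0 + ext)]
    else:
        spans = [(c0 - ext, c0 - VALVE_GAP * ax), (c0 + VALVE_GAP * ax, c0 + ext)]
    for r in rows:
        if not 0 <= r < size:
            continue
        for lo, hi in spans:
            a = max(0, int(round(lo)))
            b = min(size - 1, int(round(hi)))
            if b >= a:
                img[r, a : b + 1] = I_VALVE


def generate_study(spec: PhantomSpec) -> PhantomStudy:
    """Generate one paired 2ch/4ch phantom study; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    cine2, masks2, lms2, states = _render_view(spec, "2ch", rng)
    cine4, masks4, lms4, _ = _render_view(spec, "4ch", rng)
    return PhantomStudy(
        spec=spec,
        cine_2ch=cine2,
        cine_4ch=cine4,
        truth_masks={"2ch": masks2, "4ch": masks4},
        truth_landmarks={"2ch": lms2, "4ch": lms4},
        truth_valve_states=states,
        truth_es_index=spec.es_frame_index,
        truth_volume_ml=spec.truth_volume_ml,
    )


def generate_3d_stack(
    spec: PhantomSpec, n_slices: int, slice_thickness_mm: float
) -> PhantomStudy:
    """Generate a study with an axial multislice stack of the ES ellipsoid.

    Slices are perpendicular to the long axis c; the stack extent
    ``n_slices * slice_thickness_mm`` must cover the full long axis (2c).
    The sum of per-slice areas times the thickness converges to the analytic
    ellipsoid volume as the slices get thinner.
    """
    if n_slices < 3:
        raise ValueError("a 3-D stack needs at least 3 slices")
    if slice_thickness_mm <= 0:
        raise ValueError("slice thickness must be positive")
    a, b, c = spec.ellipsoid_semi_axes_mm
    extent = n_slices * slice_thickness_mm
    if extent < 2.0 * c:
        raise ValueError(
            f"slice extent {extent:.1f} mm does not cover the ellipsoid (2c = {2*c:.1f} mm)"
        )
    study = generate_study(spec)
    rng = np.random.default_rng(spec.seed + 1)
    size = spec.image_size
    p = spec.pixel_spacing_mm
    r0 = c0 = size // 2
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    frames, masks = [], []
    for i in range(n_slices):
        z = -extent / 2.0 + (i + 0.5) * slice_thickness_mm
        shrink = 1.0 - (z / c) ** 2
        img = np.full((size, size), I_BACKGROUND)
        ellipse = np.zeros((size, size), dtype=bool)
        if shrink > 0:
            ax = a * math.sqrt(shrink) / p
            ay = b * math.sqrt(shrink) / p
            ellipse = ((cc - c0) / max(ax, 1e-9)) ** 2 + (
                (rr - r0) / max(ay, 1e-9)
            ) ** 2 <= 1.0
            rim = ((cc - c0) / (ax + RIM_PX)) ** 2 + ((rr - r0) / (ay + RIM_PX)) ** 2 <= 1.0
            img[rim] = I_MYOCARDIUM
            img[ellipse] = I_BLOOD
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        frames.append(img)
        masks.append(MaskImage(ellipse, (p, p)))
    study.stack_3d = CineSequence(np.stack(frames), (p, p), "axial")
    study.slice_thickness_mm = float(slice_thickness_mm)
    study.truth_stack_masks = masks
    return study


def sample_specs(
    n: int,
    seed: int,
    noise_sd: float = 0.02,
    pixel_spacing_mm: float = 1.4,
    image_size: int = 96,
    n_frames: int = 25,
) -> list[PhantomSpec]:
    """Draw n study specs with anatomically plausible variation.

    Semi-axes are drawn uniformly (a: 14-26, b: 16-30, c: 26-40 mm), the ES
    index uniformly over the middle of the cycle, the contraction amplitude
    uniformly in 0.2-0.3.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        a = rng.uniform(14.0, 26.0)
        b = rng.uniform(16.0, 30.0)
        c = rng.uniform(26.0, 40.0)
        es = int(rng.integers(n_frames // 3, 2 * n_frames // 3 + 1))
        amp = float(rng.uniform(0.2, 0.3))
        specs.append(
            PhantomSpec(
                image_size=image_size,
                pixel_spacing_mm=pixel_spacing_mm,
                n_frames=n_frames,
                ellipsoid_semi_axes_mm=(a, b, c),
                volume_amplitude=amp,
                es_frame_index=es,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# persistence (NIfTI per view + JSON truth sidecars)

def write_study(study: PhantomStudy, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for view in ("2ch", "4ch"):
        write_cine(getattr(study, f"cine_{view}"), out / f"cine_{view}.nii.gz")
        states = ["closed" if s else "open" for s in study.truth_valve_states]
        ann = AnnotationSet(
            masks=list(study.truth_masks[view]),
            landmarks=list(study.truth_landmarks[view]),
            valve_states=states,
            es_index=study.truth_es_index,
            source="human",
        )
        write_annotations(ann, out / f"truth_{view}.json")
    meta = {
        "truth_volume_ml": study.truth_volume_ml,
        "truth_es_index": study.truth_es_index,
        "spec": {
            "image_size": study.spec.image_size,
            "pixel_spacing_mm": study.spec.pixel_spacing_mm,
            "n_frames": study.spec.n_frames,
            "ellipsoid_semi_axes_mm": list(study.spec.ellipsoid_semi_axes_mm),
            "volume_amplitude": study.spec.volume_amplitude,
            "es_frame_index": study.spec.es_frame_index,
            "noise_sd": study.spec.noise_sd,
            "seed": study.spec.seed,
            "view_tilt_deg": study.spec.view_tilt_deg,
        },
    }
    (out / "study.json").write_text(json.dumps(meta))
    return out


def read_study(path) -> PhantomStudy:
    path = Path(path)
    meta = json.loads((path / "study.json").read_text())
    spec_d = dict(meta["spec"])
    spec_d["ellipsoid_semi_axes_mm"] = tuple(spec_d["ellipsoid_semi_axes_mm"])
    spec = PhantomSpec(**spec_d)
    cines, masks, lms = {}, {}, {}
    states = None
    for view in ("2ch", "4ch"):
        cines[view] = read_cine(path / f"cine_{view}.nii.gz", view)
        ann = read_annotations(path / f"truth_{view}.json")
        masks[view] = ann.masks
        lms[view] = ann.landmarks
        states = np.array([s == "closed" for s in ann.valve_states])
    return PhantomStudy(
        spec=spec,
        cine_2ch=cines["2ch"],
        cine_4ch=cines["4ch"],
        truth_masks=masks,
        truth_landmarks=lms,
        truth_valve_states=states,
        truth_es_index=meta["truth_es_index"],
        truth_volume_ml=meta["truth_volume_ml"],
    )
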