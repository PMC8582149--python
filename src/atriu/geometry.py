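"""Longitudinal-diameter construction and biplane area-length volumetry.

Unit contract (package-wide): lengths in mm, areas in mm², volumes in mL
(mm³ / 1000).  Pixel coordinates are 0-based (row, col) with pixel centers at
integer positions; conversion to mm multiplies by the per-axis spacing.

Diameter lengths are measured against the continuous support of the binary
mask: a point is inside where the bilinearly interpolated mask is >= 0.5,
i.e. the region extends half a pixel beyond the boundary pixel centers.  For
a shape rasterized by the pixel-center-inside rule this 0.5 level set is an
unbiased estimate of the underlying continuous boundary, which keeps the
length (and hence the biplane volume) free of a systematic half-pixel
shortfall.  Crossings are located by 0.1-px-step ray sampling followed by
bisection to 0.01 px.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .landmarks import LandmarkPair
from .segmentation import MaskImage

__all__ = [
    "DiameterLine",
    "VolumeResult",
    "mask_area",
    "mask_centroid",
    "construct_diameter_centroid",
    "construct_diameter_perpendicular",
    "biplane_volume",
    "volume_3d",
    "bsa_m2",
    "index_volume",
]

BIPLANE_CONSTANT = 8.0 / (3.0 * math.pi)

_SAMPLE_STEP_PX = 0.1
_BISECT_TOL_PX = 0.01


@dataclass
class DiameterLine:
    """One longitudinal atrial diameter.

    ``annular_midpoint`` is the (row, col) sub-pixel base point on the mitral
    annular level; ``direction`` is the unit direction of the ray in mm
    coordinates; ``length_mm`` the distance from the base point to the
    farthest mask-boundary crossing.
    """

    annular_midpoint: tuple[float, float]
    direction: tuple[float, float]
    length_mm: float
    variant: str
    view_label: str = ""

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValueError("diameter length must be positive")
        n = math.hypot(*self.direction)
        if not math.isclose(n, 1.0, rel_tol=1e-6):
            self.direction = (self.direction[0] / n, self.direction[1] / n)
        if self.variant not in ("centroid", "perpendicular"):
            raise ValueError(f"unknown diameter variant {self.variant!r}")


@dataclass
class VolumeResult:
    """Areas, diameters and biplane volume for one study."""

    area_2ch_mm2: float
    area_4ch_mm2: float
    diameter_2ch: DiameterLine
    diameter_4ch: DiameterLine
    l_min_mm: float
    lav_max_ml: float
    lavi_max_ml_per_m2: float | None = None
    es_index: int | None = None
    source_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = min(self.diameter_2ch.length_mm, self.diameter_4ch.length_mm)
        if not math.isclose(self.l_min_mm, expected, rel_tol=1e-9):
            raise ValueError("l_min_mm must equal the minimum diameter length")
        if self.lav_max_ml < 0:
            raise ValueError("lav_max_ml must be non-negative")


def mask_area(mask: MaskImage) -> float:
    """Mask area in mm²: pixel count x row spacing x column spacing."""
    sr, sc = mask.pixel_spacing_mm
    return float(mask.n_pixels) * sr * sc


def mask_centroid(mask: MaskImage) -> tuple[float, float]:
    """Unweighted mean (row, col) of foreground pixel coordinates."""
    if mask.n_pixels == 0:
        raise ValueError("centroid undefined for an empty mask")
    coords = np.argwhere(mask.pixels)
    return (float(coords[:, 0].mean()), float(coords[:, 1].mean()))


def _px_to_mm(p, spacing) -> np.ndarray:
    return np.array([p[0] * spacing[0], p[1] * spacing[1]], dtype=float)


def _inside(mask_f: np.ndarray, pts_mm: np.ndarray, spacing) -> np.ndarray:
    """Bilinear membership test for points given in mm coordinates."""
    coords = np.vstack([pts_mm[:, 0] / spacing[0], pts_mm[:, 1] / spacing[1]])
    vals = map_coordinates(mask_f, coords, order=1, mode="constant", cval=0.0)
    return vals >= 0.5


def _farthest_crossing_mm(
    mask: MaskImage, origin_mm: np.ndarray, direction: np.ndarray
) -> float | None:
    """Distance from origin to the farthest 0.5-level crossing along the ray.

    Returns None when no ray sample falls inside the mask.
    """
    mask_f = mask.pixels.astype(float)
    h, w = mask.pixels.shape
    diag_mm = math.hypot(h * mask.pixel_spacing_mm[0], w * mask.pixel_spacing_mm[1])
    step = _SAMPLE_STEP_PX * min(mask.pixel_spacing_mm)
    ts = np.arange(0.0, diag_mm + step, step)
    pts = origin_mm[None, :] + ts[:, None] * direction[None, :]
    ins = _inside(mask_f, pts, mask.pixel_spacing_mm)
    if not ins.any():
        return None
    i = int(np.flatnonzero(ins)[-1])
    lo = ts[i]
    hi = ts[i + 1] if i + 1 < len(ts) else lo + step
    tol = _BISECT_TOL_PX * min(mask.pixel_spacing_mm)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        p = (origin_mm + mid * direction)[None, :]
        if _inside(mask_f, p, mask.pixel_spacing_mm)[0]:
            lo = mid
        else:
            hi = mid
    return float(0.5 * (lo + hi))


def construct_diameter_centroid(
    mask: MaskImage, lm: LandmarkPair, view_label: str = ""
) -> DiameterLine:
    """Diameter from the annular midpoint through the mask center of mass.

    The ray starts at the midpoint of the mitral annular level and passes
    through the segmentation centroid; its length is the distance to the
    farthest mask-boundary crossing (the posterior wall).
    """
    if mask.n_pixels == 0:
        raise ValueError("diameter undefined for an empty mask")
    spacing = mask.pixel_spacing_mm
    mid_mm = _px_to_mm(lm.midpoint(), spacing)
    cen_mm = _px_to_mm(mask_centroid(mask), spacing)
    vec = cen_mm - mid_mm
    norm = float(np.linalg.norm(vec))
    if norm < 1e-9:
        raise ValueError("degenerate direction: centroid equals annular midpoint")
    direction = vec / norm
    length = _farthest_crossing_mm(mask, mid_mm, direction)
    if length is None or length <= 0:
        raise ValueError("diameter ray never enters the mask")
    mid_px = lm.midpoint()
    return DiameterLine(mid_px, tuple(direction), length, "centroid", view_label)


def construct_diameter_perpendicular(
    mask: MaskImage, lm: LandmarkPair, view_label: str = ""
) -> DiameterLine:
    """Longest perpendicular from the mitral annular level to the posterior wall.

    Base points step along the annular segment at 0.5-px intervals; from each,
    a ray perpendicular to the annular line (in mm space, toward the mask
    side) is cast and the farthest boundary crossing is measured.  The
    maximizing line is returned.
    """
    if mask.n_pixels == 0:
        raise ValueError("diameter undefined for an empty mask")
    spacing = mask.pixel_spacing_mm
    a_mm = _px_to_mm(lm.p_left, spacing)
    b_mm = _px_to_mm(lm.p_right, spacing)
    seg = b_mm - a_mm
    seg_len = float(np.linalg.norm(seg))
    if seg_len < 1e-9:
        raise ValueError("annular segment degenerate: coincident landmarks")
    u = seg / seg_len
    normal = np.array([-u[1], u[0]])
    cen_mm = _px_to_mm(mask_centroid(mask), spacing)
    mid_mm = 0.5 * (a_mm + b_mm)
    if float(np.dot(cen_mm - mid_mm, normal)) < 0:
        normal = -normal
    step = 0.5 * min(spacing)
    n_steps = max(2, int(seg_len / step) + 1)
    best: tuple[float, np.ndarray] | None = None
    for t in np.linspace(0.0, 1.0, n_steps):
        base = a_mm + t * seg
        length = _farthest_crossing_mm(mask, base, normal)
        if length is not None and (best is None or length > best[0]):
            best = (length, base)
    if best is None or best[0] <= 0:
        raise ValueError("no perpendicular from the annular level enters the mask")
    length, base = best
    base_px = (base[0] / spacing[0], base[1] / spacing[1])
    return DiameterLine(base_px, tuple(normal), length, "perpendicular", view_label)


def biplane_volume(area_2ch_mm2: float, area_4ch_mm2: float, l_min_mm: float) -> float:
    """Biplane area-length volume V = (8 / 3π) · A2ch · A4ch / L, in mL."""
    if area_2ch_mm2 < 0 or area_4ch_mm2 < 0:
        raise ValueError("areas must be non-negative")
    if l_min_mm <= 0:
        raise ValueError("longitudinal diameter must be positive")
    return BIPLANE_CONSTANT * area_2ch_mm2 * area_4ch_mm2 / l_min_mm / 1000.0


def volume_3d(areas_mm2, slice_thickness_mm: float) -> float:
    """Slice-summation volume: sum of per-slice area times thickness, in mL."""
    if slice_thickness_mm <= 0:
        raise ValueError("slice thickness must be positive")
    areas = np.asarray(list(areas_mm2), dtype=float)
    if (areas < 0).any():
        raise ValueError("slice areas must be non-negative")
    return float(areas.sum() * slice_thickness_mm / 1000.0)


def bsa_m2(height_cm: float, weight_kg: float) -> float:
    """Mosteller body surface area: sqrt(height · weight / 3600), in m²."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return math.sqrt(height_cm * weight_kg / 3600.0)


def index_volume(lav_ml: float, bsa: float) -> float:
    """BSA-indexed volume in mL/m²."""
    if bsa <= 0:
        raise ValueError("BSA must be positive")
    if lav_ml < 0:
        raise ValueError("volume must be non-negative")
    return lav_ml / bsa


def compute_volume_result(
    mask_2ch: MaskImage,
    mask_4ch: MaskImage,
    lm_2ch: LandmarkPair,
    lm_4ch: LandmarkPair,
    es_index: int | None = None,
    variant: str = "centroid",
    height_cm: float | None = None,
    weight_kg: float | None = None,
    source_flags: dict | None = None,
) -> VolumeResult:
    """Assemble areas, diameters and the biplane volume into a VolumeResult."""
    construct = (
        construct_diameter_centroid if variant == "centroid"
        else construct_diameter_perpendicular
    )
    d2 = construct(mask_2ch, lm_2ch, view_label="2ch")
    d4 = construct(mask_4ch, lm_4ch, view_label="4ch")
    a2 = mask_area(mask_2ch)
    a4 = mask_area(mask_4ch)
    l_min = min(d2.length_mm, d4.length_mm)
    lav = biplane_volume(a2, a4, l_min)
    lavi = None
    if height_cm is not None and weight_kg is not None:
        lavi = index_volume(lav, bsa_m2(height_cm, weight_kg))
    return VolumeResult(
        area_2ch_mm2=a2,
        area_4ch_mm2=a4,
        diameter_2ch=d2,
        diameter_4ch=d4,
        l_min_mm=l_min,
        lav_max_ml=lav,
        lavi_max_ml_per_m2=lavi,
        es_index=es_index,
        source_flags=dict(source_flags or {}),
    )
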