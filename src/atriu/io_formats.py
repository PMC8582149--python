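"""Reading and writing of cines, annotation sidecars and result tables.

Coordinate convention, recorded in every sidecar: 0-based (row, col) pixel
indices with pixel centers at integer coordinates; conversion to mm
multiplies by the per-axis spacing.  Lengths are mm, areas mm², volumes mL.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from imageio.v3 import imread

from .geometry import VolumeResult
from .landmarks import LandmarkPair
from .segmentation import MaskImage

__all__ = [
    "CineSequence",
    "AnnotationSet",
    "read_cine",
    "write_cine",
    "read_annotations",
    "write_annotations",
    "write_results",
]

SCHEMA_VERSION = "atriu-annotations-1"
VIEW_LABELS = ("2ch", "4ch", "axial")
SOURCES = ("automatic", "human", "corrected")


@dataclass
class CineSequence:
    """One view's ordered multiphase frames with physical metadata."""

    frames: np.ndarray  # (n_frames, rows, cols)
    pixel_spacing_mm: tuple[float, float]
    view_label: str
    frame_times_ms: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("a cine needs >= 2 frames of identical shape")
        sr, sc = self.pixel_spacing_mm
        if not (sr > 0 and sc > 0):
            raise ValueError("pixel spacing must be positive")
        self.pixel_spacing_mm = (float(sr), float(sc))
        if self.view_label not in VIEW_LABELS:
            raise ValueError(f"view_label must be one of {VIEW_LABELS}")
        if self.frame_times_ms is not None:
            self.frame_times_ms = np.asarray(self.frame_times_ms, dtype=float)
            if len(self.frame_times_ms) != len(self.frames):
                raise ValueError("frame_times_ms length must match frame count")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class AnnotationSet:
    """Per-frame annotations for one view: masks, landmarks, valve states.

    Any present per-frame field must have one entry per cine frame (entries
    may be None for frames without that annotation).
    """

    masks: Optional[list[Optional[MaskImage]]] = None
    landmarks: Optional[list[Optional[LandmarkPair]]] = None
    valve_states: Optional[list[Optional[str]]] = None
    es_index: Optional[int] = None
    source: str = "automatic"

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}")
        lengths = {
            len(f) for f in (self.masks, self.landmarks, self.valve_states)
            if f is not None
        }
        if len(lengths) > 1:
            raise ValueError("per-frame annotation fields differ in length")
        if self.valve_states is not None:
            for s in self.valve_states:
                if s not in (None, "open", "closed"):
                    raise ValueError(f"invalid valve state {s!r}")
        if self.es_index is not None and lengths:
            n = lengths.pop()
            if not 0 <= self.es_index < n:
                raise ValueError("es_index outside the annotated frame range")

    def n_frames(self) -> Optional[int]:
        for f in (self.masks, self.landmarks, self.valve_states):
            if f is not None:
                return len(f)
        return None


# ---------------------------------------------------------------------------
# cines

def read_cine(path, view_label: str) -> CineSequence:
    """Read a cine from a NIfTI file (frames on the last axis) or a directory
    of lexically ordered image frames with a JSON spacing sidecar."""
    path = Path(path)
    if path.is_dir():
        return _read_cine_dir(path, view_label)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3 or data.shape[-1] < 2:
        raise ValueError(f"{path}: expected a 3-D volume with >= 2 frames on the last axis")
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1]))
    frames = np.moveaxis(data, -1, 0).astype(float)
    return CineSequence(frames, spacing, view_label)


def _read_cine_dir(path: Path, view_label: str) -> CineSequence:
    sidecar = path / "cine.json"
    if not sidecar.exists():
        raise ValueError(
            f"{path}: image directories require a cine.json sidecar with pixel_spacing_mm"
        )
    meta = json.loads(sidecar.read_text())
    if "pixel_spacing_mm" not in meta:
        raise ValueError(f"{sidecar}: missing pixel_spacing_mm (areas would be unitless)")
    spacing = tuple(float(v) for v in meta["pixel_spacing_mm"])
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if len(files) < 2:
        raise ValueError(f"{path}: a cine needs >= 2 frames")
    frames = np.stack([np.asarray(imread(f), dtype=float) for f in files])
    times = meta.get("frame_times_ms")
    return CineSequence(frames, spacing, view_label, frame_times_ms=times)


def write_cine(cine: CineSequence, path) -> Path:
    """Write a cine as NIfTI-1 with the spacing in the header (frames last)."""
    path = Path(path)
    data = np.moveaxis(cine.frames, 0, -1)
    sr, sc = cine.pixel_spacing_mm
    affine = np.diag([sr, sc, 1.0, 1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_zooms((sr, sc, 1.0))
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# annotation sidecars (JSON, masks run-length encoded)

def _rle_encode(pixels: np.ndarray) -> list[int]:
    flat = np.asarray(pixels, bool).ravel()
    out: list[int] = []
    diff = np.flatnonzero(np.diff(flat.astype(np.int8)))
    edges = np.concatenate([[-1], diff, [flat.size - 1]])
    for a, b in zip(edges[:-1], edges[1:]):
        if flat[a + 1]:
            out.extend([int(a + 1), int(b - a)])
    return out


def _rle_decode(runs: Sequence[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for start, length in zip(runs[::2], runs[1::2]):
        flat[start : start + length] = True
    return flat.reshape(shape)


def _mask_to_json(m: Optional[MaskImage]):
    if m is None:
        return None
    return {
        "shape": list(m.pixels.shape),
        "pixel_spacing_mm": list(m.pixel_spacing_mm),
        "rle": _rle_encode(m.pixels),
        "flagged": bool(m.flagged),
    }


def _mask_from_json(d) -> Optional[MaskImage]:
    if d is None:
        return None
    return MaskImage(
        _rle_decode(d["rle"], tuple(d["shape"])),
        tuple(d["pixel_spacing_mm"]),
        flagged=bool(d.get("flagged", False)),
    )


def _landmarks_to_json(lm: Optional[LandmarkPair]):
    if lm is None:
        return None
    return {
        "p_left": list(lm.p_left),
        "p_right": list(lm.p_right),
        "view_label": lm.view_label,
    }


def _landmarks_from_json(d) -> Optional[LandmarkPair]:
    if d is None:
        return None
    return LandmarkPair(tuple(d["p_left"]), tuple(d["p_right"]), d["view_label"])


def write_annotations(ann: AnnotationSet, path) -> Path:
    path = Path(path)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "order": "row,col",
        "origin": "0-based",
        "source": ann.source,
        "es_index": ann.es_index,
        "valve_states": ann.valve_states,
        "masks": None if ann.masks is None else [_mask_to_json(m) for m in ann.masks],
        "landmarks": None
        if ann.landmarks is None
        else [_landmarks_to_json(lm) for lm in ann.landmarks],
    }
    path.write_text(json.dumps(doc))
    return path


def read_annotations(path) -> AnnotationSet:
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"annotation schema mismatch: file has {version!r}, expected {SCHEMA_VERSION!r}"
        )
    if doc.get("order") != "row,col" or doc.get("origin") != "0-based":
        raise ValueError("annotation file missing or violating the row,col/0-based convention")
    return AnnotationSet(
        masks=None if doc["masks"] is None else [_mask_from_json(m) for m in doc["masks"]],
        landmarks=None
        if doc["landmarks"] is None
        else [_landmarks_from_json(lm) for lm in doc["landmarks"]],
        valve_states=doc["valve_states"],
        es_index=doc["es_index"],
        source=doc["source"],
    )


# ---------------------------------------------------------------------------
# result tables

RESULT_COLUMNS = [
    "study_id",
    "area_2ch_mm2",
    "area_4ch_mm2",
    "l_2ch_mm",
    "l_4ch_mm",
    "l_min_mm",
    "lav_max_ml",
    "lavi_max_ml_per_m2",
    "es_index",
    "overrides",
]


def _override_string(flags: dict) -> str:
    return ";".join(f"{k}:{v}" for k, v in sorted(flags.items()) if v != "automatic")


def write_results(results, path) -> Path:
    """Write one CSV row per study (empty input -> header-only CSV).

    ``results`` is an iterable of ``(study_id, VolumeResult)`` pairs or of
    bare ``VolumeResult`` (ids then default to the position).
    """
    rows = []
    for i, item in enumerate(results):
        sid, res = item if isinstance(item, tuple) else (str(i), item)
        assert isinstance(res, VolumeResult)
        rows.append(
            {
                "study_id": sid,
                "area_2ch_mm2": res.area_2ch_mm2,
                "area_4ch_mm2": res.area_4ch_mm2,
                "l_2ch_mm": res.diameter_2ch.length_mm,
                "l_4ch_mm": res.diameter_4ch.length_mm,
                "l_min_mm": res.l_min_mm,
                "lav_max_ml": res.lav_max_ml,
                "lavi_max_ml_per_m2": res.lavi_max_ml_per_m2,
                "es_index": res.es_index,
                "overrides": _override_string(res.source_flags),
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, index=False)
    return Path(path)
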