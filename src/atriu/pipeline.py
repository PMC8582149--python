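"""End-to-end assisted workflow: automatic proposals, optional human
overrides, and recomputation of the biplane volume.

Stage order mirrors the clinical workup: (1) valve-state classification on
the 4ch cine and ES-frame selection, (2) transfer of the ES index to the 2ch
cine by proportional frame position, (3) LA segmentation of both ES frames,
(4) hinge-point localization on both ES frames, (5) diameter construction
and the biplane volume (optionally BSA-indexed).  A failing stage downgrades
the run to "needs manual input" for that stage instead of aborting; any
override replaces the corresponding proposal and all downstream quantities
are recomputed from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .frame_detection import FrameClassifier, classify_frames, select_es_frame
from .geometry import VolumeResult, compute_volume_result
from .io_formats import AnnotationSet, CineSequence, write_results
from .landmarks import LocalizerModel, localize_landmarks
from .segmentation import SegmentationModel, segment_la

__all__ = ["ModelBundle", "StudyRun", "run_study", "run_batch", "map_es_index"]


@dataclass
class ModelBundle:
    """The three trained models the pipeline needs."""

    frame_classifier: Optional[FrameClassifier] = None
    segmenter: Optional[SegmentationModel] = None
    localizer: Optional[LocalizerModel] = None


@dataclass
class StudyRun:
    """Record of one assisted study: proposals, applied overrides, result."""

    cine_2ch: CineSequence
    cine_4ch: CineSequence
    proposals: dict = field(default_factory=dict)  # view -> AnnotationSet
    overrides: dict = field(default_factory=dict)
    result: Optional[VolumeResult] = None
    audit_log: list[str] = field(default_factory=list)
    needs_manual: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.result is not None


def map_es_index(es_4ch: int, n_4ch: int, n_2ch: int) -> int:
    """Transfer the 4ch ES index to the 2ch cine by proportional position."""
    if n_4ch == n_2ch:
        return es_4ch
    return int(round(es_4ch * (n_2ch - 1) / (n_4ch - 1)))


def _override(overrides: dict, view: str, attr: str, frame_idx: int | None = None):
    ann: AnnotationSet | None = overrides.get(view)
    if ann is None:
        return None
    value = getattr(ann, attr, None)
    if value is None:
        return None
    if attr == "es_index":
        return value
    if frame_idx is None or frame_idx >= len(value):
        return None
    return value[frame_idx]


def run_study(
    cine_2ch: CineSequence,
    cine_4ch: CineSequence,
    models: ModelBundle,
    overrides: Optional[dict] = None,
    height_cm: Optional[float] = None,
    weight_kg: Optional[float] = None,
    diameter_variant: str = "centroid",
) -> StudyRun:
    """Run the assisted workflow on one paired study.

    ``overrides`` maps view labels to sparse :class:`AnnotationSet` objects
    (an ``es_index`` override lives under the "4ch" key).  Deterministic
    given the models and inputs.
    """
    if cine_2ch is None or cine_4ch is None:
        raise ValueError("both the 2ch and the 4ch cine are required")
    overrides = overrides or {}
    run = StudyRun(cine_2ch=cine_2ch, cine_4ch=cine_4ch, overrides=overrides)
    flags: dict[str, str] = {}

    # stage 1: ES frame on the 4ch cine
    es_4ch: Optional[int] = None
    es_override = _override(overrides, "4ch", "es_index")
    if es_override is not None:
        es_4ch = int(es_override)
        flags["es"] = overrides["4ch"].source
        run.audit_log.append(f"es:{overrides['4ch'].source}")
    elif models.frame_classifier is not None:
        try:
            states = classify_frames(cine_4ch, models.frame_classifier)
            es_4ch = select_es_frame(states)
            flags["es"] = "automatic"
            run.audit_log.append("es:automatic")
            run.proposals.setdefault("4ch", AnnotationSet()).es_index = es_4ch
        except ValueError as exc:
            run.needs_manual.append("es")
            run.audit_log.append(f"es:failed ({exc})")
    else:
        run.needs_manual.append("es")
        run.audit_log.append("es:failed (no model and no override)")
    if es_4ch is None:
        run.audit_log.append("result:absent (no ES frame)")
        return run

    es_2ch = map_es_index(es_4ch, cine_4ch.n_frames, cine_2ch.n_frames)
    if cine_4ch.n_frames != cine_2ch.n_frames:
        run.audit_log.append(
            f"es:mapped 4ch frame {es_4ch}/{cine_4ch.n_frames} -> "
            f"2ch frame {es_2ch}/{cine_2ch.n_frames} (proportional)"
        )
    es_by_view = {"2ch": es_2ch, "4ch": es_4ch}

    # stages 2+3: segmentation and landmarks on both ES frames
    masks, lms = {}, {}
    for view, cine in (("2ch", cine_2ch), ("4ch", cine_4ch)):
        idx = es_by_view[view]
        frame = cine.frames[idx]

        mask = _override(overrides, view, "masks", idx)
        if mask is not None:
            flags[f"mask_{view}"] = overrides[view].source
            run.audit_log.append(f"mask_{view}:{overrides[view].source}")
        elif models.segmenter is not None:
            mask = segment_la(frame, models.segmenter, cine.pixel_spacing_mm)
            if mask.flagged or mask.n_pixels == 0:
                run.needs_manual.append(f"mask_{view}")
                run.audit_log.append(f"mask_{view}:failed (empty prediction)")
                mask = None
            else:
                flags[f"mask_{view}"] = "automatic"
                run.audit_log.append(f"mask_{view}:automatic")
        else:
            run.needs_manual.append(f"mask_{view}")
            run.audit_log.append(f"mask_{view}:failed (no model and no override)")
        masks[view] = mask

        lm = _override(overrides, view, "landmarks", idx)
        if lm is not None:
            flags[f"landmarks_{view}"] = overrides[view].source
            run.audit_log.append(f"landmarks_{view}:{overrides[view].source}")
        elif models.localizer is not None:
            try:
                lm = localize_landmarks(frame, models.localizer, view_label=view)
                flags[f"landmarks_{view}"] = "automatic"
                run.audit_log.append(f"landmarks_{view}:automatic")
            except ValueError as exc:
                run.needs_manual.append(f"landmarks_{view}")
                run.audit_log.append(f"landmarks_{view}:failed ({exc})")
                lm = None
        else:
            run.needs_manual.append(f"landmarks_{view}")
            run.audit_log.append(f"landmarks_{view}:failed (no model and no override)")
        lms[view] = lm

    if any(masks[v] is None or lms[v] is None for v in ("2ch", "4ch")):
        run.audit_log.append("result:absent (missing stage outputs)")
        return run

    # stage 4: geometry and volume
    try:
        run.result = compute_volume_result(
            masks["2ch"], masks["4ch"], lms["2ch"], lms["4ch"],
            es_index=es_4ch, variant=diameter_variant,
            height_cm=height_cm, weight_kg=weight_kg, source_flags=flags,
        )
        run.audit_log.append("volume:computed")
    except ValueError as exc:
        run.needs_manual.append("geometry")
        run.audit_log.append(f"volume:failed ({exc})")
    return run


def run_batch(studies, models: ModelBundle, out_dir) -> list[tuple[str, StudyRun]]:
    """Run independent studies, isolate failures, write CSV + per-study JSON.

    ``studies`` is an iterable of (study_id, cine_2ch, cine_4ch) triples or of
    objects with ``cine_2ch``/``cine_4ch`` attributes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runs: list[tuple[str, StudyRun]] = []
    for i, item in enumerate(studies):
        if isinstance(item, tuple):
            sid, c2, c4 = item
        else:
            sid, c2, c4 = str(i), item.cine_2ch, item.cine_4ch
        try:
            run = run_study(c2, c4, models)
        except Exception as exc:  # corrupt study: isolate, keep batch alive
            run = StudyRun(cine_2ch=c2, cine_4ch=c4)
            run.audit_log.append(f"study:failed ({exc})")
            run.needs_manual.append("study")
        runs.append((sid, run))
        (out / f"{sid}.json").write_text(
            json.dumps(
                {
                    "study_id": sid,
                    "ok": run.ok,
                    "audit_log": run.audit_log,
                    "needs_manual": run.needs_manual,
                    "lav_max_ml": run.result.lav_max_ml if run.ok else None,
                }
            )
        )
    write_results(
        [(sid, run.result) for sid, run in runs if run.ok], out / "results.csv"
    )
    flagged = sum(1 for _, r in runs if not r.ok)
    summary = {
        "n_studies": len(runs),
        "n_ok": len(runs) - flagged,
        "n_flagged": flagged,
    }
    (out / "summary.json").write_text(json.dumps(summary))
    return runs
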