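"""Agreement statistics and the clinical time-saving model.

Bland–Altman limits of agreement use the 1.96 multiplier with the sample
(n-1) standard deviation.  The time model mirrors the clinical scoring
scheme: score 0 = full time saving for that step, score 1 = half, score 2 =
none; per-step expected savings are rounded to 0.1 s before summation
(reporting convention), and the reading time of the proposals is subtracted
from the subtotal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BlandAltmanResult",
    "TimeModelConfig",
    "ScoreTable",
    "TimeSavingResult",
    "bland_altman",
    "within_bounds_fraction",
    "expected_time_saving",
    "assisted_assessment_time",
    "acceptance_rate",
]

LOA_MULTIPLIER = 1.96

STEPS = ("es", "segmentation", "landmarks")


def _round_half_up(x: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class BlandAltmanResult:
    bias: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    n: int


@dataclass
class TimeModelConfig:
    """Manual per-step times (s), per-score saving fractions, reading time (s)."""

    manual_seconds: Mapping[str, float] = field(
        default_factory=lambda: {"es": 5.0, "segmentation": 80.0, "landmarks": 20.0}
    )
    saving_fraction: Mapping[int, float] = field(
        default_factory=lambda: {0: 1.0, 1: 0.5, 2: 0.0}
    )
    reading_seconds: float = 23.0

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.manual_seconds.values()):
            raise ValueError("manual step times must be non-negative")
        if any(not 0 <= f <= 1 for f in self.saving_fraction.values()):
            raise ValueError("saving fractions must lie in [0, 1]")
        if self.reading_seconds < 0:
            raise ValueError("reading time must be non-negative")

    @property
    def manual_total(self) -> float:
        return float(sum(self.manual_seconds.values()))


@dataclass
class ScoreTable:
    """Per-step proportions of scores {0, 1, 2}; each row sums to 1."""

    proportions: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for step, (p0, p1, p2) in self.proportions.items():
            if min(p0, p1, p2) < 0:
                raise ValueError(f"negative score proportion for step {step!r}")
            if abs(p0 + p1 + p2 - 1.0) > 1e-9:
                raise ValueError(f"score proportions for step {step!r} do not sum to 1")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int]]) -> "ScoreTable":
        """Build proportions from raw (step, score) records."""
        counts: dict[str, list[int]] = {}
        for step, score in records:
            if score not in (0, 1, 2):
                raise ValueError(f"score must be 0, 1 or 2, got {score}")
            counts.setdefault(step, [0, 0, 0])[score] += 1
        props = {
            step: tuple(c / sum(cs) for c in cs) for step, cs in counts.items()
        }
        return cls(props)


@dataclass
class TimeSavingResult:
    per_step_seconds: dict[str, float]
    subtotal_seconds: float
    total_seconds: float


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltmanResult:
    """Bland–Altman agreement of paired measurements (differences x - y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired measurements must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("Bland–Altman analysis needs at least 3 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = LOA_MULTIPLIER * sd
    return BlandAltmanResult(bias, bias - half, bias + half, sd, n)


def within_bounds_fraction(
    differences: Sequence[float], bounds: tuple[float, float]
) -> tuple[float, int, int]:
    """Fraction (and counts) of differences inside closed bounds [lower, upper]."""
    lower, upper = bounds
    if lower > upper:
        raise ValueError("lower bound exceeds upper bound")
    d = np.asarray(differences, dtype=float)
    n_within = int(np.sum((d >= lower) & (d <= upper)))
    n_total = int(d.size)
    return n_within / n_total, n_within, n_total


def expected_time_saving(
    scores: ScoreTable, cfg: TimeModelConfig | None = None
) -> TimeSavingResult:
    """Expected per-case seconds saved per step and in total.

    Per-step saving = manual seconds x sum of saving fraction times score
    proportion; rounded to one decimal per step, then summed; the total
    subtracts the reading time.
    """
    cfg = cfg or TimeModelConfig()
    per_step: dict[str, float] = {}
    for step, props in scores.proportions.items():
        manual = cfg.manual_seconds[step]
        saved = manual * sum(cfg.saving_fraction[s] * p for s, p in enumerate(props))
        per_step[step] = _round_half_up(saved, 1)
    subtotal = _round_half_up(sum(per_step.values()), 1)
    total = _round_half_up(subtotal - cfg.reading_seconds, 1)
    return TimeSavingResult(per_step, subtotal, total)


def assisted_assessment_time(
    scores: ScoreTable, cfg: TimeModelConfig | None = None
) -> tuple[float, int]:
    """Expected per-case assessment time with assistance, and the percentage
    reduction relative to the fully manual time (rounded to whole percent)."""
    cfg = cfg or TimeModelConfig()
    saving = expected_time_saving(scores, cfg)
    assisted = _round_half_up(cfg.manual_total - saving.subtotal_seconds + cfg.reading_seconds, 1)
    reduction = int(_round_half_up((cfg.manual_total - assisted) / cfg.manual_total * 100.0))
    return assisted, reduction


def acceptance_rate(score_records: Sequence[int]) -> tuple[float, int, int, int]:
    """Fraction of cases with score <= 1 (no or minimal correction).

    Returns (fraction, whole-percent rounded half-up, n_acceptable, n_total).
    """
    if len(score_records) == 0:
        raise ValueError("acceptance rate undefined for an empty score list")
    if any(s not in (0, 1, 2) for s in score_records):
        raise ValueError("scores must be 0, 1 or 2")
    n_ok = sum(1 for s in score_records if s <= 1)
    n = len(score_records)
    frac = n_ok / n
    return frac, int(_round_half_up(frac * 100.0)), n_ok, n
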