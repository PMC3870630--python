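"""Segmentation and width-measurement metrics.

Pixel confusion metrics (sensitivity, specificity, accuracy) are computed
inside the field of view against a ground-truth mask.  Width performance is
reported as a success rate (fraction of profile points where a meaningful
width was obtained), the mean width over meaningful measurements, per-point
absolute errors, and a rounded-diameter frequency distribution.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import SpecError
from .image_model import PixelMask

__all__ = [
    "ConfusionMetrics",
    "WidthReport",
    "confusion_metrics",
    "width_statistics",
    "diameter_distribution",
]


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


@dataclass
class WidthReport:
    total: int
    meaningful: int
    success_rate: float  # percent
    mean_width: float | None
    errors: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def mean_abs_error(self) -> float | None:
        return float(np.mean(self.errors)) if self.errors.size else None


def confusion_metrics(
    predicted: PixelMask, truth: PixelMask, fov: PixelMask | None = None
) -> ConfusionMetrics:
    """Pixel confusion counts restricted to the field of view.

    Sensitivity is None (flagged undefined) when the truth holds no vessel
    pixels inside the FOV; likewise specificity without background pixels.
    """
    if predicted.shape != truth.shape:
        raise SpecError("predicted and truth masks must share a shape")
    if fov is None:
        fov_data = np.ones(truth.shape, dtype=bool)
    else:
        if fov.shape != truth.shape:
            raise SpecError("FOV mask must match the image shape")
        fov_data = fov.data
    p = predicted.data[fov_data]
    t = truth.data[fov_data]
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    n = tp + fp + fn + tn
    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=tp / (tp + fn) if (tp + fn) else None,
        specificity=tn / (tn + fp) if (tn + fp) else None,
        accuracy=(tp + tn) / n if n else float("nan"),
    )


def width_statistics(
    measured: list[float | None], truth_widths: list[float] | None = None
) -> WidthReport:
    """Success rate and width error statistics over aligned profile points.

    ``None`` entries mark failed (meaningless) measurements.  When truth
    widths are given, per-point absolute errors are computed over the
    meaningful measurements.
    """
    total = len(measured)
    ok = [(i, m) for i, m in enumerate(measured) if m is not None]
    meaningful = len(ok)
    if truth_widths is not None and len(truth_widths) != total:
        raise SpecError("measured and truth width lists must align")
    errors = (
        np.array([abs(m - truth_widths[i]) for i, m in ok])
        if truth_widths is not None
        else np.empty(0)
    )
    return WidthReport(
        total=total,
        meaningful=meaningful,
        success_rate=100.0 * meaningful / total if total else 0.0,
        mean_width=float(np.mean([m for _, m in ok])) if ok else None,
        errors=errors,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def diameter_distribution(widths) -> dict[int, float]:
    """Frequency of diameters after rounding half away from zero."""
    widths = list(widths)
    if any(w < 0 for w in widths):
        raise SpecError("widths must be non-negative")
    if not widths:
        return {}
    counts: dict[int, int] = {}
    for w in widths:
        b = _round_half_away(float(w))
        counts[b] = counts.get(b, 0) + 1
    n = len(widths)
    return {b: counts[b] / n for b in sorted(counts)}


def export_distribution_csv(dist: dict[int, float], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["diameter", "frequency"])
        for d, f in dist.items():
            writer.writerow([d, f"{f:.6f}"])
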