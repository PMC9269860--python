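"""Two-period calibration and direct proportional force estimation.

One iEMG channel drives one normalized joint-force output: the feature
series is divided by its maximum over the first two sine-tracking periods
(the calibration span), and the remaining periods are used exclusively for
evaluation.  Estimates are not clipped at 1 and receive no post-filtering
beyond the analysis window's inherent smoothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .features import FeatureSeries, ThresholdSpec, WindowSpec


@dataclass(frozen=True)
class CalibrationModel:
    """Normalization scale learned from the first two tracking periods."""

    scale: float
    algorithm: str
    window: WindowSpec
    threshold: ThresholdSpec | float | None
    repetition_boundaries: tuple
    segment_id: str = ""

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("calibration scale must be positive")

    def to_json(self, path) -> None:
        d = {
            "scale": self.scale,
            "algorithm": self.algorithm,
            "window_ms": self.window.width_ms,
            "increment_samples": self.window.increment_samples,
            "threshold": asdict(self.threshold) if isinstance(self.threshold, ThresholdSpec) else self.threshold,
            "repetition_boundaries": list(self.repetition_boundaries),
            "segment_id": self.segment_id,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


@dataclass
class ForceEstimate:
    """Normalized force estimate over the evaluation span (periods 3..R)."""

    values: np.ndarray
    sample_index: np.ndarray


def calibrate(series: FeatureSeries, repetition_boundaries, segment_id: str = "") -> CalibrationModel:
    """Scale = max of the feature series over tracking periods 1-2."""
    rb = np.asarray(repetition_boundaries, dtype=np.int64)
    if rb.size < 3:
        raise ValueError("need at least 2 complete repetitions to calibrate")
    mask = (series.sample_index >= rb[0]) & (series.sample_index < rb[2])
    if not mask.any():
        raise ValueError("no feature values inside the calibration span")
    scale = float(np.max(series.values[mask]))
    if scale <= 0:
        raise ValueError("feature silent during calibration (max <= 0)")
    return CalibrationModel(
        scale=scale,
        algorithm=series.algorithm,
        window=series.window,
        threshold=series.threshold,
        repetition_boundaries=tuple(int(v) for v in rb),
        segment_id=segment_id,
    )


def estimate_force(series: FeatureSeries, model: CalibrationModel) -> ForceEstimate:
    """Direct proportional estimate: series / scale over periods 3..R only."""
    if (
        series.algorithm != model.algorithm
        or series.window != model.window
        or not _thresholds_equal(series.threshold, model.threshold)
    ):
        raise ValueError("series configuration does not match the calibration model")
    rb = np.asarray(model.repetition_boundaries, dtype=np.int64)
    mask = (series.sample_index >= rb[2]) & (series.sample_index < rb[-1])
    values = np.clip(series.values[mask] / model.scale, 0.0, None)
    return ForceEstimate(values=values, sample_index=series.sample_index[mask])


def _thresholds_equal(a, b) -> bool:
    if a is None and b is None:
        return True
    return a == b
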