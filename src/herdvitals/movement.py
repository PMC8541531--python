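"""Abrupt-movement metrics from the tracked head centroid.

The head bounding box of each frame yields an x-y centroid series; the
one-minute recording is split into four contiguous temporal quartiles and
per-quartile centroid means/variances plus whole-video variances are the
exported movement features.  Large x variance means sideways head motion,
large y variance up-down motion.  Units are pixels (no metric calibration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .video import RoiTrack


@dataclass(frozen=True)
class CentroidSeries:
    """Per-frame head-box centre coordinates, pixels."""

    x: np.ndarray
    y: np.ndarray

    def __len__(self):
        return len(self.x)


@dataclass(frozen=True)
class MovementMetrics:
    """Quartile pattern statistics plus whole-video variances (pixels^2)."""

    q_mean_x: np.ndarray  # shape (4,)
    q_mean_y: np.ndarray
    q_var_x: np.ndarray
    q_var_y: np.ndarray
    var_x: float
    var_y: float

    def as_dict(self) -> dict:
        out = {}
        for q in range(4):
            out[f"q{q + 1}_mean_x"] = float(self.q_mean_x[q])
        for q in range(4):
            out[f"q{q + 1}_mean_y"] = float(self.q_mean_y[q])
        for q in range(4):
            out[f"q{q + 1}_var_x"] = float(self.q_var_x[q])
        for q in range(4):
            out[f"q{q + 1}_var_y"] = float(self.q_var_y[q])
        out["var_x"] = float(self.var_x)
        out["var_y"] = float(self.var_y)
        return out


def centroid_series(track: RoiTrack) -> CentroidSeries:
    """Box centres: x = x_min + width/2, y = y_min + height/2, per frame."""
    if len(track.boxes) == 0:
        raise ValueError("empty ROI track")
    b = np.asarray(track.boxes, dtype=float)
    return CentroidSeries(x=b[:, 0] + b[:, 2] / 2.0, y=b[:, 1] + b[:, 3] / 2.0)


def quartile_movement(series: CentroidSeries) -> MovementMetrics:
    """Four contiguous equal-length blocks (remainder to the last block).

    Population (divide-by-n) variances throughout.
    """
    n = len(series)
    if n < 8:
        raise ValueError(f"need at least 8 frames for quartile analysis, got {n}")
    block = n // 4
    bounds = [0, block, 2 * block, 3 * block, n]
    q_mean_x = np.empty(4)
    q_mean_y = np.empty(4)
    q_var_x = np.empty(4)
    q_var_y = np.empty(4)
    for q in range(4):
        xs = series.x[bounds[q] : bounds[q + 1]]
        ys = series.y[bounds[q] : bounds[q + 1]]
        q_mean_x[q] = xs.mean()
        q_mean_y[q] = ys.mean()
        q_var_x[q] = xs.var()
        q_var_y[q] = ys.var()
    return MovementMetrics(
        q_mean_x=q_mean_x,
        q_mean_y=q_mean_y,
        q_var_x=q_var_x,
        q_var_y=q_var_y,
        var_x=float(series.x.var()),
        var_y=float(series.y.var()),
    )


def movement_metrics(track: RoiTrack) -> MovementMetrics:
    """Convenience composition: head track -> centroid -> quartile metrics."""
    return quartile_movement(centroid_series(track))
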