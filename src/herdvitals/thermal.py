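"""Radiometric thermal-frame analysis: eye (face-maximum) temperature.

Thermal cameras with radiometric export produce one CSV matrix of calibrated
°C values per frame.  The eye region is the warmest part of a cow's face, so
the maximum temperature inside the tracked head ROI per frame, averaged over
the recording, is the eye-temperature estimate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .video import RoiTrack, _roi_slices

SANE_BAND_C = (-20.0, 60.0)


@dataclass(frozen=True)
class ThermalFrameSet:
    """Stack of radiometric frames (°C floats) with its own sampling rate."""

    frames: np.ndarray  # (n, h, w) float
    fps: float

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (n, h, w)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def write_csv_dir(self, directory, prefix: str = "thermal") -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, frame in enumerate(self.frames):
            p = directory / f"{prefix}_{i:06d}.csv"
            np.savetxt(p, frame, delimiter=",", fmt="%.4f")
            paths.append(p)
        return paths


@dataclass(frozen=True)
class EyeTemperature:
    per_frame_max: np.ndarray  # °C, one per frame
    mean_max: float
    sd_max: float


def _parse_matrix(path) -> np.ndarray:
    rows = []
    width = None
    with open(path, newline="") as fh:
        for row_idx, row in enumerate(csv.reader(fh)):
            if not row:
                continue
            try:
                values = [float(cell) for cell in row]
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric cell in {path}, row {row_idx}: {exc}"
                ) from None
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise ValueError(
                    f"ragged row in {path}: row {row_idx} has {len(values)} "
                    f"cells, expected {width}"
                )
            rows.append(values)
    if not rows:
        raise ValueError(f"empty radiometric file {path}")
    mat = np.asarray(rows, dtype=float)
    if np.any(np.isnan(mat)):
        raise ValueError(f"NaN cells in {path}")
    return mat


def read_radiometric_csv(paths, fps: float = 30.0, check_band: bool = True) -> ThermalFrameSet:
    """Read an ordered list of per-frame CSV matrices into a frame stack.

    Ragged rows, non-numeric cells and shape mismatches raise descriptive
    errors naming the offending file.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no radiometric files given")
    frames = []
    shape = None
    for p in paths:
        mat = _parse_matrix(p)
        if shape is None:
            shape = mat.shape
        elif mat.shape != shape:
            raise ValueError(
                f"shape mismatch: {p} is {mat.shape}, expected {shape}"
            )
        frames.append(mat)
    stack = np.stack(frames)
    if check_band:
        lo, hi = SANE_BAND_C
        if stack.min() < lo or stack.max() > hi:
            raise ValueError(
                f"temperatures outside the sane band {SANE_BAND_C} °C "
                f"(observed {stack.min():.1f}..{stack.max():.1f}); "
                "pass check_band=False to override"
            )
    return ThermalFrameSet(frames=stack, fps=fps)


def eye_temperature(frames: ThermalFrameSet, roi: RoiTrack) -> EyeTemperature:
    """Per-frame maximum °C inside the ROI, then its temporal mean and sd.

    A single head track row may be reused across all frames (static crush
    position); otherwise the track must align 1:1 with the stack.
    """
    n, h, w = frames.frames.shape
    boxes = roi.boxes
    if len(boxes) == 1:
        boxes = np.repeat(boxes, n, axis=0)
    if len(boxes) != n:
        raise ValueError(f"track length {len(roi)} does not match {n} frames")
    per_max = np.empty(n)
    for t in range(n):
        ys, xs = _roi_slices(boxes[t], h, w)
        per_max[t] = frames.frames[t, ys, xs].max()
    return EyeTemperature(
        per_frame_max=per_max,
        mean_max=float(per_max.mean()),
        sd_max=float(per_max.std(ddof=1)) if n > 1 else 0.0,
    )
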