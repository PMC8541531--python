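"""Video-based vitals: heart rate and respiration rate from ROI colour traces.

Heart rate follows the remote-photoplethysmography (rPPG) principle: cardiac
pulsation modulates the light reflected by perfused tissue, so the mean green
channel of an eye-region ROI carries a weak periodic component at the cardiac
frequency.  Respiration is read the same way from the nose region using the
CIELab a* (green-to-red opponent) channel.  Both traces are detrended,
band-passed to the physiologically plausible band, and the rate is obtained by
peak counting ("peak analysis"); an FFT-argmax estimate is kept as a quality
cross-check.

Default bands reflect bovine physiology: 40-150 BPM cardiac, 9-72 BrPM
respiratory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import signal as sps
from skimage import color as skcolor

HR_BAND_HZ = (0.67, 2.5)  # 40-150 BPM
RR_BAND_HZ = (0.15, 1.2)  # 9-72 BrPM
HR_MIN_SEPARATION_S = 0.4
RR_MIN_SEPARATION_S = 0.8
PEAK_PROMINENCE_SD = 0.25


@dataclass(frozen=True)
class FrameSequence:
    """Ordered stack of 8-bit RGB frames with a common sampling rate."""

    frames: np.ndarray  # (n, h, w, 3) uint8
    fps: float

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (n, h, w, 3)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def write_png_dir(self, directory) -> None:
        """Write frames as zero-padded PNGs (frame_000001.png, ...)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(self.frames):
            iio.imwrite(directory / f"frame_{i:06d}.png", frame)

    @classmethod
    def read_png_dir(cls, directory, fps: float) -> "FrameSequence":
        paths = sorted(Path(directory).glob("frame_*.png"))
        if not paths:
            raise FileNotFoundError(f"no frame_*.png files in {directory}")
        frames = np.stack([iio.imread(p) for p in paths])
        return cls(frames=frames, fps=fps)


@dataclass(frozen=True)
class RoiTrack:
    """Per-frame axis-aligned bounding box for one region (eye, nose, head).

    Boxes are (x_min, y_min, width, height) in pixels, half-open, 0-based.
    """

    region: str
    boxes: np.ndarray  # (n, 4) float

    def __post_init__(self):
        b = np.asarray(self.boxes, dtype=float)
        if b.ndim != 2 or b.shape[1] != 4:
            raise ValueError("boxes must have shape (n, 4)")
        if len(b) and (np.any(b[:, 2] <= 0) or np.any(b[:, 3] <= 0)):
            raise ValueError("box width and height must be positive")
        object.__setattr__(self, "boxes", b)

    def __len__(self):
        return len(self.boxes)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.boxes, columns=["x_min", "y_min", "width", "height"])
        df.insert(0, "region", self.region)
        df.insert(0, "frame", np.arange(len(df)))
        return df


def write_tracks_csv(path, tracks: list[RoiTrack]) -> None:
    pd.concat([t.to_frame() for t in tracks], ignore_index=True).to_csv(path, index=False)


def read_tracks_csv(path) -> dict[str, RoiTrack]:
    """Load all region tracks from a CSV (frame, region, x_min, y_min, width, height)."""
    df = pd.read_csv(path)
    required = {"frame", "region", "x_min", "y_min", "width", "height"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track file {path} missing columns {sorted(missing)}")
    out = {}
    for region, grp in df.groupby("region"):
        grp = grp.sort_values("frame")
        out[region] = RoiTrack(
            region=str(region),
            boxes=grp[["x_min", "y_min", "width", "height"]].to_numpy(float),
        )
    return out


@dataclass(frozen=True)
class SignalTrace:
    """One scalar channel-mean per frame."""

    values: np.ndarray
    fps: float
    channel: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("trace contains non-finite values")
        object.__setattr__(self, "values", v)

    def __len__(self):
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fps


@dataclass(frozen=True)
class VitalsResult:
    """Rate estimate from peak analysis.

    ``rate`` is NaN (with quality 0) when fewer than two peaks are found —
    an undefined rate is flagged, never silently reported as 0.
    """

    rate: float  # BPM or BrPM; NaN if undefined
    amplitude: float  # mean peak-to-preceding-trough, channel units
    n_peaks: int
    quality: float  # fraction of inter-peak intervals within +-25% of median
    spectral_rate: float = float("nan")  # FFT-argmax cross-check

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rate)


def _roi_slices(box, h, w):
    x0, y0, bw, bh = box
    x0i, y0i = int(round(x0)), int(round(y0))
    x1i, y1i = int(round(x0 + bw)), int(round(y0 + bh))
    if x0i < 0 or y0i < 0 or x1i > w or y1i > h or x1i <= x0i or y1i <= y0i:
        raise ValueError(f"ROI box {box} outside frame bounds {h}x{w} or empty")
    return slice(y0i, y1i), slice(x0i, x1i)


def extract_channel_trace(seq: FrameSequence, roi: RoiTrack, channel: str) -> SignalTrace:
    """Mean of the requested channel over the ROI, per frame.

    channel: ``green_rgb`` (raw 8-bit green mean) or ``a_cielab`` (per-pixel
    sRGB->CIELab conversion under D65, then the a* mean).  Means are computed
    in float before any rounding.
    """
    if channel not in ("green_rgb", "a_cielab"):
        raise ValueError(f"unknown channel {channel!r}")
    if len(roi) != seq.n_frames:
        raise ValueError(
            f"track length {len(roi)} does not match frame count {seq.n_frames}"
        )
    n, h, w, _ = seq.frames.shape
    values = np.empty(n)
    for t in range(n):
        ys, xs = _roi_slices(roi.boxes[t], h, w)
        patch = seq.frames[t, ys, xs]
        if channel == "green_rgb":
            values[t] = patch[..., 1].astype(float).mean()
        else:
            lab = skcolor.rgb2lab(patch.astype(float) / 255.0)
            values[t] = lab[..., 1].mean()
    return SignalTrace(values=values, fps=seq.fps, channel=channel)


def detrend_and_filter(trace: SignalTrace, band_hz: tuple[float, float]) -> SignalTrace:
    """Moving-average detrend (window 1/low s) then zero-phase band-pass."""
    low, high = band_hz
    nyq = trace.fps / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band {band_hz} outside (0, Nyquist={nyq}) or unordered")
    x = trace.values
    win = max(3, int(round(trace.fps / low)))
    win = min(win, len(x))
    kernel = np.ones(win) / win
    # reflect-padded moving average avoids edge droop on short traces
    padded = np.pad(x, (win // 2, win - 1 - win // 2), mode="reflect")
    trend = np.convolve(padded, kernel, mode="valid")
    detrended = x - trend
    sos = sps.butter(3, [low / nyq, high / nyq], btype="bandpass", output="sos")
    filtered = sps.sosfiltfilt(sos, detrended)
    return SignalTrace(values=filtered, fps=trace.fps, channel=trace.channel)


def spectral_rate(trace: SignalTrace) -> float:
    """FFT-argmax frequency x 60 — the quality cross-check, not the estimator."""
    x = trace.values - trace.values.mean()
    if np.allclose(x, 0):
        return float("nan")
    freqs = np.fft.rfftfreq(len(x), d=1.0 / trace.fps)
    spectrum = np.abs(np.fft.rfft(x))
    spectrum[0] = 0.0
    return float(freqs[np.argmax(spectrum)] * 60.0)


def peak_rate(trace: SignalTrace, min_separation_s: float) -> VitalsResult:
    """Peak-analysis rate: count prominent local maxima, convert to per-minute.

    Peaks must exceed a prominence of ``PEAK_PROMINENCE_SD`` x trace sd and be
    separated by at least ``min_separation_s``.  Amplitude is the mean
    peak-minus-preceding-trough excursion.
    """
    if min_separation_s <= 0:
        raise ValueError("min_separation_s must be positive")
    x = trace.values
    sd = x.std()
    sr = spectral_rate(trace)
    if sd == 0:
        return VitalsResult(float("nan"), 0.0, 0, 0.0, sr)
    distance = max(1, int(round(min_separation_s * trace.fps)))
    peaks, _ = sps.find_peaks(x, prominence=PEAK_PROMINENCE_SD * sd, distance=distance)
    if len(peaks) < 2:
        return VitalsResult(float("nan"), 0.0, int(len(peaks)), 0.0, sr)
    rate = len(peaks) / trace.duration_s * 60.0
    # preceding trough: minimum between consecutive peaks (and before first peak)
    amplitudes = []
    prev = 0
    for p in peaks:
        trough = x[prev:p].min() if p > prev else x[p]
        amplitudes.append(x[p] - trough)
        prev = p
    intervals = np.diff(peaks) / trace.fps
    med = np.median(intervals)
    quality = float(np.mean(np.abs(intervals - med) <= 0.25 * med))
    return VitalsResult(
        rate=float(rate),
        amplitude=float(np.mean(amplitudes)),
        n_peaks=int(len(peaks)),
        quality=quality,
        spectral_rate=sr,
    )


def estimate_heart_rate(seq: FrameSequence, eye_roi: RoiTrack) -> VitalsResult:
    """Eye-ROI green trace -> detrend/band-pass (40-150 BPM) -> peak rate."""
    trace = extract_channel_trace(seq, eye_roi, "green_rgb")
    filtered = detrend_and_filter(trace, HR_BAND_HZ)
    return peak_rate(filtered, HR_MIN_SEPARATION_S)


def estimate_respiration_rate(seq: FrameSequence, nose_roi: RoiTrack) -> VitalsResult:
    """Nose-ROI a* trace -> detrend/band-pass (9-72 BrPM) -> peak rate."""
    trace = extract_channel_trace(seq, nose_roi, "a_cielab")
    filtered = detrend_and_filter(trace, RR_BAND_HZ)
    return peak_rate(filtered, RR_MIN_SEPARATION_S)
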