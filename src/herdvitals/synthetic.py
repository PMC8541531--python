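"""Synthetic farm recordings with known ground truth.

Every downstream stage of the pipeline is exercised against data from this
module: RGB frame stacks with a cardiac-frequency green-channel modulation in
the eye region and a respiratory-frequency red-green modulation in the nose
region, radiometric thermal stacks with a known hottest eye pixel, a winter
weather series at 15-min cadence, and a herd table whose five targets are
documented smooth functions of the features plus Gaussian noise (so an oracle
correlation between noise-free and noisy targets is computable).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import movement as mv
from . import weather as wx
from .schema import FEATURE_COLUMNS, TARGET_COLUMNS
from .thermal import ThermalFrameSet
from .video import HR_BAND_HZ, RR_BAND_HZ, FrameSequence, RoiTrack

# ---------------------------------------------------------------------------
# RGB scene generation


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Parameters of one simulated 1-min crush recording.

    Amplitudes are injected before 8-bit quantization; with the default ROI
    sizes the eye patch covers >= 400 pixels so sub-level amplitudes remain
    recoverable from the ROI mean.
    """

    duration_s: float = 60.0
    fps: float = 30.0
    frame_size: tuple[int, int] = (360, 640)  # (h, w); scaled stand-in for 4K
    hr_bpm: float = 78.0
    rr_brpm: float = 30.0
    pulse_amplitude: float = 2.0  # green-channel 8-bit units
    resp_amplitude: float = 3.0  # red/green-balance 8-bit units
    noise_sd: float = 1.0  # per-pixel Gaussian sd
    motion_model: str = "static"  # static | linear_drift | random_walk
    motion_step: float = 0.3  # px/frame drift velocity or walk step sd
    seed: int = 0

    def __post_init__(self):
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration_s must be positive")
        if self.hr_bpm <= 0 or self.rr_brpm <= 0:
            raise ValueError("rates must be positive")
        if self.hr_bpm / 60.0 >= self.fps / 2.0:
            raise ValueError(
                f"hr_bpm={self.hr_bpm} violates Nyquist at fps={self.fps}"
            )
        if self.rr_brpm / 60.0 >= self.fps / 2.0:
            raise ValueError(
                f"rr_brpm={self.rr_brpm} violates Nyquist at fps={self.fps}"
            )
        hr_lo, hr_hi = (HR_BAND_HZ[0] * 60.0, HR_BAND_HZ[1] * 60.0)
        if not (hr_lo <= self.hr_bpm <= hr_hi):
            raise ValueError(
                f"hr_bpm={self.hr_bpm} outside the recoverable cardiac band "
                f"{hr_lo:.0f}-{hr_hi:.0f} BPM"
            )
        rr_lo, rr_hi = (RR_BAND_HZ[0] * 60.0, RR_BAND_HZ[1] * 60.0)
        if not (rr_lo <= self.rr_brpm <= rr_hi):
            raise ValueError(
                f"rr_brpm={self.rr_brpm} outside the recoverable respiratory "
                f"band {rr_lo:.0f}-{rr_hi:.0f} BrPM"
            )
        if self.motion_model not in ("static", "linear_drift", "random_walk"):
            raise ValueError(f"unknown motion_model {self.motion_model!r}")


@dataclass(frozen=True)
class SceneGroundTruth:
    hr_bpm: float
    rr_brpm: float
    centroid_x: np.ndarray  # head-box centre per frame
    centroid_y: np.ndarray
    eye_base_green: float
    nose_base_red: float
    nose_base_green: float


# base colours (R, G, B), 8-bit
_BG_COLOR = (120.0, 120.0, 120.0)
_HEAD_COLOR = (100.0, 95.0, 90.0)
_EYE_COLOR = (105.0, 140.0, 95.0)
_NOSE_COLOR = (130.0, 120.0, 110.0)


def _head_geometry(h: int, w: int):
    """Head box and eye/nose offsets (fractions of the frame)."""
    head_h, head_w = int(0.5 * h), int(0.5 * w)
    eye_h, eye_w = max(10, int(0.17 * h)), max(10, int(0.15 * w))
    nose_h, nose_w = max(10, int(0.20 * h)), max(10, int(0.19 * w))
    eye_off = (int(0.12 * head_w), int(0.15 * head_h))  # (dx, dy) inside head
    nose_off = (int(0.40 * head_w), int(0.60 * head_h))
    return (head_h, head_w), (eye_h, eye_w), (nose_h, nose_w), eye_off, nose_off


def _motion_path(spec: SyntheticSceneSpec, n: int, start_xy, bounds, rng):
    x0, y0 = start_xy
    if spec.motion_model == "static":
        xs = np.full(n, float(x0))
        ys = np.full(n, float(y0))
    elif spec.motion_model == "linear_drift":
        t = np.arange(n, dtype=float)
        xs = x0 + spec.motion_step * t
        ys = y0 + 0.4 * spec.motion_step * t
    else:  # random_walk
        xs = x0 + np.cumsum(rng.normal(0.0, spec.motion_step, n))
        ys = y0 + np.cumsum(rng.normal(0.0, spec.motion_step, n))
    (x_lo, x_hi), (y_lo, y_hi) = bounds
    return np.clip(xs, x_lo, x_hi), np.clip(ys, y_lo, y_hi)


def _paint_rect(frame, x0, y0, bw, bh, color):
    x0i, y0i = int(round(x0)), int(round(y0))
    frame[y0i : y0i + bh, x0i : x0i + bw] = color


def gen_rgb_sequence(
    spec: SyntheticSceneSpec,
) -> tuple[FrameSequence, RoiTrack, RoiTrack, RoiTrack, SceneGroundTruth]:
    """Simulate one RGB recording with embedded cardiac/respiratory signals.

    Returns the frame stack, eye/nose/head ROI tracks and the ground truth.
    The eye-patch green channel oscillates at hr_bpm/60 Hz, the nose patch's
    red-green balance at rr_brpm/60 Hz; the head box follows the motion model.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_size
    n = int(round(spec.duration_s * spec.fps))
    if n <= 0:
        raise ValueError("frame count must be positive")
    (head_h, head_w), (eye_h, eye_w), (nose_h, nose_w), eye_off, nose_off = (
        _head_geometry(h, w)
    )
    start = ((w - head_w) / 2.0, (h - head_h) / 2.0)  # head x_min, y_min
    bounds = ((0.0, float(w - head_w)), (0.0, float(h - head_h)))
    head_x, head_y = _motion_path(spec, n, start, bounds, rng)

    t = np.arange(n) / spec.fps
    pulse = spec.pulse_amplitude * np.sin(2 * np.pi * (spec.hr_bpm / 60.0) * t)
    resp = spec.resp_amplitude * np.sin(2 * np.pi * (spec.rr_brpm / 60.0) * t)

    frames = np.empty((n, h, w, 3), dtype=np.uint8)
    base = np.empty((h, w, 3), dtype=float)
    for i in range(n):
        base[:] = _BG_COLOR
        _paint_rect(base, head_x[i], head_y[i], head_w, head_h, _HEAD_COLOR)
        ex, ey = head_x[i] + eye_off[0], head_y[i] + eye_off[1]
        nx, ny = head_x[i] + nose_off[0], head_y[i] + nose_off[1]
        eye_color = (_EYE_COLOR[0], _EYE_COLOR[1] + pulse[i], _EYE_COLOR[2])
        nose_color = (_NOSE_COLOR[0] + resp[i], _NOSE_COLOR[1] - resp[i], _NOSE_COLOR[2])
        _paint_rect(base, ex, ey, eye_w, eye_h, eye_color)
        _paint_rect(base, nx, ny, nose_w, nose_h, nose_color)
        noisy = base if spec.noise_sd == 0 else base + rng.normal(0, spec.noise_sd, base.shape)
        frames[i] = np.clip(np.round(noisy), 0, 255).astype(np.uint8)

    seq = FrameSequence(frames=frames, fps=spec.fps)
    head_track = RoiTrack(
        "head", np.column_stack([head_x, head_y, np.full(n, head_w), np.full(n, head_h)])
    )
    # eye/nose boxes use the same rounding as the painter so the extraction
    # window covers exactly the painted patch
    eye_x = np.round(head_x) + eye_off[0]
    eye_y = np.round(head_y) + eye_off[1]
    nose_x = np.round(head_x) + nose_off[0]
    nose_y = np.round(head_y) + nose_off[1]
    eye_track = RoiTrack(
        "eye", np.column_stack([eye_x, eye_y, np.full(n, eye_w), np.full(n, eye_h)])
    )
    nose_track = RoiTrack(
        "nose", np.column_stack([nose_x, nose_y, np.full(n, nose_w), np.full(n, nose_h)])
    )
    truth = SceneGroundTruth(
        hr_bpm=spec.hr_bpm,
        rr_brpm=spec.rr_brpm,
        centroid_x=head_x + head_w / 2.0,
        centroid_y=head_y + head_h / 2.0,
        eye_base_green=_EYE_COLOR[1],
        nose_base_red=_NOSE_COLOR[0],
        nose_base_green=_NOSE_COLOR[1],
    )
    return seq, eye_track, nose_track, head_track, truth


# ---------------------------------------------------------------------------
# Thermal generation


def gen_thermal_sequence(
    duration_s: float = 10.0,
    fps_thermal: float = 8.0,
    frame_size: tuple[int, int] = (120, 160),  # scaled stand-in for 514x652
    eye_temp_c: float = 36.5,
    background_c: float = 12.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[ThermalFrameSet, RoiTrack]:
    """Radiometric stack with one compact hot eye region inside the head ROI.

    The per-frame maximum inside the ROI equals eye_temp_c + N(0, noise_sd):
    the hottest pixel carries the draw directly while the surrounding warm
    blob stays strictly below it.
    """
    if eye_temp_c <= background_c:
        raise ValueError("eye_temp_c must exceed background_c")
    n = int(round(duration_s * fps_thermal))
    if n <= 0:
        raise ValueError("frame count must be positive")
    rng = np.random.default_rng(seed)
    h, w = frame_size
    head_h, head_w = int(0.6 * h), int(0.6 * w)
    head_x, head_y = (w - head_w) // 2, (h - head_h) // 2
    cy, cx = head_y + head_h // 3, head_x + head_w // 3  # hottest eye pixel
    yy, xx = np.mgrid[0:h, 0:w]
    sigma = max(2.0, 0.04 * min(h, w))
    blob_shape = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    # blob plateau sits safely below the injected peak value
    blob_peak = eye_temp_c - max(0.5, 4.0 * noise_sd)
    blob = (blob_peak - background_c) * blob_shape

    frames = np.empty((n, h, w), dtype=float)
    for i in range(n):
        frame = background_c + blob
        if noise_sd > 0:
            frame = frame + rng.normal(0, noise_sd, frame.shape)
        frame[cy, cx] = eye_temp_c + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
        frames[i] = frame
    stack = ThermalFrameSet(frames=frames, fps=fps_thermal)
    head_track = RoiTrack(
        "head", np.array([[head_x, head_y, head_w, head_h]] * n, dtype=float)
    )
    return stack, head_track


# ---------------------------------------------------------------------------
# Weather generation


@dataclass(frozen=True)
class WeatherProfile:
    """AR(1)-smoothed series centred on winter farm conditions."""

    T_mean: float = 11.3
    T_sd: float = 1.0
    RH_mean: float = 81.0
    RH_sd: float = 4.0
    wind_mean: float = 11.0
    wind_sd: float = 3.0
    wind_dir_mean: float = 225.0
    wind_dir_sd: float = 25.0
    pressure_mean: float = 1013.25
    pressure_sd: float = 4.0
    ar_coef: float = 0.9


def _ar1(rng, n, mean, sd, phi):
    innov_sd = sd * np.sqrt(1 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + rng.normal(0, innov_sd)
    return mean + x


def gen_weather_series(
    start,
    end,
    cadence_min: int = 15,
    profile: WeatherProfile | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Station-style weather table (timestamp, T, RH, wind, pressure)."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start >= end:
        raise ValueError("start must precede end")
    profile = profile or WeatherProfile()
    stamps = pd.date_range(start, end, freq=f"{cadence_min}min")
    n = len(stamps)
    rng = np.random.default_rng(seed)
    phi = profile.ar_coef
    df = pd.DataFrame(
        {
            "timestamp": stamps,
            "T": _ar1(rng, n, profile.T_mean, profile.T_sd, phi),
            "RH": np.clip(
                _ar1(rng, n, profile.RH_mean, profile.RH_sd, phi), 1.0, 100.0
            ),
            "wind_speed": np.maximum(
                _ar1(rng, n, profile.wind_mean, profile.wind_sd, phi), 0.0
            ),
            "wind_dir": np.mod(
                _ar1(rng, n, profile.wind_dir_mean, profile.wind_dir_sd, phi), 360.0
            ),
            "pressure": _ar1(rng, n, profile.pressure_mean, profile.pressure_sd, phi),
        }
    )
    return df


# ---------------------------------------------------------------------------
# Herd dataset generation


@dataclass(frozen=True)
class HerdSpec:
    """Conditions for one synthetic herd draw.

    Ages follow the observed winter-herd age distribution (2-11 years);
    target noise is calibrated so the oracle correlation between noise-free
    and noisy targets is ``oracle_r`` unless explicit per-target sds are
    given in ``noise_sd_targets``.
    """

    n_cows: int = 150
    oracle_r: float = 0.96
    noise_sd_targets: dict | None = None
    seed: int = 0
    weather_profile: WeatherProfile = field(default_factory=WeatherProfile)
    n_motion_frames: int = 1800  # 60 s at 30 fps

    def __post_init__(self):
        if self.n_cows < 2:
            raise ValueError("n_cows must be at least 2")
        if self.noise_sd_targets is not None and any(
            v < 0 for v in self.noise_sd_targets.values()
        ):
            raise ValueError("noise sds must be non-negative")
        if not (0 < self.oracle_r <= 1):
            raise ValueError("oracle_r must be in (0, 1]")


# empirical herd age mix (years 2..11)
_AGE_YEARS = np.arange(2, 12)
_AGE_WEIGHTS = np.array([42, 46, 63, 19, 38, 10, 14, 24, 23, 3], dtype=float)
_AGE_WEIGHTS /= _AGE_WEIGHTS.sum()


_REVERSION = 0.02  # per-frame pull toward the stance position


def _mean_reverting_walk(rng, n, home, step_sd):
    # AR(1) around home: x_i = home + (1 - theta) (x_{i-1} - home) + step_i
    from scipy.signal import lfilter

    steps = rng.normal(0, step_sd, n)
    return home + lfilter([1.0], [1.0, -(1.0 - _REVERSION)], steps)


def _target_functions(f: pd.DataFrame) -> pd.DataFrame:
    """Noise-free targets as documented smooth functions of <= 4 features.

    Mildly nonlinear (log1p terms) so a nonlinear regressor has an edge over
    a straight line; values stay within farm-plausible ranges.
    """
    thi9 = f["THI9"]
    clean = pd.DataFrame(index=f.index)
    clean["eye_temp_c"] = (
        35.2
        + 0.030 * (f["hr_bpm"] - 80.0)
        + 0.020 * (f["rr_brpm"] - 34.0)
        - 0.50 * np.log1p(f["wind_speed"])
    )
    clean["milk_kg_day"] = 24.0 + 0.15 * (thi9 - 43.0) - 0.8 * np.log1p(f["var_y"])
    clean["milk_kg_milking"] = (
        13.0
        + 0.08 * (thi9 - 43.0)
        - 0.45 * np.log1p(f["var_y"])
        + 0.02 * (f["hr_bpm"] - 80.0)
    )
    clean["fat_pct"] = (
        4.1
        + 0.012 * (f["hr_bpm"] - 80.0)
        - 0.10 * np.log1p(f["var_x"])
        + 0.03 * (f["T"] - 12.0)
    )
    clean["protein_pct"] = (
        3.6
        + 0.010 * (f["rr_brpm"] - 34.0)
        + 0.020 * (thi9 - 43.0)
        - 0.05 * np.log1p(f["var_x"])
    )
    return clean[TARGET_COLUMNS]


@dataclass
class HerdDataset:
    features: pd.DataFrame  # n x 37
    targets: pd.DataFrame  # n x 5 (noisy)
    targets_clean: pd.DataFrame  # n x 5 (noise-free ground truth)
    meta: pd.DataFrame  # cow_id, age, timestamp
    noise_sd: pd.Series  # per-target sd actually applied
    oracle_r: pd.Series  # realized corr(clean, noisy) per target


def gen_herd_dataset(spec: HerdSpec) -> HerdDataset:
    """Draw one herd of recordings with features, targets and ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cows

    ages = rng.choice(_AGE_YEARS, size=n, p=_AGE_WEIGHTS)
    # four winter recording days, 9:00-16:00
    days = pd.to_datetime(
        ["2021-07-14", "2021-07-15", "2021-08-04", "2021-08-05"]
    )
    day_idx = rng.integers(0, len(days), n)
    seconds = rng.uniform(9 * 3600, 16 * 3600, n).astype(int)
    stamps = pd.Series(
        [days[d] + pd.Timedelta(seconds=int(s)) for d, s in zip(day_idx, seconds)]
    )

    # one weather series covering all four days
    weather_frames = []
    for i, day in enumerate(days):
        series = gen_weather_series(
            day + pd.Timedelta(hours=8),
            day + pd.Timedelta(hours=17),
            profile=spec.weather_profile,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        weather_frames.append(series)
    weather = pd.concat(weather_frames, ignore_index=True)
    derived = wx.derive_frame(weather)

    rows = []
    for i in range(n):
        row = {}
        row["hr_bpm"] = float(np.clip(rng.normal(80, 8), 60, 110))
        row["hr_amplitude"] = float(rng.lognormal(np.log(2.0), 0.3))
        row["rr_brpm"] = float(np.clip(rng.normal(34, 6), 20, 60))
        row["rr_amplitude"] = float(rng.lognormal(np.log(3.0), 0.3))
        # head-centroid motion: mean-reverting walk around a per-cow stance
        # position (the crush constrains the head near a home position).
        # The step-size spread keeps log1p(path variance) within ~2
        # natural-log units so the variance-driven target terms stay mildly
        # nonlinear.
        step_x = rng.lognormal(np.log(0.8), 0.35)
        step_y = rng.lognormal(np.log(0.8), 0.35)
        home_x = 320.0 + rng.normal(0, 15.0)
        home_y = 180.0 + rng.normal(0, 10.0)
        cs = mv.CentroidSeries(
            x=_mean_reverting_walk(rng, spec.n_motion_frames, home_x, step_x),
            y=_mean_reverting_walk(rng, spec.n_motion_frames, home_y, step_y),
        )
        row.update(mv.quartile_movement(cs).as_dict())
        rec = wx.match_weather(stamps.iloc[i], derived)
        for col in ["T", "RH", "wind_speed", "wind_dir", "Tdp", "Twet"]:
            row[col] = float(rec[col])
        for key in wx.THI_KEYS:
            row[key] = float(rec[key])
        rows.append(row)

    features = pd.DataFrame(rows)[FEATURE_COLUMNS]
    features.index.name = "recording_id"
    clean = _target_functions(features)

    if spec.noise_sd_targets is not None:
        sds = pd.Series(
            {c: float(spec.noise_sd_targets.get(c, 0.0)) for c in TARGET_COLUMNS}
        )
    else:
        # sd chosen so E[corr(clean, clean + noise)] = oracle_r
        ratio = np.sqrt(1.0 / spec.oracle_r**2 - 1.0)
        sds = clean.std(ddof=0) * ratio
    noise = pd.DataFrame(
        rng.normal(0.0, 1.0, (n, len(TARGET_COLUMNS))),
        columns=TARGET_COLUMNS,
        index=clean.index,
    ).mul(sds, axis=1)
    targets = clean + noise
    # percentages are physically bounded
    targets["fat_pct"] = targets["fat_pct"].clip(0.0, 100.0)
    targets["protein_pct"] = targets["protein_pct"].clip(0.0, 100.0)

    realized_r = pd.Series(
        {
            c: (
                float(np.corrcoef(clean[c], targets[c])[0, 1])
                if clean[c].std() > 0
                else 1.0
            )
            for c in TARGET_COLUMNS
        }
    )
    meta = pd.DataFrame(
        {"cow_id": np.arange(n), "age": ages, "timestamp": stamps.to_numpy()}
    )
    meta.index.name = "recording_id"
    return HerdDataset(
        features=features,
        targets=targets,
        targets_clean=clean,
        meta=meta,
        noise_sd=sds,
        oracle_r=realized_r,
    )
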