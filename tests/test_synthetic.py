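"""Generator ground-truth and determinism checks."""

import numpy as np
import pandas as pd
import pytest

from herdvitals.synthetic import (
    HerdSpec,
    SyntheticSceneSpec,
    WeatherProfile,
    gen_herd_dataset,
    gen_rgb_sequence,
    gen_thermal_sequence,
    gen_weather_series,
)
from herdvitals.video import extract_channel_trace


def _tiny_spec(**kw):
    base = dict(duration_s=3.0, fps=30.0, frame_size=(120, 160), seed=1)
    base.update(kw)
    return SyntheticSceneSpec(**base)


class TestRgbScene:
    def test_identical_seed_gives_bit_identical_frames(self):
        a = gen_rgb_sequence(_tiny_spec(hr_bpm=78, rr_brpm=30))[0]
        b = gen_rgb_sequence(_tiny_spec(hr_bpm=78, rr_brpm=30))[0]
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_noise_free_eye_green_matches_injected_sinusoid(self):
        spec = _tiny_spec(noise_sd=0.0, pulse_amplitude=2.0, hr_bpm=78.0)
        seq, eye, _, _, truth = gen_rgb_sequence(spec)
        trace = extract_channel_trace(seq, eye, "green_rgb")
        t = np.arange(seq.n_frames) / spec.fps
        expected = truth.eye_base_green + 2.0 * np.sin(2 * np.pi * (78 / 60) * t)
        assert np.max(np.abs(trace.values - expected)) <= 0.5  # quantization

    def test_static_motion_keeps_centroid_constant(self):
        _, _, _, head, truth = gen_rgb_sequence(_tiny_spec(motion_model="static"))
        assert np.ptp(truth.centroid_x) == 0
        assert np.ptp(truth.centroid_y) == 0
        assert np.ptp(head.boxes[:, 0]) == 0

    def test_linear_drift_tracks_ground_truth_path(self):
        from herdvitals.movement import centroid_series

        _, _, _, head, truth = gen_rgb_sequence(
            _tiny_spec(motion_model="linear_drift", motion_step=0.2)
        )
        series = centroid_series(head)
        np.testing.assert_allclose(series.x, truth.centroid_x)
        np.testing.assert_allclose(series.y, truth.centroid_y)

    @pytest.mark.parametrize(
        "kw",
        [
            {"hr_bpm": 200.0},  # above the cardiac band
            {"hr_bpm": 20.0},  # below the cardiac band
            {"rr_brpm": 100.0},  # above the respiratory band
            {"fps": 2.0, "hr_bpm": 78.0},  # Nyquist violation
        ],
    )
    def test_out_of_band_or_nyquist_rejected(self, kw):
        with pytest.raises(ValueError):
            _tiny_spec(**kw)


class TestThermalScene:
    def test_noise_free_max_equals_eye_temperature(self):
        stack, head = gen_thermal_sequence(
            duration_s=2, fps_thermal=4, noise_sd=0.0, eye_temp_c=36.5,
            background_c=12.0,
        )
        x0, y0, w, h = head.boxes[0].astype(int)
        roi = stack.frames[:, y0 : y0 + h, x0 : x0 + w]
        np.testing.assert_allclose(roi.max(axis=(1, 2)), 36.5)

    def test_frame_dimensions_as_requested(self):
        stack, _ = gen_thermal_sequence(duration_s=1, fps_thermal=3, frame_size=(120, 160))
        assert stack.frames.shape[1:] == (120, 160)

    def test_fixed_seed_reproduces_frames(self):
        a, _ = gen_thermal_sequence(seed=5, duration_s=1, fps_thermal=4)
        b, _ = gen_thermal_sequence(seed=5, duration_s=1, fps_thermal=4)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_inverted_contrast_rejected(self):
        with pytest.raises(ValueError):
            gen_thermal_sequence(eye_temp_c=10.0, background_c=20.0)


class TestWeatherSeries:
    def test_record_count_over_seven_hours(self):
        df = gen_weather_series("2021-07-14 09:00", "2021-07-14 16:00")
        assert len(df) == 29

    def test_means_near_profile_centers(self):
        profile = WeatherProfile(T_mean=11.3, RH_mean=81.0)
        df = gen_weather_series(
            "2021-07-14 00:00", "2021-07-20 00:00", profile=profile, seed=3
        )
        assert abs(df["T"].mean() - 11.3) <= profile.T_sd
        assert abs(df["RH"].mean() - 81.0) <= profile.RH_sd

    def test_physical_bounds(self):
        df = gen_weather_series("2021-07-14 00:00", "2021-07-16 00:00", seed=9)
        assert (df["RH"] <= 100).all() and (df["RH"] > 0).all()
        assert (df["wind_speed"] >= 0).all()
        assert ((df["wind_dir"] >= 0) & (df["wind_dir"] < 360)).all()

    def test_start_after_end_rejected(self):
        with pytest.raises(ValueError):
            gen_weather_series("2021-07-15", "2021-07-14")


class TestHerdDataset:
    def test_zero_noise_gives_perfect_oracle(self):
        sds = {c: 0.0 for c in ["eye_temp_c", "milk_kg_day", "milk_kg_milking",
                                "fat_pct", "protein_pct"]}
        ds = gen_herd_dataset(HerdSpec(n_cows=30, noise_sd_targets=sds, seed=2))
        assert (ds.oracle_r >= 0.999999).all()
        pd.testing.assert_frame_equal(ds.targets, ds.targets_clean)

    def test_determinism(self):
        a = gen_herd_dataset(HerdSpec(n_cows=40, seed=7))
        b = gen_herd_dataset(HerdSpec(n_cows=40, seed=7))
        pd.testing.assert_frame_equal(a.features, b.features)
        pd.testing.assert_frame_equal(a.targets, b.targets)

    def test_schema_and_plausible_ranges(self):
        ds = gen_herd_dataset(HerdSpec(n_cows=60, seed=1))
        assert ds.features.shape == (60, 37)
        assert ds.features["hr_bpm"].between(60, 110).all()
        assert ds.features["rr_brpm"].between(20, 60).all()
        assert ds.targets["fat_pct"].between(0, 100).all()
        assert ds.targets["protein_pct"].between(0, 100).all()
        assert (ds.features[["var_x", "var_y"]] >= 0).all().all()

    def test_calibrated_oracle_near_requested(self):
        ds = gen_herd_dataset(HerdSpec(n_cows=400, oracle_r=0.96, seed=5))
        assert np.allclose(ds.oracle_r, 0.96, atol=0.02)

    def test_too_small_herd_rejected(self):
        with pytest.raises(ValueError):
            HerdSpec(n_cows=1)
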