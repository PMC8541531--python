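"""End-to-end orchestration: simulate -> extract -> assemble -> train -> deploy.

A run produces a directory with the feature/target tables, the serialized
model, development and deployment regression reports, the age-group summary
and a log with per-stage row counts.  Runs are idempotent for a fixed seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import modeling, synthetic, video
from .schema import FEATURE_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic run (YAML-serializable)."""

    out_dir: str = "runs/latest"
    seed: int = 0
    n_dev: int = 150  # development recordings
    n_deploy: int = 132  # held-out deployment recordings
    oracle_r: float = 0.96
    train_frac: float = 0.7
    sizes: tuple = tuple(modeling.TRIM_SIZES)
    max_epochs: int = 300
    # how many development recordings get their HR/RR re-measured from a
    # rendered synthetic video (end-to-end demonstration); the rest keep the
    # generator-drawn biometrics
    n_video_recordings: int = 0
    video_duration_s: float = 60.0
    video_fps: float = 30.0
    video_frame_size: tuple = (120, 160)

    def __post_init__(self):
        if not (0 < self.train_frac < 1):
            raise ValueError("train_frac must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sizes" in raw:
            raw["sizes"] = tuple(raw["sizes"])
        if "video_frame_size" in raw:
            raw["video_frame_size"] = tuple(raw["video_frame_size"])
        return cls(**raw)


def _remeasure_from_video(features: pd.DataFrame, cfg: PipelineConfig, rng) -> int:
    """Replace generator biometrics by video-measured ones for a subset."""
    n = min(cfg.n_video_recordings, len(features))
    for idx in features.index[:n]:
        hr = float(np.clip(features.at[idx, "hr_bpm"], 45, 140))
        rr = float(np.clip(features.at[idx, "rr_brpm"], 10, 70))
        spec = synthetic.SyntheticSceneSpec(
            duration_s=cfg.video_duration_s,
            fps=cfg.video_fps,
            frame_size=tuple(cfg.video_frame_size),
            hr_bpm=hr,
            rr_brpm=rr,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        seq, eye, nose, _head, _truth = synthetic.gen_rgb_sequence(spec)
        hr_res = video.estimate_heart_rate(seq, eye)
        rr_res = video.estimate_respiration_rate(seq, nose)
        if hr_res.defined:
            features.at[idx, "hr_bpm"] = hr_res.rate
            features.at[idx, "hr_amplitude"] = hr_res.amplitude
        if rr_res.defined:
            features.at[idx, "rr_brpm"] = rr_res.rate
            features.at[idx, "rr_amplitude"] = rr_res.amplitude
    return n


def run_all(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("herdvitals")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t0 = time.time()
    try:
        ss = np.random.SeedSequence(config.seed)
        dev_seed, deploy_seed, video_seed, split_seed = (
            int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)
        )

        dev = synthetic.gen_herd_dataset(
            synthetic.HerdSpec(
                n_cows=config.n_dev, oracle_r=config.oracle_r, seed=dev_seed
            )
        )
        held = synthetic.gen_herd_dataset(
            synthetic.HerdSpec(
                n_cows=config.n_deploy, oracle_r=config.oracle_r, seed=deploy_seed
            )
        )
        logger.info(
            "simulate: %d development + %d deployment recordings",
            len(dev.features),
            len(held.features),
        )
        if config.n_video_recordings:
            n_vid = _remeasure_from_video(
                dev.features, config, np.random.default_rng(video_seed)
            )
            logger.info("video re-measurement applied to %d recordings", n_vid)

        dev.features.to_csv(out / "features.csv")
        dev.targets.to_csv(out / "targets.csv")
        held.features.to_csv(out / "deployment_features.csv")
        held.targets.to_csv(out / "deployment_targets.csv")

        model, trials, (train_idx, test_idx) = modeling.neuron_trimming(
            dev.features.to_numpy(float),
            dev.targets.to_numpy(float),
            sizes=config.sizes,
            seed=split_seed,
            train_frac=config.train_frac,
            max_epochs=config.max_epochs,
        )
        logger.info(
            "train: split %d/%d, selected hidden size %d",
            len(train_idx),
            len(test_idx),
            model.hidden_size,
        )
        trials.to_csv(out / "trimming_trials.csv", index=False)
        (out / "model.json").write_text(model.to_json())

        X = dev.features.to_numpy(float)
        Y = dev.targets.to_numpy(float)
        reports = pd.DataFrame(
            {
                "training": modeling._model_report(
                    model, X[train_idx], Y[train_idx]
                ).as_dict(),
                "testing": modeling._model_report(
                    model, X[test_idx], Y[test_idx]
                ).as_dict(),
                "overall": modeling._model_report(model, X, Y).as_dict(),
            }
        ).T
        reports.index.name = "stage"
        reports.to_csv(out / "development_report.csv")

        dep_report = modeling.deploy(
            model, held.features.to_numpy(float), held.targets.to_numpy(float)
        )
        pd.DataFrame([dep_report.as_dict()]).to_csv(
            out / "deployment_report.csv", index=False
        )
        logger.info(
            "deploy: %d points, R=%.3f, outliers=%.1f%%",
            dep_report.n_points,
            dep_report.R,
            dep_report.outlier_pct,
        )

        summary_input = pd.concat(
            [dev.meta[["age"]], dev.features, dev.targets], axis=1
        )
        modeling.summarize_by_group(summary_input, "age").to_csv(
            out / "summary_by_age.csv"
        )

        explained, loadings = modeling.pca_summary(dev.features)
        pca_df = pd.DataFrame(
            loadings[:, :5],
            index=FEATURE_COLUMNS,
            columns=[f"PC{k + 1}" for k in range(5)],
        )
        pca_df.loc["explained_pct"] = explained[:5]
        pca_df.to_csv(out / "pca_loadings.csv")

        logger.info("run complete in %.1f s", time.time() - t0)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
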