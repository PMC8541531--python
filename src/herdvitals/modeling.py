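"""Modelling protocol around the Bayesian-regularized network.

Assembles the 37-column feature table, performs the 70/30 development split
and the input-count overfit guard, runs the neuron-trimming model selection
(hidden sizes 3, 5, 7, 10), and produces pooled predicted-vs-observed
regression reports with 95 %-prediction-band outlier flagging, for both the
development and deployment stages.  A correlation-matrix PCA summary and
mean +- SE age-group tables round out the descriptive statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ann import BayesRegNN
from .schema import FEATURE_COLUMNS, TARGET_COLUMNS

logger = logging.getLogger(__name__)

TRIM_SIZES = (3, 5, 7, 10)
OVERFIT_MSE_RATIO = 3.0  # test MSE > ratio x train MSE flags overfitting


def assemble_features(
    vitals: pd.DataFrame,
    movement: pd.DataFrame,
    weather_derived: pd.DataFrame,
    ids=None,
) -> pd.DataFrame:
    """Inner-join biometric, movement and weather blocks into the 37-column table.

    All inputs must be indexed (or carry a ``recording_id`` column) by the
    recording id.  Rows missing any component are dropped with a logged count;
    duplicated ids are an error.
    """
    blocks = []
    for name, df in [
        ("vitals", vitals),
        ("movement", movement),
        ("weather", weather_derived),
    ]:
        df = df.copy()
        if "recording_id" in df.columns:
            df = df.set_index("recording_id")
        if df.index.duplicated().any():
            raise ValueError(f"duplicate recording ids in {name} block")
        blocks.append(df)
    joined = blocks[0].join(blocks[1:], how="inner")
    if ids is not None:
        joined = joined.loc[joined.index.intersection(pd.Index(ids))]
    missing = set(FEATURE_COLUMNS) - set(joined.columns)
    if missing:
        raise ValueError(f"missing feature columns: {sorted(missing)}")
    n_before = max(len(b) for b in blocks)
    table = joined[FEATURE_COLUMNS].dropna()
    dropped = n_before - len(table)
    if dropped:
        logger.info("assemble_features: dropped %d incomplete recordings", dropped)
    return table


def split_samples(n: int, train_frac: float = 0.7, seed: int = 0):
    """Random disjoint train/test index split, sizes round(n*frac)/remainder."""
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must be in (0, 1)")
    n_train = int(round(n * train_frac))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def overfit_guard(n_inputs: int, n_train: int) -> bool:
    """Under/overfitting precondition: inputs < 70 % of training samples."""
    return n_inputs < 0.7 * n_train


@dataclass
class RegressionReport:
    """Pooled predicted-vs-observed statistics across all targets."""

    R: float  # Pearson correlation
    slope_b: float  # least-squares slope of predicted on observed
    MSE: float  # on the pooled (scaled) values
    n_points: int
    n_outliers: int
    outlier_pct: float  # % beyond the 95 % prediction band, 1 decimal
    per_target_mse: dict = field(default_factory=dict)  # original units

    def as_dict(self) -> dict:
        out = {
            "R": self.R,
            "slope_b": self.slope_b,
            "MSE": self.MSE,
            "n_points": self.n_points,
            "n_outliers": self.n_outliers,
            "outlier_pct": self.outlier_pct,
        }
        out.update({f"mse_{k}": v for k, v in self.per_target_mse.items()})
        return out


def regression_report(observed, predicted, per_target_mse=None) -> RegressionReport:
    """Pooled regression statistics with 95 %-prediction-band outliers.

    All targets' points are pooled; the least-squares line of predicted on
    observed defines a 95 % prediction band (t-based, per-point), and points
    outside it are the flagged outliers.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("observed and predicted must be equal-length and non-empty")
    n = obs.size
    mse = float(np.mean((pred - obs) ** 2))
    if np.std(obs) == 0 or np.std(pred) == 0:
        r = 0.0
        slope = 0.0
        n_out = 0
    else:
        r = float(np.corrcoef(obs, pred)[0, 1])
        sxx = float(np.sum((obs - obs.mean()) ** 2))
        slope = float(np.sum((obs - obs.mean()) * (pred - pred.mean())) / sxx)
        intercept = pred.mean() - slope * obs.mean()
        fitted = slope * obs + intercept
        resid = pred - fitted
        dof = max(n - 2, 1)
        s = float(np.sqrt(np.sum(resid**2) / dof))
        tcrit = stats.t.ppf(0.975, dof)
        half_width = tcrit * s * np.sqrt(1.0 + 1.0 / n + (obs - obs.mean()) ** 2 / sxx)
        n_out = int(np.sum(np.abs(resid) > half_width)) if s > 0 else 0
    pct = round(100.0 * n_out / n, 1)
    return RegressionReport(
        R=r,
        slope_b=slope,
        MSE=mse,
        n_points=n,
        n_outliers=n_out,
        outlier_pct=pct,
        per_target_mse=per_target_mse or {},
    )


def _model_report(model: BayesRegNN, X, Y) -> RegressionReport:
    """Report on the model's pooled scaled predictions for (X, Y)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    pred_s = model.predict_scaled(X)
    obs_s = model.scale_targets(Y)
    pred_raw = model.predict(X)
    pred_raw = pred_raw.reshape(Y.shape)
    per_target = {
        TARGET_COLUMNS[j] if Y.shape[1] == len(TARGET_COLUMNS) else f"target_{j}": float(
            np.mean((pred_raw[:, j] - Y[:, j]) ** 2)
        )
        for j in range(Y.shape[1])
    }
    return regression_report(obs_s, pred_s, per_target_mse=per_target)


def neuron_trimming(
    X,
    Y,
    sizes=TRIM_SIZES,
    seed: int = 0,
    train_frac: float = 0.7,
    max_epochs: int = 300,
):
    """Model selection over hidden-layer sizes on a fixed 70/30 split.

    Each candidate trains on the same split; the winner is the highest test R
    among models whose test MSE <= 3x train MSE (overfit screen), smallest
    size on ties.  If every candidate is screened out, the best test R is
    returned with an overfitting warning.

    Returns (best_model, trials) where trials is a DataFrame of per-size
    train/test R and MSE, plus (train_idx, test_idx).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    n = X.shape[0]
    train_idx, test_idx = split_samples(n, train_frac, seed)
    if not overfit_guard(X.shape[1], len(train_idx)):
        raise ValueError(
            f"overfit guard failed: {X.shape[1]} inputs >= 70% of "
            f"{len(train_idx)} training samples"
        )
    rows = []
    models = {}
    for size in sizes:
        model = BayesRegNN(
            hidden_size=int(size), max_epochs=max_epochs, random_state=seed
        )
        model.fit(X[train_idx], Y[train_idx])
        rep_tr = _model_report(model, X[train_idx], Y[train_idx])
        rep_te = _model_report(model, X[test_idx], Y[test_idx])
        models[size] = model
        rows.append(
            {
                "hidden_size": size,
                "train_R": rep_tr.R,
                "train_MSE": rep_tr.MSE,
                "test_R": rep_te.R,
                "test_MSE": rep_te.MSE,
                "gamma_eff": model.gamma_eff_,
                "overfit_flag": rep_te.MSE > OVERFIT_MSE_RATIO * rep_tr.MSE,
            }
        )
    trials = pd.DataFrame(rows)
    screened = trials[~trials["overfit_flag"]]
    pool = screened if len(screened) else trials
    if not len(screened):
        warnings.warn(
            "all hidden sizes failed the overfit screen; returning best test R",
            stacklevel=2,
        )
    # highest test R, smallest hidden size on ties (parsimony)
    pool = pool.sort_values(["test_R", "hidden_size"], ascending=[False, True])
    best_size = int(pool.iloc[0]["hidden_size"])
    return models[best_size], trials, (train_idx, test_idx)


def deploy(model: BayesRegNN, X_new, Y_new) -> RegressionReport:
    """Evaluate a frozen model on held-out recordings (forward + report)."""
    X_new = np.asarray(X_new, dtype=float)
    Y_new = np.asarray(Y_new, dtype=float)
    if Y_new.ndim == 1:
        Y_new = Y_new.reshape(-1, 1)
    if X_new.size == 0 or Y_new.size == 0:
        raise ValueError("deployment data is empty")
    return _model_report(model, X_new, Y_new)


def pca_summary(X) -> tuple[np.ndarray, np.ndarray]:
    """Correlation-matrix PCA: explained-variance % per PC and factor loadings.

    Columns are z-scored; loadings are the eigenvectors of the correlation
    matrix (orthonormal), each signed so its largest-magnitude element is
    positive.  Returns (explained_pct, loadings) with loadings[:, k] the k-th
    component.
    """
    A = np.asarray(X, dtype=float)
    if isinstance(X, pd.DataFrame):
        A = X.to_numpy(float)
    sd = A.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant columns cannot be z-scored for PCA")
    Z = (A - A.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for k in range(eigvec.shape[1]):
        j = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    explained_pct = 100.0 * eigval / eigval.sum()
    return explained_pct, eigvec


def summarize_by_group(records: pd.DataFrame, group_key: str = "age") -> pd.DataFrame:
    """Mean +- standard error of every numeric column per group.

    SE = sd/sqrt(n) with sample sd; single-member groups report SE as NaN
    (undefined), never 0.
    """
    if group_key not in records.columns:
        raise ValueError(f"missing group column {group_key!r}")
    numeric = records.select_dtypes(include=[np.number]).columns.drop(
        group_key, errors="ignore"
    )
    grouped = records.groupby(group_key)
    means = grouped[list(numeric)].mean()
    sds = grouped[list(numeric)].std(ddof=1)  # NaN for n = 1
    counts = grouped.size()
    ses = sds.div(np.sqrt(counts), axis=0)
    out = pd.concat({"mean": means, "se": ses}, axis=1)
    out[("n", "")] = counts
    return out
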