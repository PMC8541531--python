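"""Two-layer feedforward network trained by Bayesian-regularized Levenberg-Marquardt.

The regression core of the package: a single hidden layer of tan-sigmoid
neurons feeding a linear output layer,

    y_hat = W2 tanh(W1 x + b1) + b2,

with inputs and targets min-max scaled per column to [-1, 1].  Training
minimizes the regularized objective

    F = beta * E_D + alpha * E_W,

where E_D is the sum of squared errors on the scaled targets and E_W the sum
of squared weights, by Levenberg-Marquardt steps.  After each accepted step
the hyperparameters are re-estimated under MacKay's evidence framework
(Foresee & Hagan formulation):

    gamma = P - 2 alpha tr(H^-1),   alpha = gamma / (2 E_W),
    beta  = (N - gamma) / (2 E_D),  H = 2 beta J'J + 2 alpha I,

with P the parameter count, N the number of target values and gamma the
effective number of parameters.  This gives built-in overfitting control:
weights the data cannot support are shrunk toward zero.

With ``bayes=False`` and ``alpha_init=0`` the trainer reduces to plain
Levenberg-Marquardt least squares.
"""

from __future__ import annotations

import json

import numpy as np
from scipy import linalg as sla
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, check_random_state, validate_data


def _minmax_fit(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return A.min(axis=0), A.max(axis=0)


def _minmax_scale(A, lo, hi):
    span = np.where(hi > lo, hi - lo, 1.0)
    return 2.0 * (A - lo) / span - 1.0


def _minmax_unscale(S, lo, hi):
    span = np.where(hi > lo, hi - lo, 1.0)
    return (S + 1.0) / 2.0 * span + lo


class BayesRegNN(RegressorMixin, BaseEstimator):
    """Bayesian-regularized two-layer feedforward regressor.

    Parameters
    ----------
    hidden_size : int
        Number of tan-sigmoid hidden neurons.
    max_epochs : int
        Maximum accepted Levenberg-Marquardt steps.
    bayes : bool
        Re-estimate (alpha, beta) by the evidence framework after each
        accepted step.  ``False`` keeps them fixed at their initial values
        (``alpha_init=0`` then yields plain LM least squares).
    alpha_init, beta_init : float
        Initial regularization / noise-precision hyperparameters.
    grad_tol : float
        Stop when the gradient norm of F falls below this.
    mu_init, mu_max : float
        Initial and maximal LM damping; exceeding ``mu_max`` stops training.
    init_scale : float
        Scale of the small-uniform output-layer initialization; the hidden
        layer uses Nguyen-Widrow placement on the [-1, 1] input cube.
    n_restarts : int
        Independent seeded initializations; the fit with the lowest final
        objective F is kept (a training-set criterion only).
    random_state : int, RandomState or None
        Seed for weight initialization.

    Attributes
    ----------
    W1_, b1_, W2_, b2_ : ndarray
        Fitted weights (hidden x d, hidden, m x hidden, m).
    alpha_, beta_, gamma_eff_ : float
        Final hyperparameters and effective parameter count.
    training_log_ : list of dict
        Per-epoch F (before/after step), E_D, E_W, alpha, beta, gamma.
    """

    def __init__(
        self,
        hidden_size: int = 5,
        max_epochs: int = 300,
        bayes: bool = True,
        alpha_init: float = 0.0,
        beta_init: float = 1.0,
        grad_tol: float = 1e-7,
        mu_init: float = 5e-3,
        mu_max: float = 1e10,
        init_scale: float = 0.5,
        n_restarts: int = 1,
        random_state=None,
    ):
        self.hidden_size = hidden_size
        self.max_epochs = max_epochs
        self.bayes = bayes
        self.alpha_init = alpha_init
        self.beta_init = beta_init
        self.grad_tol = grad_tol
        self.mu_init = mu_init
        self.mu_max = mu_max
        self.init_scale = init_scale
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- parameter vector packing -------------------------------------------------

    def _shapes(self, d, m):
        H = self.hidden_size
        return [(H, d), (H,), (m, H), (m,)]

    def _unpack(self, w, d, m):
        H = self.hidden_size
        i = 0
        W1 = w[i : i + H * d].reshape(H, d)
        i += H * d
        b1 = w[i : i + H]
        i += H
        W2 = w[i : i + m * H].reshape(m, H)
        i += m * H
        b2 = w[i : i + m]
        return W1, b1, W2, b2

    @staticmethod
    def _forward_scaled(W1, b1, W2, b2, Xs):
        A = np.tanh(Xs @ W1.T + b1)  # (n, H)
        return A @ W2.T + b2, A

    def _errors(self, w, Xs, Ys, d, m):
        W1, b1, W2, b2 = self._unpack(w, d, m)
        Yhat, A = self._forward_scaled(W1, b1, W2, b2, Xs)
        return (Yhat - Ys).ravel(), A

    def _jacobian(self, w, Xs, A, d, m):
        """d(residual)/d(w), residuals flattened sample-major then output."""
        n = Xs.shape[0]
        H = self.hidden_size
        W1, b1, W2, b2 = self._unpack(w, d, m)
        P = H * d + H + m * H + m
        J = np.zeros((n * m, P))
        dA = 1.0 - A**2  # (n, H)
        # dy_k/dW1[j, :] = W2[k, j] * (1 - a_j^2) * x ; dy_k/db1[j] analogous
        # build via einsum: G[i, k, j] = W2[k, j] * dA[i, j]
        G = dA[:, None, :] * W2[None, :, :]  # (n, m, H)
        J[:, : H * d] = np.einsum("ikj,id->ikjd", G, Xs).reshape(n * m, H * d)
        J[:, H * d : H * d + H] = G.reshape(n * m, H)
        off = H * d + H
        # dy_k/dW2[k, j] = a_j (zero for other output rows);
        # residuals are ordered (sample0: y0..ym-1, sample1: ...)
        idx = np.arange(n * m)
        out_k = idx % m
        samp = idx // m
        for k in range(m):
            sel = out_k == k
            J[sel, off + k * H : off + (k + 1) * H] = A[samp[sel]]
            J[sel, off + m * H + k] = 1.0
        return J

    # -- fitting ------------------------------------------------------------------

    def _init_weights(self, rng, d, m):
        """Nguyen-Widrow hidden layer on the [-1, 1] cube; small-uniform output."""
        H = self.hidden_size
        W1 = rng.uniform(-1.0, 1.0, (H, d))
        norms = np.linalg.norm(W1, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        magnitude = 0.7 * H ** (1.0 / d)
        W1 = magnitude * W1 / norms
        b1 = magnitude * np.linspace(-1.0, 1.0, H) * np.sign(W1[:, 0] + 1e-12)
        W2 = rng.uniform(-self.init_scale, self.init_scale, (m, H))
        b2 = rng.uniform(-self.init_scale, self.init_scale, m)
        return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])

    def fit(self, X, y):
        X, y = validate_data(self, X, y, multi_output=True, y_numeric=True)
        Y = y.reshape(-1, 1) if y.ndim == 1 else y
        self._single_output = y.ndim == 1
        n, d = X.shape
        m = Y.shape[1]
        self.x_min_, self.x_max_ = _minmax_fit(X)
        self.y_min_, self.y_max_ = _minmax_fit(Y)
        Xs = _minmax_scale(X, self.x_min_, self.x_max_)
        Ys = _minmax_scale(Y, self.y_min_, self.y_max_)

        rng = check_random_state(self.random_state)
        best = None
        for _ in range(max(1, self.n_restarts)):
            run = self._fit_once(Xs, Ys, n, d, m, rng)
            # compare restarts by penalized error in data units
            score = run["E_D"] + (run["alpha"] / run["beta"]) * run["E_W"] if run[
                "beta"
            ] > 0 else run["E_D"]
            if best is None or score < best[0]:
                best = (score, run)
        run = best[1]
        self.W1_, self.b1_, self.W2_, self.b2_ = self._unpack(run["w"], d, m)
        self.alpha_ = run["alpha"]
        self.beta_ = run["beta"]
        self.gamma_eff_ = run["gamma"]
        self.n_params_ = run["P"]
        self.E_D_ = run["E_D"]
        self.E_W_ = run["E_W"]
        self.training_log_ = run["log"]
        self.stop_reason_ = run["stop_reason"]
        self.n_outputs_ = m
        return self

    def _fit_once(self, Xs, Ys, n, d, m, rng):
        H = self.hidden_size
        P = H * d + H + m * H + m
        N = n * m
        w = self._init_weights(rng, d, m)

        alpha = float(self.alpha_init)
        beta = float(self.beta_init)
        mu = float(self.mu_init)
        eye = np.eye(P)

        e, A = self._errors(w, Xs, Ys, d, m)
        E_D = float(e @ e)
        E_W = float(w @ w)
        F = beta * E_D + alpha * E_W
        gamma = float(P)
        log = []

        stop_reason = "max_epochs"
        for epoch in range(self.max_epochs):
            J = self._jacobian(w, Xs, A, d, m)
            g = 2.0 * beta * (J.T @ e) + 2.0 * alpha * w
            gnorm = float(np.linalg.norm(g))
            if gnorm < self.grad_tol:
                stop_reason = "gradient"
                break
            JtJ = J.T @ J
            F_before = F
            accepted = False
            while mu <= self.mu_max:
                Amat = 2.0 * beta * JtJ + (2.0 * alpha + mu) * eye
                try:
                    dw = sla.solve(Amat, -g, assume_a="pos")
                except np.linalg.LinAlgError:
                    mu *= 10.0
                    continue
                if not np.all(np.isfinite(dw)):
                    mu *= 10.0
                    continue
                w_new = w + dw
                e_new, A_new = self._errors(w_new, Xs, Ys, d, m)
                E_D_new = float(e_new @ e_new)
                E_W_new = float(w_new @ w_new)
                if not np.isfinite(E_D_new):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch} (mu={mu:.3g}, "
                        f"|w|={np.linalg.norm(w_new):.3g})"
                    )
                F_new = beta * E_D_new + alpha * E_W_new
                if F_new < F:
                    w, e, A = w_new, e_new, A_new
                    E_D, E_W, F = E_D_new, E_W_new, F_new
                    mu = max(mu / 10.0, 1e-20)
                    accepted = True
                    break
                mu *= 10.0
            if not accepted:
                stop_reason = "mu_overflow"
                break
            F_after_step = F  # objective after the accepted step, same (alpha, beta)
            if self.bayes:
                # evidence-framework re-estimation at the new point
                if alpha == 0.0:
                    gamma = float(P)  # 2*alpha*tr(H^-1) vanishes exactly
                else:
                    Hm = 2.0 * beta * JtJ + 2.0 * alpha * eye
                    try:
                        Hinv_trace = float(np.trace(sla.inv(Hm)))
                    except np.linalg.LinAlgError:
                        Hinv_trace = float(np.trace(np.linalg.pinv(Hm)))
                    gamma = P - 2.0 * alpha * Hinv_trace
                gamma = float(np.clip(gamma, 0.0, P))
                alpha = gamma / (2.0 * E_W) if E_W > 0 else 0.0
                beta = (N - gamma) / (2.0 * E_D) if E_D > 0 else self.beta_init
                F = beta * E_D + alpha * E_W
            log.append(
                {
                    "epoch": epoch,
                    "F_before_step": F_before,
                    "F_after_step": F_after_step,
                    "E_D": E_D,
                    "E_W": E_W,
                    "alpha": alpha,
                    "beta": beta,
                    "gamma": gamma,
                    "grad_norm": gnorm,
                    "mu": mu,
                }
            )
        return {
            "w": w,
            "alpha": alpha,
            "beta": beta,
            "gamma": gamma,
            "P": P,
            "E_D": E_D,
            "E_W": E_W,
            "log": log,
            "stop_reason": stop_reason,
        }

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        Xs = _minmax_scale(X, self.x_min_, self.x_max_)
        Yhat_s, _ = self._forward_scaled(self.W1_, self.b1_, self.W2_, self.b2_, Xs)
        Yhat = _minmax_unscale(Yhat_s, self.y_min_, self.y_max_)
        return Yhat.ravel() if self._single_output else Yhat

    def predict_scaled(self, X):
        """Predictions on the [-1, 1] target scale (for pooled reporting)."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        Xs = _minmax_scale(X, self.x_min_, self.x_max_)
        Yhat_s, _ = self._forward_scaled(self.W1_, self.b1_, self.W2_, self.b2_, Xs)
        return Yhat_s

    def scale_targets(self, Y):
        """Map targets (original units) onto the fitted [-1, 1] scale."""
        check_is_fitted(self)
        Y = np.asarray(Y, dtype=float)
        Y2 = Y.reshape(-1, 1) if Y.ndim == 1 else Y
        return _minmax_scale(Y2, self.y_min_, self.y_max_)

    # -- serialization ------------------------------------------------------------

    def to_json(self) -> str:
        check_is_fitted(self)
        payload = {
            "format": "herdvitals-bayesregnn-1",
            "params": self.get_params(),
            "weights": {
                "W1": self.W1_.tolist(),
                "b1": self.b1_.tolist(),
                "W2": self.W2_.tolist(),
                "b2": self.b2_.tolist(),
            },
            "scalers": {
                "x_min": self.x_min_.tolist(),
                "x_max": self.x_max_.tolist(),
                "y_min": self.y_min_.tolist(),
                "y_max": self.y_max_.tolist(),
            },
            "hyper": {
                "alpha": self.alpha_,
                "beta": self.beta_,
                "gamma_eff": self.gamma_eff_,
                "n_params": self.n_params_,
            },
            "single_output": self._single_output,
            "n_features_in": int(self.n_features_in_),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "BayesRegNN":
        payload = json.loads(text)
        if payload.get("format") != "herdvitals-bayesregnn-1":
            raise ValueError("not a serialized BayesRegNN model")
        params = payload["params"]
        params.pop("random_state", None)
        model = cls(**params)
        wts = payload["weights"]
        model.W1_ = np.asarray(wts["W1"], dtype=float)
        model.b1_ = np.asarray(wts["b1"], dtype=float)
        model.W2_ = np.asarray(wts["W2"], dtype=float)
        model.b2_ = np.asarray(wts["b2"], dtype=float)
        sc = payload["scalers"]
        model.x_min_ = np.asarray(sc["x_min"], dtype=float)
        model.x_max_ = np.asarray(sc["x_max"], dtype=float)
        model.y_min_ = np.asarray(sc["y_min"], dtype=float)
        model.y_max_ = np.asarray(sc["y_max"], dtype=float)
        hyper = payload["hyper"]
        model.alpha_ = hyper["alpha"]
        model.beta_ = hyper["beta"]
        model.gamma_eff_ = hyper["gamma_eff"]
        model.n_params_ = hyper["n_params"]
        model._single_output = payload["single_output"]
        model.n_features_in_ = payload["n_features_in"]
        model.training_log_ = []
        model.n_outputs_ = model.W2_.shape[0]
        return model


def forward(model: BayesRegNN, X) -> np.ndarray:
    """Functional forward pass in original units (thin wrapper on predict)."""
    return model.predict(X)
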