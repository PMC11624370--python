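"""Bayesian-regularized neural network for CH4 prediction from MIR spectra.

A single hidden layer of 2 tanh neurons with a linear output, trained by
minimizing

    F = beta * E_D + alpha * E_W,    E_D = 1/2 sum(e^2),  E_W = 1/2 sum(w^2),

where alpha (weight penalty) and beta (error precision) are re-estimated
every epoch with the Gauss-Newton evidence approximation

    gamma = n_w - alpha * tr(H^-1),  H = beta J'J + alpha I,
    alpha = gamma / (2 E_W),         beta = (n - gamma) / (2 E_D).

Inner steps are Levenberg-Marquardt.  Inputs are z-scored and the target is
centred/scaled internally; both transforms are stored in the model.  With
two neurons the network can represent near-linear responses (small weights,
tanh in its linear range) and saturating ones alike, which is why it is the
tool of choice for the partially nonlinear spectra-to-CH4 link.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

FORMAT_VERSION = 1


@dataclass
class BRNNModel:
    """Trained network: weights, regularization state and scaling."""

    n_inputs: int
    hidden: int
    weights: np.ndarray          # packed parameter vector
    alpha: float
    beta: float
    epochs: int
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    seed: int
    gamma: float = 0.0           # effective number of parameters

    def __post_init__(self):
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite network weights")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")

    @property
    def n_weights(self) -> int:
        return self.hidden * (self.n_inputs + 1) + self.hidden + 1

    def _unpack(self):
        d, h = self.n_inputs, self.hidden
        w = self.weights
        w_in = w[: h * d].reshape(h, d)
        b_in = w[h * d : h * d + h]
        v = w[h * d + h : h * d + 2 * h]
        b_out = w[-1]
        return w_in, b_in, v, b_out

    def forward_scaled(self, xs: np.ndarray) -> np.ndarray:
        w_in, b_in, v, b_out = self._unpack()
        a = np.tanh(xs @ w_in.T + b_in)
        return a @ v + b_out

    def to_json(self, path) -> None:
        payload = {
            "format": "mefeval-brnn",
            "version": FORMAT_VERSION,
            "n_inputs": self.n_inputs,
            "hidden": self.hidden,
            "weights": self.weights.tolist(),
            "alpha": self.alpha,
            "beta": self.beta,
            "epochs": self.epochs,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "seed": self.seed,
            "gamma": self.gamma,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "BRNNModel":
        with open(path) as fh:
            p = json.load(fh)
        if p.get("format") != "mefeval-brnn":
            raise ValueError("not a mefeval BRNN model file")
        return cls(
            n_inputs=p["n_inputs"], hidden=p["hidden"],
            weights=np.array(p["weights"]), alpha=p["alpha"], beta=p["beta"],
            epochs=p["epochs"], x_mean=np.array(p["x_mean"]),
            x_sd=np.array(p["x_sd"]), y_mean=p["y_mean"], y_sd=p["y_sd"],
            seed=p["seed"], gamma=p.get("gamma", 0.0),
        )


def _jacobian(xs, w_in, b_in, v):
    """Jacobian of predictions wrt packed parameters."""
    n, d = xs.shape
    h = len(b_in)
    a = np.tanh(xs @ w_in.T + b_in)       # n x h
    da = 1.0 - a**2
    j_win = (v[None, :] * da)[:, :, None] * xs[:, None, :]   # n x h x d
    j = np.concatenate(
        [j_win.reshape(n, h * d), v[None, :] * da, a, np.ones((n, 1))], axis=1
    )
    return j, a


def train_brnn(
    spectra: np.ndarray,
    targets: np.ndarray,
    epochs: int = 100,
    hidden: int = 2,
    seed: int = 0,
    init_sd: float = 0.1,
) -> BRNNModel:
    """Fit the Bayesian-regularized network (deterministic given seed)."""
    x = np.asarray(spectra, dtype=float)
    y = np.asarray(targets, dtype=float)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("spectra and targets must align")
    n, d = x.shape
    if n < 10:
        raise ValueError("need at least 10 training pairs")

    x_mean, x_sd = x.mean(axis=0), x.std(axis=0)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    xs = (x - x_mean) / x_sd
    y_mean, y_sd = float(y.mean()), float(y.std())
    if y_sd == 0:
        y_sd = 1.0
    ys = (y - y_mean) / y_sd

    rng = np.random.default_rng(seed)
    n_w = hidden * (d + 1) + hidden + 1
    w = rng.normal(0.0, init_sd, size=n_w)
    alpha, beta = 0.01, 1.0
    mu = 0.005
    eye = np.eye(n_w)

    def split(wv):
        w_in = wv[: hidden * d].reshape(hidden, d)
        b_in = wv[hidden * d : hidden * d + hidden]
        v = wv[hidden * d + hidden : hidden * d + 2 * hidden]
        b_out = wv[-1]
        return w_in, b_in, v, b_out

    def objective(wv):
        w_in, b_in, v, b_out = split(wv)
        pred = np.tanh(xs @ w_in.T + b_in) @ v + b_out
        e = ys - pred
        return 0.5 * np.sum(e**2), 0.5 * np.sum(wv**2), e

    ed, ew, e = objective(w)
    gamma = float(n_w)
    for epoch in range(epochs):
        w_in, b_in, v, b_out = split(w)
        j, _ = _jacobian(xs, w_in, b_in, v)
        jtj = j.T @ j
        grad = beta * (j.T @ e) - alpha * w
        improved = False
        for _ in range(30):
            h_lm = beta * jtj + (alpha + mu) * eye
            try:
                step = np.linalg.solve(h_lm, grad)
            except np.linalg.LinAlgError:
                mu *= 10
                continue
            w_try = w + step
            ed_t, ew_t, e_t = objective(w_try)
            f_try = beta * ed_t + alpha * ew_t
            if not np.isfinite(f_try):
                raise RuntimeError(
                    f"non-finite objective at epoch {epoch} (mu={mu:.2e})"
                )
            if f_try < beta * ed + alpha * ew:
                w, ed, ew, e = w_try, ed_t, ew_t, e_t
                mu = max(mu * 0.1, 1e-12)
                improved = True
                break
            mu *= 10
            if mu > 1e10:
                break
        # evidence re-estimation of alpha, beta
        h_full = beta * jtj + alpha * eye
        try:
            hinv_tr = np.trace(np.linalg.inv(h_full))
        except np.linalg.LinAlgError:
            hinv_tr = np.trace(np.linalg.pinv(h_full))
        gamma = n_w - alpha * hinv_tr
        gamma = float(np.clip(gamma, 1e-6, min(n_w, n - 1e-6) if n > 1 else n_w))
        alpha = float(gamma / max(2.0 * ew, 1e-12))
        alpha = float(np.clip(alpha, 1e-10, 1e10))
        beta = float((n - gamma) / max(2.0 * ed, 1e-12))
        beta = float(np.clip(beta, 1e-10, 1e10))
        if not improved and mu > 1e10:
            break

    return BRNNModel(
        n_inputs=d, hidden=hidden, weights=w, alpha=alpha, beta=beta,
        epochs=epochs, x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd,
        seed=seed, gamma=gamma,
    )


def predict_ch4(model: BRNNModel, spectra: np.ndarray) -> np.ndarray:
    """Deterministic forward pass on new spectra (g/d scale)."""
    x = np.asarray(spectra, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.n_inputs:
        raise ValueError(
            f"spectra have {x.shape[1]} points; model expects {model.n_inputs}"
        )
    xs = (x - model.x_mean) / model.x_sd
    return model.forward_scaled(xs) * model.y_sd + model.y_mean
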