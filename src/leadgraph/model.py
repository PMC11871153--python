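"""Reference 1-D convolutional classifier, implemented directly on numpy.

This is the small fixed model the evaluation harness trains: four
convolution blocks (kernel 7, 'same' padding, ReLU, average-pool 2) with
channel widths (16, 24, 32, 32), global average pooling over time, dropout,
and a linear head.  Forward and backward passes are hand-written, which
keeps the model dependency-free and — importantly for the robustness
protocol — makes the gradient of the loss with respect to the *input*
available for gradient-sign attacks.

Multi-class heads use softmax cross-entropy; multi-label heads use
per-class sigmoid binary cross-entropy.  The optimizer is Adam with
decoupled-style l2 regularization added to the weight gradients.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ConvClassifier", "AdamOptimizer"]


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """'Same' 1-D convolution via an im2col strided view.

    x: (N, C, T); W: (O, C, k) with k odd; returns y (N, O, T) and the
    column view needed by the backward pass.
    """
    k = W.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
    cols = sliding_window_view(xp, k, axis=2)  # (N, C, T, k)
    y = np.einsum("nctk,ock->not", cols, W, optimize=True) + b[None, :, None]
    return y, cols


def _conv_backward(dy: np.ndarray, cols: np.ndarray, W: np.ndarray):
    """Gradients of a 'same' conv: (dx, dW, db)."""
    k = W.shape[2]
    p = k // 2
    T = dy.shape[2]
    dW = np.einsum("not,nctk->ock", dy, cols, optimize=True)
    db = dy.sum(axis=(0, 2))
    dyp = np.pad(dy, ((0, 0), (0, 0), (k - 1, k - 1)))
    dcols = sliding_window_view(dyp, k, axis=2)  # (N, O, T + k - 1, k)
    dxp = np.einsum("nosk,ock->ncs", dcols, W[:, :, ::-1], optimize=True)
    return dxp[:, :, p : p + T], dW, db


def _pool2_forward(x: np.ndarray):
    T = x.shape[2] - (x.shape[2] % 2)
    xt = x[:, :, :T]
    return xt.reshape(x.shape[0], x.shape[1], T // 2, 2).mean(axis=3), x.shape[2]


def _pool2_backward(dy: np.ndarray, T_in: int):
    dx = np.repeat(dy, 2, axis=2) / 2.0
    if dx.shape[2] < T_in:  # odd input length: last sample got no gradient
        dx = np.pad(dx, ((0, 0), (0, 0), (0, T_in - dx.shape[2])))
    return dx


class AdamOptimizer:
    """Adam with l2 regularization folded into the weight gradients."""

    def __init__(self, params: dict, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8, weight_decay=1e-5):
        self.lr, self.b1, self.b2, self.eps, self.wd = lr, beta1, beta2, eps, weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for key, p in params.items():
            g = grads[key]
            if self.wd and not key.startswith("b"):
                g = g + self.wd * p
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ConvClassifier:
    """Fixed small 1-D CNN; see the module docstring for the layer table."""

    CHANNELS = (16, 24, 32, 32)
    KERNEL = 7

    def __init__(self, n_leads: int, n_classes: int, task: str = "multi-class",
                 dropout: float = 0.1, seed: int = 0):
        if task not in ("multi-class", "multi-label"):
            raise ValueError(f"unknown task {task!r}")
        self.task = task
        self.n_classes = n_classes
        self.dropout = float(dropout)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = n_leads
        for i, c_out in enumerate(self.CHANNELS):
            fan_in = c_in * self.KERNEL
            self.params[f"W{i}"] = rng.normal(0, np.sqrt(2.0 / fan_in),
                                              size=(c_out, c_in, self.KERNEL))
            self.params[f"b{i}"] = np.zeros(c_out)
            c_in = c_out
        self.params["Wfc"] = rng.normal(0, np.sqrt(2.0 / c_in), size=(c_in, n_classes))
        self.params["bfc"] = np.zeros(n_classes)

    # ------------------------------------------------------------------ forward

    def _forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None):
        cache = {"acts": [], "cols": [], "T_ins": [], "relu": []}
        h = x
        for i in range(len(self.CHANNELS)):
            y, cols = _conv_forward(h, self.params[f"W{i}"], self.params[f"b{i}"])
            relu_mask = y > 0
            y = y * relu_mask
            pooled, T_in = _pool2_forward(y)
            cache["cols"].append(cols)
            cache["relu"].append(relu_mask)
            cache["T_ins"].append(T_in)
            h = pooled
        if h.shape[2] < 1:
            raise ValueError(
                "input too short for the 4-block architecture (need T >= 16)"
            )
        cache["pre_gap_T"] = h.shape[2]
        feat = h.mean(axis=2)  # global average pool -> (N, C)
        if train and self.dropout > 0:
            keep = (rng.random(feat.shape) >= self.dropout) / (1 - self.dropout)
            feat = feat * keep
            cache["drop"] = keep
        cache["feat"] = feat
        logits = feat @ self.params["Wfc"] + self.params["bfc"]
        return logits, cache

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(np.asarray(x, dtype=np.float64), train=False, rng=None)
        return logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.predict_logits(x)
        if self.task == "multi-class":
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)
        return 1.0 / (1.0 + np.exp(-logits))

    # ------------------------------------------------------------------ loss

    def _loss_dlogits(self, logits: np.ndarray, y: np.ndarray):
        N = logits.shape[0]
        if self.task == "multi-class":
            z = logits - logits.max(axis=1, keepdims=True)
            logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
            loss = -logp[np.arange(N), y].mean()
            dlogits = np.exp(logp)
            dlogits[np.arange(N), y] -= 1.0
            return loss, dlogits / N
        # multi-label sigmoid BCE, mean over samples and classes
        yv = np.asarray(y, dtype=np.float64)
        prob = 1.0 / (1.0 + np.exp(-logits))
        eps = 1e-12
        loss = -np.mean(yv * np.log(prob + eps) + (1 - yv) * np.log(1 - prob + eps))
        return loss, (prob - yv) / (N * logits.shape[1])

    # ------------------------------------------------------------------ backward

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, train: bool = True,
                       rng: np.random.Generator | None = None):
        """Returns (loss, parameter gradients, gradient w.r.t. the input)."""
        x = np.asarray(x, dtype=np.float64)
        logits, cache = self._forward(x, train=train, rng=rng)
        loss, dlogits = self._loss_dlogits(logits, y)
        grads: dict[str, np.ndarray] = {}
        grads["Wfc"] = cache["feat"].T @ dlogits
        grads["bfc"] = dlogits.sum(axis=0)
        dfeat = dlogits @ self.params["Wfc"].T
        if "drop" in cache:
            dfeat = dfeat * cache["drop"]
        T_gap = cache["pre_gap_T"]
        dh = np.repeat(dfeat[:, :, None], T_gap, axis=2) / T_gap
        for i in reversed(range(len(self.CHANNELS))):
            dy = _pool2_backward(dh, cache["T_ins"][i])
            dy = dy * cache["relu"][i]
            dh, dW, db = _conv_backward(dy, cache["cols"][i], self.params[f"W{i}"])
            grads[f"W{i}"] = dW
            grads[f"b{i}"] = db
        return loss, grads, dh

    def input_gradient(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """d(loss)/d(input) in evaluation mode (no dropout)."""
        _, _, dx = self.loss_and_grads(x, y, train=False, rng=None)
        return dx
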