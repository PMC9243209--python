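"""Compact NumPy CNN for classifying ULBPEZ feature images.

The architecture is a fixed stack of three 1x5 convolution + batch-norm +
ReLU groups, each followed by 1x2 max pooling with stride 2 on both axes,
then two fully-connected layers and a softmax.  The 1x5 kernels act as 1-D
filters along token-stream rows of the feature image; padding of 1 on all
sides grows the height by 2 at every convolution while the width shrinks
by 2, reproducing the characteristic activation shapes (93x89x8 after the
first convolution of a 91x91 input, down to 14x9x8 = 1008 features before
the dense head).

Training is plain mini-batch Adam on the softmax cross-entropy, with He
weight initialisation, batch statistics for batch-norm during training and
exponential running statistics at inference.  Everything is seeded, so runs
are bit-reproducible on a fixed BLAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["ConvSpec", "CNNArchitecture", "TrainConfig", "SmallCNN", "cnn_output_shapes"]

_KW = 5  # convolution kernel width (1 x 5 filters)
_PAD = 1  # padding on all four sides


@dataclass(frozen=True)
class CNNArchitecture:
    """Layer plan: three conv/BN/ReLU/maxpool groups and a dense head."""

    input_side: int = 91
    conv_filters: tuple[int, int, int] = (8, 16, 8)
    fc_width: int = 100
    n_classes: int = 5


def cnn_output_shapes(arch: CNNArchitecture) -> list[tuple[str, tuple[int, ...]]]:
    """Activation dimensions (H, W, C) of every layer.

    Convolutions use 1x5 kernels, stride 1, padding 1 on every side:
    H -> H + 2, W -> W - 2.  Max pooling uses a 1x2 window with stride 2 and
    no padding on both axes: H -> floor((H-1)/2)+1, W -> floor((W-2)/2)+1.
    Raises if any dimension collapses to zero or below.
    """
    h = w = arch.input_side
    shapes: list[tuple[str, tuple[int, ...]]] = [("input", (h, w, 1))]
    for i, nf in enumerate(arch.conv_filters, start=1):
        h = (h - 1 + 2 * _PAD) // 1 + 1
        w = (w - _KW + 2 * _PAD) // 1 + 1
        if h <= 0 or w <= 0:
            raise ValueError(f"conv{i} output collapsed to {h}x{w}")
        shapes.append((f"conv{i}", (h, w, nf)))
        shapes.append((f"batchnorm{i}", (h, w, nf)))
        shapes.append((f"relu{i}", (h, w, nf)))
        h = (h - 1) // 2 + 1
        w = (w - 2) // 2 + 1
        if h <= 0 or w <= 0:
            raise ValueError(f"maxpool{i} output collapsed to {h}x{w}")
        shapes.append((f"maxpool{i}", (h, w, nf)))
    flat = h * w * arch.conv_filters[-1]
    shapes.append(("fc1", (arch.fc_width,)))
    shapes.append(("fc2", (arch.n_classes,)))
    shapes.append(("softmax", (arch.n_classes,)))
    return shapes


# alias kept for callers thinking in terms of the conv spec table
ConvSpec = CNNArchitecture


@dataclass
class TrainConfig:
    """Optimiser settings; defaults suit the small net and input."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    val_fraction: float = 0.10
    patience: int = 10  # early-stopping patience in epochs (None disables)
    seed: int = 0


def _conv1x5_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x: (N, C, H, W) -> (N, F, H+2, W-2); W: (F, C, 5)."""
    xp = np.pad(x, ((0, 0), (0, 0), (_PAD, _PAD), (_PAD, _PAD)))
    win = np.lib.stride_tricks.sliding_window_view(xp, _KW, axis=3)
    out = np.einsum("nchwk,fck->nfhw", win, W, optimize=True)
    out += b[None, :, None, None]
    return out, xp


def _conv1x5_backward(dout: np.ndarray, xp: np.ndarray, W: np.ndarray):
    win = np.lib.stride_tricks.sliding_window_view(xp, _KW, axis=3)
    dW = np.einsum("nchwk,nfhw->fck", win, dout, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    dxp = np.zeros_like(xp)
    w_out = dout.shape[3]
    for k in range(_KW):
        dxp[:, :, :, k : k + w_out] += np.einsum(
            "nfhw,fc->nchw", dout, W[:, :, k], optimize=True
        )
    dx = dxp[:, :, _PAD:-_PAD, _PAD:-_PAD]
    return dx, dW, db


def _pool_forward(x: np.ndarray):
    """1x2 max pooling, stride 2 on both axes, no padding."""
    n, c, h, w = x.shape
    h_out = (h - 1) // 2 + 1
    w_out = (w - 2) // 2 + 1
    rows = x[:, :, ::2, :][:, :, :h_out, : 2 * w_out]
    pairs = rows.reshape(n, c, h_out, w_out, 2)
    arg = pairs.argmax(axis=4)
    out = np.take_along_axis(pairs, arg[..., None], axis=4)[..., 0]
    return out, (arg, x.shape)


def _pool_backward(dout: np.ndarray, cache):
    arg, shape = cache
    n, c, h, w = shape
    h_out, w_out = dout.shape[2], dout.shape[3]
    dpairs = np.zeros((n, c, h_out, w_out, 2), dtype=dout.dtype)
    np.put_along_axis(dpairs, arg[..., None], dout[..., None], axis=4)
    dx = np.zeros(shape, dtype=dout.dtype)
    dx_rows = dpairs.reshape(n, c, h_out, 2 * w_out)
    dx[:, :, ::2, :][:, :, :h_out, : 2 * w_out] = dx_rows
    return dx


class _BatchNorm:
    def __init__(self, channels: int):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)
        self.momentum = 0.9
        self.eps = 1e-5

    def forward(self, x: np.ndarray, training: bool):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]
        return out, (xhat, inv)

    def backward(self, dout: np.ndarray, cache):
        xhat, inv = cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        dbeta = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (
            inv[None, :, None, None]
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            )
        )
        return dx, dgamma, dbeta


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCNN:
    """The fixed three-group convolutional classifier (see module docstring)."""

    def __init__(self, arch: CNNArchitecture, seed: int = 0):
        self.arch = arch
        rng = np.random.default_rng(seed)
        f1, f2, f3 = arch.conv_filters
        self.params: dict[str, np.ndarray] = {}
        for name, (fout, cin) in {
            "conv1": (f1, 1),
            "conv2": (f2, f1),
            "conv3": (f3, f2),
        }.items():
            fan_in = cin * _KW
            self.params[f"{name}_W"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(fout, cin, _KW)
            )
            self.params[f"{name}_b"] = np.zeros(fout)
        self.bns = [_BatchNorm(f1), _BatchNorm(f2), _BatchNorm(f3)]
        shapes = dict(cnn_output_shapes(arch))
        h, w, c = shapes["maxpool3"]
        self.flat_dim = h * w * c
        self.params["fc1_W"] = rng.normal(
            0.0, np.sqrt(2.0 / self.flat_dim), size=(arch.fc_width, self.flat_dim)
        )
        self.params["fc1_b"] = np.zeros(arch.fc_width)
        self.params["fc2_W"] = rng.normal(
            0.0, np.sqrt(2.0 / arch.fc_width), size=(arch.n_classes, arch.fc_width)
        )
        self.params["fc2_b"] = np.zeros(arch.n_classes)
        self.classes_: Optional[np.ndarray] = None

    def n_parameters(self) -> int:
        n = sum(p.size for p in self.params.values())
        n += sum(b.gamma.size + b.beta.size for b in self.bns)
        return n

    # --- forward / backward ------------------------------------------------

    def _forward(self, x: np.ndarray, training: bool):
        cache: dict = {}
        h = x
        for i in (1, 2, 3):
            h, xp = _conv1x5_forward(h, self.params[f"conv{i}_W"], self.params[f"conv{i}_b"])
            cache[f"conv{i}_xp"] = xp
            h, bn_cache = self.bns[i - 1].forward(h, training)
            cache[f"bn{i}"] = bn_cache
            cache[f"relu{i}"] = h > 0
            h = np.maximum(h, 0.0)
            h, pool_cache = _pool_forward(h)
            cache[f"pool{i}"] = pool_cache
        cache["flat_shape"] = h.shape
        flat = h.reshape(h.shape[0], -1)
        cache["flat"] = flat
        z1 = flat @ self.params["fc1_W"].T + self.params["fc1_b"]
        cache["z1"] = z1
        z2 = z1 @ self.params["fc2_W"].T + self.params["fc2_b"]
        probs = _softmax(z2)
        return probs, cache

    def _backward(self, probs: np.ndarray, onehot: np.ndarray, cache: dict):
        grads: dict[str, np.ndarray] = {}
        n = probs.shape[0]
        dz2 = (probs - onehot) / n
        grads["fc2_W"] = dz2.T @ cache["z1"]
        grads["fc2_b"] = dz2.sum(axis=0)
        dz1 = dz2 @ self.params["fc2_W"]
        grads["fc1_W"] = dz1.T @ cache["flat"]
        grads["fc1_b"] = dz1.sum(axis=0)
        dh = (dz1 @ self.params["fc1_W"]).reshape(cache["flat_shape"])
        for i in (3, 2, 1):
            dh = _pool_backward(dh, cache[f"pool{i}"])
            dh = dh * cache[f"relu{i}"]
            dh, dgamma, dbeta = self.bns[i - 1].backward(dh, cache[f"bn{i}"])
            grads[f"bn{i}_gamma"] = dgamma
            grads[f"bn{i}_beta"] = dbeta
            dh, dW, db = _conv1x5_backward(dh, cache[f"conv{i}_xp"], self.params[f"conv{i}_W"])
            grads[f"conv{i}_W"] = dW
            grads[f"conv{i}_b"] = db
        return grads

    # --- training ----------------------------------------------------------

    @staticmethod
    def _prepare(images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None, :, :]
        return x / 255.0

    def fit(
        self,
        images: np.ndarray,
        labels: Sequence,
        cfg: Optional[TrainConfig] = None,
    ) -> "SmallCNN":
        """Train on (N, side, side) uint8 feature images with class labels."""
        cfg = cfg or TrainConfig()
        x = self._prepare(images)
        if x.shape[2] != self.arch.input_side or x.shape[3] != self.arch.input_side:
            raise ValueError(
                f"expected {self.arch.input_side}x{self.arch.input_side} images, "
                f"got {x.shape[2]}x{x.shape[3]}"
            )
        labels = np.asarray(labels)
        self.classes_ = np.unique(labels)
        if self.classes_.size < 2:
            raise ValueError("training needs at least two classes")
        if self.classes_.size != self.arch.n_classes:
            raise ValueError(
                f"architecture has {self.arch.n_classes} outputs but "
                f"{self.classes_.size} classes were given"
            )
        y = np.searchsorted(self.classes_, labels)
        onehot_all = np.eye(self.arch.n_classes)[y]

        rng = np.random.default_rng(cfg.seed)
        n = x.shape[0]
        n_val = int(round(cfg.val_fraction * n)) if cfg.patience else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]

        # Adam state
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v) for k, v in self.params.items()}
        for i, bn in enumerate(self.bns, start=1):
            for pname in ("gamma", "beta"):
                m[f"bn{i}_{pname}"] = np.zeros_like(getattr(bn, pname))
                v[f"bn{i}_{pname}"] = np.zeros_like(getattr(bn, pname))
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        def apply(name: str, ref: np.ndarray, g: np.ndarray):
            nonlocal t
            m[name] = beta1 * m[name] + (1 - beta1) * g
            v[name] = beta2 * v[name] + (1 - beta2) * g * g
            mhat = m[name] / (1 - beta1**t)
            vhat = v[name] / (1 - beta2**t)
            ref -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

        best_val = -np.inf
        best_state = None
        stall = 0
        for _epoch in range(cfg.epochs):
            order = rng.permutation(tr_idx)
            for start in range(0, order.size, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                if batch.size < 2:
                    continue  # batch-norm needs >= 2 samples
                probs, cache = self._forward(x[batch], training=True)
                grads = self._backward(probs, onehot_all[batch], cache)
                t += 1
                for key in self.params:
                    apply(key, self.params[key], grads[key])
                for i, bn in enumerate(self.bns, start=1):
                    apply(f"bn{i}_gamma", bn.gamma, grads[f"bn{i}_gamma"])
                    apply(f"bn{i}_beta", bn.beta, grads[f"bn{i}_beta"])
            if n_val:
                val_probs, _ = self._forward(x[val_idx], training=False)
                val_acc = (val_probs.argmax(1) == y[val_idx]).mean()
                # ties keep the most recent state: small validation sets
                # saturate early while the model is still improving
                if val_acc >= best_val:
                    stall = 0 if val_acc > best_val else stall + 1
                    best_val = val_acc
                    best_state = self._snapshot()
                else:
                    stall += 1
                if stall >= cfg.patience:
                    break
        if best_state is not None:
            self._restore(best_state)
        return self

    def _snapshot(self):
        return (
            {k: p.copy() for k, p in self.params.items()},
            [
                (bn.gamma.copy(), bn.beta.copy(), bn.run_mean.copy(), bn.run_var.copy())
                for bn in self.bns
            ],
        )

    def _restore(self, state):
        params, bns = state
        for k in self.params:
            self.params[k] = params[k].copy()
        for bn, (g, b, rm, rv) in zip(self.bns, bns):
            bn.gamma, bn.beta, bn.run_mean, bn.run_var = g.copy(), b.copy(), rm.copy(), rv.copy()

    # --- inference ---------------------------------------------------------

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = self._prepare(images)
        out = []
        for start in range(0, x.shape[0], batch_size):
            probs, _ = self._forward(x[start : start + batch_size], training=False)
            out.append(probs)
        return np.concatenate(out)

    def predict(self, images: np.ndarray) -> np.ndarray:
        if self.classes_ is None:
            raise RuntimeError("model is not fitted")
        probs = self.predict_proba(images)
        return self.classes_[probs.argmax(axis=1)]
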