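"""A compact trainable CNN in pure numpy.

Three 3×3 convolution blocks (ReLU + 2×2 max-pool), flattened feature maps
into a dense two-logit head — one logit per finding.  Convolutions run as
im2col matrix products; gradients are derived by hand and optimized with
Adam.  The class implements the backend contract used by the training and
saliency code:

* ``fit(X, Y, config)`` — multi-target training with BCE-with-logits loss
* ``predict_logits(X)`` — per-finding raw logits
* ``feature_maps_and_grads(x, finding)`` — last-conv activations and the
  gradient of the chosen finding's logit w.r.t. them (for Grad-CAM)

Everything is deterministic given the construction seed and input order.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .training import TrainConfig, multi_target_loss


def _im2col(x: np.ndarray, k: int = 3, pad: int = 1) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) patches of a same-size 3x3 convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (n, c, h, w, k, k), (s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)


def _col2im(cols: np.ndarray, shape: Tuple[int, int, int, int], k: int = 3,
            pad: int = 1) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to image layout."""
    n, c, h, w = shape
    out = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(n, h, w, c, k, k)
    for di in range(k):
        for dj in range(k):
            out[:, :, di : di + h, dj : dj + w] += cols[:, :, :, :, di, dj].transpose(
                0, 3, 1, 2
            )
    return out[:, :, pad : pad + h, pad : pad + w]


def _maxpool(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    n, c, h, w = x.shape
    r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, h // 2, w // 2, 4
    )
    idx = r.argmax(axis=-1)
    return np.take_along_axis(r, idx[..., None], axis=-1)[..., 0], idx


def _maxpool_backward(dout: np.ndarray, idx: np.ndarray,
                      shape: Tuple[int, int, int, int]) -> np.ndarray:
    n, c, h, w = shape
    r = np.zeros((n, c, h // 2, w // 2, 4))
    np.put_along_axis(r, idx[..., None], dout[..., None], axis=-1)
    return r.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, h, w
    )


class _Adam:
    def __init__(self, params: List[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SmallCNN:
    """3 conv blocks (3×3, ReLU, 2×2 max-pool) + flattened dense head, 2 logits."""

    def __init__(self, side: int = 64, channels: Tuple[int, int, int] = (8, 16, 32),
                 n_outputs: int = 2, seed: int = 0):
        if side % 8 != 0:
            raise ValueError("side must be divisible by 8 (three 2x2 pools)")
        self.side = side
        self.channels = channels
        self.n_outputs = n_outputs
        self.seed = seed
        rng = np.random.default_rng(seed)
        c_in = (1,) + channels[:-1]
        self.W = [
            (rng.standard_normal((co, ci * 9)) * np.sqrt(2.0 / (ci * 9)))
            for ci, co in zip(c_in, channels)
        ]
        self.b = [np.zeros(co) for co in channels]
        feat = channels[-1] * (side // 8) ** 2
        self.Wd = rng.standard_normal((n_outputs, feat)) * np.sqrt(1.0 / feat)
        self.bd = np.zeros(n_outputs)

    # ---------------------------------------------------------------- forward
    def _forward(self, x: np.ndarray, keep: bool = False):
        """x: (N, side, side) -> logits (N, n_outputs); cache intermediates if keep."""
        a = x[:, None, :, :]
        cache = {"inputs": [], "cols": [], "pre": [], "pool_idx": [], "pool_in": []}
        for W, b in zip(self.W, self.b):
            cols = _im2col(a)
            n, hw, _ = cols.shape
            h = w = int(np.sqrt(hw))
            pre = (cols @ W.T + b).transpose(0, 2, 1).reshape(n, -1, h, w)
            act = np.maximum(pre, 0.0)
            pooled, idx = _maxpool(act)
            if keep:
                cache["inputs"].append(a)
                cache["cols"].append(cols)
                cache["pre"].append(pre)
                cache["pool_in"].append(act)
                cache["pool_idx"].append(idx)
            a = pooled
        feats = a.reshape(a.shape[0], -1)
        logits = feats @ self.Wd.T + self.bd
        if keep:
            cache["last_maps"] = a  # post-ReLU, post-pool last conv features
            cache["feats"] = feats
            return logits, cache
        return logits

    def predict_logits(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = [self._forward(X[i : i + batch_size]) for i in range(0, len(X), batch_size)]
        return np.concatenate(out, axis=0)

    # --------------------------------------------------------------- backward
    def _backward(self, cache, dlogits: np.ndarray) -> List[np.ndarray]:
        """Gradients in the same order as _params(): [W1, b1, ..., Wd, bd]."""
        dWd = dlogits.T @ cache["feats"]
        dbd = dlogits.sum(axis=0)
        da = (dlogits @ self.Wd).reshape(cache["last_maps"].shape)
        conv_grads: List[np.ndarray] = []
        for layer in reversed(range(len(self.W))):
            act = cache["pool_in"][layer]
            dact = _maxpool_backward(da, cache["pool_idx"][layer], act.shape)
            dpre = dact * (cache["pre"][layer] > 0)
            n, c, h, w = dpre.shape
            dpre_flat = dpre.reshape(n, c, h * w).transpose(0, 2, 1)  # (N, HW, C)
            cols = cache["cols"][layer]
            dW = np.einsum("npc,npk->ck", dpre_flat, cols)
            db = dpre_flat.sum(axis=(0, 1))
            dcols = dpre_flat @ self.W[layer]
            da = _col2im(dcols, cache["inputs"][layer].shape)
            conv_grads = [dW, db] + conv_grads
        return conv_grads + [dWd, dbd]

    def _params(self) -> List[np.ndarray]:
        out: List[np.ndarray] = []
        for W, b in zip(self.W, self.b):
            out += [W, b]
        out += [self.Wd, self.bd]
        return out

    # ------------------------------------------------------------------- fit
    def fit(self, X: np.ndarray, Y: np.ndarray, config: TrainConfig,
            augment_fn=None) -> List[float]:
        """Train with summed BCE-with-logits; returns mean loss per epoch."""
        n = len(X)
        rng = np.random.default_rng(config.seed)
        opt = _Adam(self._params(), lr=config.learning_rate)
        history: List[float] = []
        for _ in range(config.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, config.batch_size):
                sel = order[start : start + config.batch_size]
                xb = X[sel]
                if augment_fn is not None:
                    xb = np.stack([augment_fn(im, rng) for im in xb])
                yb = Y[sel]
                logits, cache = self._forward(xb, keep=True)
                losses.append(float(np.mean(
                    [multi_target_loss(u, y) for u, y in zip(logits, yb)]
                )))
                # d/du of summed BCE-with-logits, averaged over the batch
                dlogits = (1.0 / (1.0 + np.exp(-logits)) - yb) / len(sel)
                opt.step(self._backward(cache, dlogits))
            history.append(float(np.mean(losses)))
        return history

    # ---------------------------------------------------------- persistence
    def save(self, path) -> None:
        arrays = {f"W{i}": W for i, W in enumerate(self.W)}
        arrays |= {f"b{i}": b for i, b in enumerate(self.b)}
        arrays |= {"Wd": self.Wd, "bd": self.bd,
                   "meta": np.array([self.side, self.n_outputs, self.seed])}
        arrays |= {"channels": np.array(self.channels)}
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SmallCNN":
        data = np.load(path)
        side, n_outputs, seed = (int(v) for v in data["meta"])
        model = cls(side=side, channels=tuple(int(c) for c in data["channels"]),
                    n_outputs=n_outputs, seed=seed)
        model.W = [data[f"W{i}"] for i in range(len(model.W))]
        model.b = [data[f"b{i}"] for i in range(len(model.b))]
        model.Wd, model.bd = data["Wd"], data["bd"]
        return model

    # -------------------------------------------------------------- grad-cam
    def feature_maps_and_grads(self, image: np.ndarray, finding: int):
        """Last-conv feature maps and d(logit_finding)/d(maps) for one image."""
        logits, cache = self._forward(image[None], keep=True)
        maps = cache["last_maps"][0]  # (C, H', W')
        grad = self.Wd[finding].reshape(maps.shape)
        return maps, grad
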