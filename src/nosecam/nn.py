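"""Minimal deterministic CNN engine in NumPy.

The classification problems here are tiny (tens of samples, 40 x 14 x 3
inputs), so a compact, fully seeded NumPy implementation is the most
reproducible way to run them: single-threaded, bitwise-deterministic
given the seed, no framework nondeterminism.

Architecture (fixed topology, configurable sizes): a stack of
3x3 "same"-padded conv + ReLU blocks, each followed by 2x1 max-pooling
over the time axis, then flatten, one ReLU dense layer (optional
inverted dropout), and a softmax output.  Trained with Adam on
cross-entropy.  The post-ReLU output of the LAST conv layer is exposed
as the activation maps consumed by Score-CAM.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SmallCNN"]


def _conv2d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """'same' 2-D convolution, stride 1.  x: (N,H,W,Cin), w: (kh,kw,Cin,Cout)."""
    kh, kw = w.shape[:2]
    ph, pw = kh // 2, kw // 2
    n, h, wd, _ = x.shape
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    out = np.zeros((n, h, wd, w.shape[3]))
    for di in range(kh):
        for dj in range(kw):
            out += xp[:, di:di + h, dj:dj + wd, :] @ w[di, dj]
    return out + b


def _conv2d_same_backward(
    x: np.ndarray, w: np.ndarray, dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    kh, kw = w.shape[:2]
    ph, pw = kh // 2, kw // 2
    n, h, wd, _ = x.shape
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    for di in range(kh):
        for dj in range(kw):
            patch = xp[:, di:di + h, dj:dj + wd, :]
            dw[di, dj] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, di:di + h, dj:dj + wd, :] += dout @ w[di, dj].T
    db = dout.sum(axis=(0, 1, 2))
    dx = dxp[:, ph:ph + h, pw:pw + wd, :] if (ph or pw) else dxp
    return dx, dw, db


def _maxpool_time2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x1 max pool over the time (H) axis.  Returns (pooled, argmax mask)."""
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w, c)
    out = xr.max(axis=2)
    mask = xr == out[:, :, None, :, :]
    # break ties toward the first element so the gradient is not duplicated
    mask[:, :, 1, :, :] &= ~mask[:, :, 0, :, :]
    return out, mask


def _maxpool_time2_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n, hh, w, c = dout.shape
    dxr = mask * dout[:, :, None, :, :]
    return dxr.reshape(n, hh * 2, w, c)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCNN:
    """Seeded NumPy CNN for 40 x 14 x 3 sensor tensors.

    Parameters
    ----------
    input_shape : (H, W, C)
    conv_filters : filter counts per conv block; the last entry is the
        number of activation maps exposed to Score-CAM.
    kernel : conv kernel size (odd, 'same' padding).
    dense : width of the hidden dense layer.
    n_classes : output classes.
    seed : initialization/shuffling/dropout seed.
    lr : Adam learning rate.
    dropout : inverted-dropout rate on the dense layer during training.
    """

    def __init__(
        self,
        input_shape: tuple[int, int, int],
        conv_filters: tuple[int, ...],
        kernel: tuple[int, int],
        dense: int,
        n_classes: int,
        seed: int = 0,
        lr: float = 1e-3,
        dropout: float = 0.0,
    ) -> None:
        h, w, c = input_shape
        if any(k % 2 == 0 for k in kernel):
            raise ValueError("kernel dimensions must be odd for 'same' padding")
        if h % (2 ** len(conv_filters)) != 0:
            raise ValueError("time dimension must be divisible by 2 per conv block")
        self.input_shape = input_shape
        self.conv_filters = tuple(conv_filters)
        self.kernel = tuple(kernel)
        self.n_classes = n_classes
        self.lr = lr
        self.dropout = dropout
        self.seed = seed
        self.loss_history: list[float] = []

        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        cin = c
        kh, kw = kernel
        for i, cout in enumerate(conv_filters):
            fan_in = kh * kw * cin
            self.params[f"Wc{i}"] = rng.normal(0, np.sqrt(2.0 / fan_in), (kh, kw, cin, cout))
            self.params[f"bc{i}"] = np.zeros(cout)
            cin = cout
        self._flat_dim = (h // 2 ** len(conv_filters)) * w * conv_filters[-1]
        self.params["Wd"] = rng.normal(0, np.sqrt(2.0 / self._flat_dim), (self._flat_dim, dense))
        self.params["bd"] = np.zeros(dense)
        self.params["Wo"] = rng.normal(0, np.sqrt(2.0 / dense), (dense, n_classes))
        self.params["bo"] = np.zeros(n_classes)
        # Adam state
        self._m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._t = 0

    # -- forward ---------------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool = False, drop_rng=None):
        cache: dict = {"x": x, "convs": []}
        a = x
        for i in range(len(self.conv_filters)):
            z = _conv2d_same(a, self.params[f"Wc{i}"], self.params[f"bc{i}"])
            r = np.maximum(z, 0.0)
            p, mask = _maxpool_time2(r)
            cache["convs"].append({"a_in": a, "z": z, "r": r, "mask": mask})
            a = p
        cache["last_maps"] = cache["convs"][-1]["r"]  # (N, h_f, w_f, K) pre-pool
        flat = a.reshape(a.shape[0], -1)
        cache["flat"] = flat
        hd = flat @ self.params["Wd"] + self.params["bd"]
        rd = np.maximum(hd, 0.0)
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            dmask = (drop_rng.random(rd.shape) < keep) / keep
            rd = rd * dmask
            cache["dmask"] = dmask
        cache["hd"] = hd
        cache["rd"] = rd
        logits = rd @ self.params["Wo"] + self.params["bo"]
        cache["logits"] = logits
        probs = _softmax(logits)
        return probs, cache

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch (N, H, W, C) or single (H, W, C)."""
        x = np.asarray(x, float)
        single = x.ndim == 3
        if single:
            x = x[None]
        probs, _ = self._forward(x)
        return probs[0] if single else probs

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        single = x.ndim == 3
        if single:
            x = x[None]
        _, cache = self._forward(x)
        return cache["logits"][0] if single else cache["logits"]

    def activation_maps(self, x: np.ndarray) -> np.ndarray:
        """Post-ReLU maps of the final conv layer for ONE input: (K, h_f, w_f)."""
        x = np.asarray(x, float)
        if x.ndim != 3:
            raise ValueError("activation_maps expects a single (H, W, C) input")
        _, cache = self._forward(x[None])
        return np.moveaxis(cache["last_maps"][0], -1, 0)

    # -- backward / training ---------------------------------------------

    def _backward(self, cache: dict, y_onehot: np.ndarray) -> dict[str, np.ndarray]:
        n = y_onehot.shape[0]
        probs = _softmax(cache["logits"])
        dlogits = (probs - y_onehot) / n
        grads: dict[str, np.ndarray] = {}
        grads["Wo"] = cache["rd"].T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        drd = dlogits @ self.params["Wo"].T
        if "dmask" in cache:
            drd = drd * cache["dmask"]
        dhd = drd * (cache["hd"] > 0)
        grads["Wd"] = cache["flat"].T @ dhd
        grads["bd"] = dhd.sum(axis=0)
        dflat = dhd @ self.params["Wd"].T
        n_blocks = len(self.conv_filters)
        last = cache["convs"][-1]
        pooled_shape = (n, last["r"].shape[1] // 2, last["r"].shape[2], last["r"].shape[3])
        da = dflat.reshape(pooled_shape)
        for i in range(n_blocks - 1, -1, -1):
            blk = cache["convs"][i]
            dr = _maxpool_time2_backward(da, blk["mask"])
            dz = dr * (blk["z"] > 0)
            da, dw, db = _conv2d_same_backward(blk["a_in"], self.params[f"Wc{i}"], dz)
            grads[f"Wc{i}"] = dw
            grads[f"bc{i}"] = db
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        self._t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self._m[k] = b1 * self._m[k] + (1 - b1) * g
            self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            mhat = self._m[k] / (1 - b1 ** self._t)
            vhat = self._v[k] / (1 - b2 ** self._t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 30,
        batch_size: int = 8,
    ) -> "SmallCNN":
        """Train on (N, H, W, C) inputs and integer labels in 0..K-1.

        Per-epoch shuffling, dropout and everything else derive from the
        model seed, so training is a pure function of (weights-at-init,
        data, epochs, batch_size).
        """
        x = np.asarray(x, float)
        y = np.asarray(y, int)
        n = x.shape[0]
        onehot = np.eye(self.n_classes)[y]
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x7EA1]))
        self.loss_history = []
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                probs, cache = self._forward(x[idx], train=True, drop_rng=rng)
                eps = 1e-12
                loss = -np.mean(np.sum(onehot[idx] * np.log(probs + eps), axis=1))
                epoch_loss += loss * len(idx)
                grads = self._backward(cache, onehot[idx])
                self._adam_step(grads)
            self.loss_history.append(epoch_loss / n)
        return self
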