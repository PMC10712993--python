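"""A small fully-convolutional per-sample classifier, implemented in numpy.

Architecture (all "same" padding, applied per time sample):

    conv(k, F) -> ReLU -> conv(k, F) -> ReLU -> dropout
    -> dense(D) (1x1 conv) -> ReLU -> linear(3) -> softmax

The network maps a 2048-sample ECG segment to a 2048 x 3 matrix of class
probabilities over {none, normal QRS, PVC QRS}.  Training uses Adam on a
class-weighted cross-entropy (the "none" class dominates the per-sample
label distribution, so classes are reweighted by inverse frequency).

Everything is seeded and, on a single thread, bit-reproducible; the final
layer is zero-initialised so an untrained network outputs exactly uniform
probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

__all__ = ["NetworkConfig", "PvcNet", "train", "CLASS_NONE", "CLASS_NORMAL", "CLASS_PVC", "CLASS_NAMES"]

CLASS_NONE, CLASS_NORMAL, CLASS_PVC = 0, 1, 2
CLASS_NAMES = ("none", "normal_qrs", "pvc_qrs")


@dataclass(frozen=True)
class NetworkConfig:
    n_filters: int = 16
    kernel: int = 9
    dropout: float = 0.3
    dense: int = 32
    n_classes: int = 3
    learning_rate: float = 1e-3
    epochs: int = 8
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != 3:
            raise ValueError("the detector is a 3-class model")
        if self.kernel % 2 != 1:
            raise ValueError("kernel length must be odd (same padding)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, k: int):
    """x: (B, L, Cin); W: (Cin*k, Cout).  Returns (out, cols) with
    out (B, L, Cout)."""
    B, L, Cin = x.shape
    p = k // 2
    xp = np.zeros((B, L + 2 * p, Cin))
    xp[:, p : p + L] = x
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B, L, Cin, k)
    cols = cols.reshape(B * L, Cin * k)
    out = (cols @ W + b).reshape(B, L, -1)
    return out, cols


def _conv_backward_input(dout: np.ndarray, W: np.ndarray, k: int, Cin: int):
    """dout: (B, L, Cout) -> gradient w.r.t. the conv input (B, L, Cin)."""
    B, L, Cout = dout.shape
    p = k // 2
    dcols = (dout.reshape(B * L, Cout) @ W.T).reshape(B, L, Cin, k)
    dxp = np.zeros((B, L + 2 * p, Cin))
    for j in range(k):
        dxp[:, j : j + L] += dcols[:, :, :, j]
    return dxp[:, p : p + L]


class PvcNet:
    """Trainable per-sample classifier; see module docstring."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k, F, D, C = config.kernel, config.n_filters, config.dense, config.n_classes
        he = lambda fan_in, shape: rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)
        self.params = {
            "W1": he(k, (1 * k, F)),
            "b1": np.zeros(F),
            "W2": he(F * k, (F * k, F)),
            "b2": np.zeros(F),
            "W3": he(F, (F, D)),
            "b3": np.zeros(D),
            "W4": np.zeros((D, C)),  # zero init -> uniform softmax untrained
            "b4": np.zeros(C),
        }
        self._adam_m = {n: np.zeros_like(v) for n, v in self.params.items()}
        self._adam_v = {n: np.zeros_like(v) for n, v in self.params.items()}
        self._adam_t = 0
        self.history: list[float] = []

    # ---------------------------------------------------------------- forward

    def _forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        """x: (B, L).  Returns softmax probabilities and a cache for backprop.
        Dropout is active only when an rng is supplied (training mode)."""
        cfg = self.config
        k = cfg.kernel
        x3 = x[:, :, None]
        z1, cols1 = _conv_forward(x3, self.params["W1"], self.params["b1"], k)
        h1 = np.maximum(z1, 0.0)
        z2, cols2 = _conv_forward(h1, self.params["W2"], self.params["b2"], k)
        h2 = np.maximum(z2, 0.0)
        if rng is not None and cfg.dropout > 0:
            mask = (rng.random(h2.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            h2d = h2 * mask
        else:
            mask = None
            h2d = h2
        z3 = h2d @ self.params["W3"] + self.params["b3"]
        h3 = np.maximum(z3, 0.0)
        logits = h3 @ self.params["W4"] + self.params["b4"]
        logits -= logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=-1, keepdims=True)
        cache = (x3, cols1, z1, h1, cols2, z2, h2, mask, h2d, z3, h3)
        return probs, cache

    def predict_proba(self, segments: np.ndarray, chunk: int = 64) -> np.ndarray:
        """Class probabilities for (n, 2048) segments -> (n, 2048, 3)."""
        segments = np.atleast_2d(np.asarray(segments, dtype=float))
        out = np.empty((segments.shape[0], segments.shape[1], self.config.n_classes))
        for i in range(0, len(segments), chunk):
            out[i : i + chunk], _ = self._forward(segments[i : i + chunk])
        return out

    # --------------------------------------------------------------- training

    def _step(self, x: np.ndarray, y: np.ndarray, class_w: np.ndarray, rng: np.random.Generator) -> float:
        cfg = self.config
        k, F = cfg.kernel, cfg.n_filters
        B, L = x.shape
        probs, cache = self._forward(x, rng=rng)
        x3, cols1, z1, h1, cols2, z2, h2, mask, h2d, z3, h3 = cache

        w = class_w[y]  # (B, L)
        wsum = w.sum()
        p_true = np.take_along_axis(probs, y[:, :, None], axis=-1)[:, :, 0]
        loss = float((w * -np.log(np.clip(p_true, 1e-12, None))).sum() / wsum)

        dlogits = probs.copy()
        np.put_along_axis(dlogits, y[:, :, None], np.take_along_axis(dlogits, y[:, :, None], axis=-1) - 1.0, axis=-1)
        dlogits *= (w / wsum)[:, :, None]

        g = {}
        flat = lambda a: a.reshape(B * L, -1)
        g["W4"] = flat(h3).T @ flat(dlogits)
        g["b4"] = dlogits.sum((0, 1))
        dh3 = dlogits @ self.params["W4"].T
        dz3 = dh3 * (z3 > 0)
        g["W3"] = flat(h2d).T @ flat(dz3)
        g["b3"] = dz3.sum((0, 1))
        dh2d = dz3 @ self.params["W3"].T
        dh2 = dh2d * mask if mask is not None else dh2d
        dz2 = dh2 * (z2 > 0)
        g["W2"] = cols2.T @ flat(dz2)
        g["b2"] = dz2.sum((0, 1))
        dh1 = _conv_backward_input(dz2, self.params["W2"], k, F)
        dz1 = dh1 * (z1 > 0)
        g["W1"] = cols1.T @ flat(dz1)
        g["b1"] = dz1.sum((0, 1))

        self._adam_t += 1
        b1m, b2m, eps = 0.9, 0.999, 1e-8
        lr = cfg.learning_rate
        t = self._adam_t
        for name, grad in g.items():
            m = self._adam_m[name] = b1m * self._adam_m[name] + (1 - b1m) * grad
            v = self._adam_v[name] = b2m * self._adam_v[name] + (1 - b2m) * grad**2
            mhat = m / (1 - b1m**t)
            vhat = v / (1 - b2m**t)
            self.params[name] -= lr * mhat / (np.sqrt(vhat) + eps)
        return loss

    # ------------------------------------------------------------ persistence

    def save(self, path) -> None:
        """Serialize weights + config to an .npz checkpoint."""
        np.savez(path, config=json.dumps(asdict(self.config)), **self.params)

    @classmethod
    def load(cls, path) -> "PvcNet":
        data = np.load(path, allow_pickle=False)
        config = NetworkConfig(**json.loads(str(data["config"])))
        net = cls(config)
        for name in net.params:
            net.params[name] = data[name]
        return net


def train(config: NetworkConfig, segments: np.ndarray, masks: np.ndarray) -> PvcNet:
    """Train a detector on (n, 2048) segments with (n, 2048) int class masks.

    Raises ``ValueError`` naming any class absent from the training masks.
    With ``config.epochs == 0`` the initialised (uniform-output) network is
    returned — the sanity path for testing the inference plumbing.
    """
    segments = np.atleast_2d(np.asarray(segments, dtype=float))
    masks = np.atleast_2d(np.asarray(masks, dtype=np.int64))
    if segments.shape != masks.shape:
        raise ValueError("segments and masks must have identical shapes")
    present = np.unique(masks)
    missing = [CLASS_NAMES[c] for c in range(config.n_classes) if c not in present]
    if missing:
        raise ValueError(f"training data contains no samples of class(es): {missing}")

    counts = np.bincount(masks.reshape(-1), minlength=config.n_classes).astype(float)
    class_w = counts.sum() / (config.n_classes * np.maximum(counts, 1.0))

    net = PvcNet(config)
    rng = np.random.default_rng(config.seed + 1)
    n = len(segments)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            losses.append(net._step(segments[idx], masks[idx], class_w, rng))
        net.history.append(float(np.mean(losses)))
    return net
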