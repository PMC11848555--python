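"""Fingerprint neural network: locally connected extraction + bilinear interaction.

The classifier takes a fixed-length fingerprint vector (aligned signal
intensities zero-padded to ``input_length``, 144 by default = 134 signals +
10 padding cells) and runs it through

* a feature-extraction stage: two locally connected 1-D layers (kernel 3,
  stride 1, 16 then 32 channels, ReLU).  Unlike convolutions, locally
  connected layers share no weights across positions, so every m/z signal
  gets its own filter bank — in effect a learned per-signal nonlinear
  rescaling plus local context, which matters for highly skewed intensity
  distributions;
* a non-linear feature-interaction stage: the element-wise product of two
  learned linear projections of the flattened features (a bilinear form)
  with dropout; and
* a softmax classification head emitting a two-class probability.

Implemented directly in NumPy with hand-written backpropagation and Adam.
Training is fully deterministic for a fixed seed (seeded init, seeded
shuffling and dropout, ordered batches), and the backward pass exposes
exact gradients with respect to the *input* vector, which the
integrated-gradients attribution in :mod:`smfkit.panel` consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NNArchitecture", "NeuralNetClassifier", "fit_nn"]


@dataclass
class NNArchitecture:
    """Hyperparameters of the fingerprint network.

    Training defaults: batch 32, 200 epochs, dropout 0.25, Adam at 1e-3.
    """

    input_length: int = 144
    input_compression: str = "asinh"  # smooth dynamic-range compression
    compression_gain: float = 10.0
    channels: tuple[int, int] = (16, 32)
    kernel: int = 3
    interaction_dim: int = 32
    pool_positions: bool = True  # average channel responses over positions
    drop_rate: float = 0.25
    batch_size: int = 32
    epochs: int = 200
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3  # decoupled L2, scaled by the learning rate
    seed: int = 0


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """x (N, C, L) -> (L_out, N, C*k) window view, L_out = L - k + 1."""
    n, c, length = x.shape
    l_out = length - k + 1
    cols = np.empty((l_out, n, c * k), dtype=x.dtype)
    for j in range(k):
        cols[:, :, j * c:(j + 1) * c] = x[:, :, j:j + l_out].transpose(2, 0, 1)
    return cols


def _local_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, k: int):
    """Locally connected layer: per-position weights.

    x (N, C_in, L); w (L_out, C_out, C_in*k); b (L_out, C_out).
    Returns y (N, C_out, L_out) and the cached column view.
    """
    cols = _im2col(x, k)  # (L_out, N, D)
    y = np.matmul(cols, w.transpose(0, 2, 1)) + b[:, None, :]  # (L_out, N, C_out)
    return y.transpose(1, 2, 0), cols


def _local_backward(dy: np.ndarray, cols: np.ndarray, w: np.ndarray,
                    x_shape: tuple, k: int):
    n, c_in, length = x_shape
    l_out = length - k + 1
    dyt = dy.transpose(2, 0, 1)  # (L_out, N, C_out)
    dw = np.matmul(dyt.transpose(0, 2, 1), cols)  # (L_out, C_out, D)
    db = dyt.sum(axis=1)  # (L_out, C_out)
    dcols = np.matmul(dyt, w)  # (L_out, N, D)
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    for j in range(k):
        dx[:, :, j:j + l_out] += dcols[:, :, j * c_in:(j + 1) * c_in].transpose(1, 2, 0)
    return dx, dw, db


class NeuralNetClassifier:
    """Two-class fingerprint network with exact input gradients.

    Expects standardized features; inputs shorter than ``input_length`` are
    zero-padded on the right (padding cells stay exactly 0 and receive no
    attribution).
    """

    def __init__(self, arch: NNArchitecture | None = None):
        self.arch = arch or NNArchitecture()
        self.n_features_: int | None = None
        self._params: dict[str, np.ndarray] = {}

    # -- parameters --------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        a = self.arch
        c1, c2 = a.channels
        k = a.kernel
        l1 = a.input_length - k + 1
        l2 = l1 - k + 1
        self._l2 = l2
        flat = c2 if a.pool_positions else c2 * l2
        h = a.interaction_dim

        shapes = {
            "w1": (l1, c1, 1 * k), "b1": (l1, c1),
            "w2": (l2, c2, c1 * k), "b2": (l2, c2),
            "wa": (h, flat), "ba": (h,),
            "wb": (h, flat), "bb": (h,),
            "wo": (2, h), "bo": (2,),
        }
        fan_in = {"w1": k, "w2": c1 * k, "wa": flat, "wb": flat, "wo": h}
        # single flat buffer so the optimizer updates all weights in one op
        total = sum(int(np.prod(s)) for s in shapes.values())
        self._theta = np.zeros(total, dtype=np.float32)
        self._params = {}
        offset = 0
        for name, shape in shapes.items():
            size = int(np.prod(shape))
            view = self._theta[offset:offset + size].reshape(shape)
            if name in fan_in:
                view[...] = rng.normal(0.0, np.sqrt(2.0 / fan_in[name]), size=shape).astype(np.float32)
            elif name == "bb":
                view[...] = 1.0  # near-linear start for the bilinear stage
            self._params[name] = view
            offset += size

    def _pad(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 1:
            x = x[None, :]
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite values in input features")
        n_feat = x.shape[1]
        if n_feat > self.arch.input_length:
            raise ValueError(
                f"{n_feat} features exceed input_length {self.arch.input_length}")
        if n_feat < self.arch.input_length:
            x = np.pad(x, ((0, 0), (0, self.arch.input_length - n_feat)))
        return x

    # -- forward / backward ------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool,
                 rng: np.random.Generator | None = None):
        a, p = self.arch, self._params
        cache: dict = {}
        if a.input_compression == "asinh":
            cache["x_raw"] = x
            g = np.float32(a.compression_gain)
            x = np.arcsinh(g * x) / np.arcsinh(g)
        h0 = x[:, None, :]  # (N, 1, L)
        z1, cache["cols1"] = _local_forward(h0, p["w1"], p["b1"], a.kernel)
        r1 = np.maximum(z1, 0.0)
        z2, cache["cols2"] = _local_forward(r1, p["w2"], p["b2"], a.kernel)
        r2 = np.maximum(z2, 0.0)
        # bridge: either mean over positions (additive-model bias, the
        # default) or a full flatten of the position x channel map
        flat = r2.mean(axis=2) if a.pool_positions else r2.reshape(len(x), -1)
        u = flat @ p["wa"].T + p["ba"]
        v = flat @ p["wb"].T + p["bb"]
        z = u * v
        if train and a.drop_rate > 0:
            mask = ((rng.uniform(size=z.shape) >= a.drop_rate)
                    .astype(np.float32) / np.float32(1.0 - a.drop_rate))
            z = z * mask
            cache["mask"] = mask
        logits = z @ p["wo"].T + p["bo"]
        shifted = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(shifted)
        proba = expz / expz.sum(axis=1, keepdims=True)
        cache.update(h0=h0, z1=z1, r1=r1, z2=z2, r2=r2, flat=flat,
                     u=u, v=v, z=z, proba=proba)
        return proba, cache

    def _backward_from_dz(self, dlogits: np.ndarray, cache: dict,
                          accumulate_params: bool):
        """Backprop dlogits down to the input; optionally collect parameter grads."""
        a, p = self.arch, self._params
        grads: dict[str, np.ndarray] = {}
        z = cache["z"]
        if accumulate_params:
            grads["wo"] = dlogits.T @ z
            grads["bo"] = dlogits.sum(axis=0)
        dz = dlogits @ p["wo"]
        if "mask" in cache:
            dz = dz * cache["mask"]
        du = dz * cache["v"]
        dv = dz * cache["u"]
        flat = cache["flat"]
        if accumulate_params:
            grads["wa"] = du.T @ flat
            grads["ba"] = du.sum(axis=0)
            grads["wb"] = dv.T @ flat
            grads["bb"] = dv.sum(axis=0)
        dflat = du @ p["wa"] + dv @ p["wb"]
        r2_shape = cache["r2"].shape
        if a.pool_positions:
            dr2 = np.repeat(dflat[:, :, None], r2_shape[2], axis=2) / r2_shape[2]
        else:
            dr2 = dflat.reshape(r2_shape)
        dz2 = dr2 * (cache["z2"] > 0)
        dr1, dw2, db2 = _local_backward(dz2, cache["cols2"], p["w2"],
                                        cache["r1"].shape, a.kernel)
        if accumulate_params:
            grads["w2"], grads["b2"] = dw2, db2
        dz1 = dr1 * (cache["z1"] > 0)
        dh0, dw1, db1 = _local_backward(dz1, cache["cols1"], p["w1"],
                                        cache["h0"].shape, a.kernel)
        if accumulate_params:
            grads["w1"], grads["b1"] = dw1, db1
        dx = dh0[:, 0, :]
        if a.input_compression == "asinh":
            # d asinh(gx)/dx = g / sqrt(1 + (gx)^2)
            g = np.float32(a.compression_gain)
            dx = dx * (g / np.arcsinh(g)) / np.sqrt(1.0 + (g * cache["x_raw"]) ** 2)
        return dx, grads

    # -- training ----------------------------------------------------------

    def fit(self, x: np.ndarray, y: np.ndarray) -> "NeuralNetClassifier":
        a = self.arch
        x = np.asarray(x, dtype=float)
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        self.n_features_ = x.shape[1]
        xp = self._pad(x)
        rng = np.random.default_rng(a.seed)
        self._init_params(rng)
        grad_flat = np.zeros_like(self._theta)
        grad_views = {}
        offset = 0
        for name, par in self._params.items():
            grad_views[name] = grad_flat[offset:offset + par.size].reshape(par.shape)
            offset += par.size
        m = np.zeros_like(self._theta)
        v2 = np.zeros_like(self._theta)
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = len(xp)
        onehot = np.eye(2, dtype=np.float32)[y]
        for _ in range(a.epochs):
            order = rng.permutation(n)
            for start in range(0, n, a.batch_size):
                idx = order[start:start + a.batch_size]
                proba, cache = self._forward(xp[idx], train=True, rng=rng)
                dlogits = (proba - onehot[idx]) / len(idx)
                _, grads = self._backward_from_dz(dlogits, cache,
                                                  accumulate_params=True)
                for key, g in grads.items():
                    grad_views[key][...] = g
                t += 1
                m *= beta1
                m += (1 - beta1) * grad_flat
                v2 *= beta2
                v2 += (1 - beta2) * grad_flat * grad_flat
                step = a.learning_rate / (1 - beta1 ** t)
                denom = np.sqrt(v2 / (1 - beta2 ** t)) + eps
                self._theta -= step * m / denom
                if a.weight_decay > 0:
                    self._theta *= np.float32(1.0 - a.learning_rate * a.weight_decay)
        return self

    # -- inference ---------------------------------------------------------

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        proba, _ = self._forward(self._pad(np.atleast_2d(x)), train=False)
        return proba

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        """Class-1 (case) probability per sample."""
        return self.predict_proba(x)[:, 1]

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.decision_scores(x) >= 0.5).astype(int)

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """Exact gradient of the class-1 probability w.r.t. each input cell.

        Padding columns are stripped, so the result matches the original
        feature dimension.
        """
        x2 = np.atleast_2d(np.asarray(x, dtype=float))
        xp = self._pad(x2)
        proba, cache = self._forward(xp, train=False)
        # d p1 / d logits = p1 * (e1 - p)
        p1 = proba[:, 1][:, None]
        dlogits = p1 * (np.eye(2)[1][None, :] - proba)
        dx, _ = self._backward_from_dz(dlogits, cache, accumulate_params=False)
        n_feat = self.n_features_ or x2.shape[1]
        return dx[:, :n_feat]


def fit_nn(x: np.ndarray, y: np.ndarray,
           arch: NNArchitecture | None = None) -> NeuralNetClassifier:
    """Train the fingerprint network on standardized features.

    Returns a fitted :class:`NeuralNetClassifier` whose
    :meth:`~NeuralNetClassifier.decision_scores` maps feature vectors to
    case probabilities.
    """
    return NeuralNetClassifier(arch).fit(x, y)
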