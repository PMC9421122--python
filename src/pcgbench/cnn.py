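"""The fixed small CNN used by every experiment arm.

Architecture (identical across arms, asserted by hash): conv 32x(3x3) stride 1,
ReLU -> maxpool 2x2 stride 2 -> conv 64x(3x3) stride 1, ReLU -> maxpool 2x2
stride 2 -> flatten -> dense 64, ReLU -> dense 1, sigmoid. No padding in any
layer. Trained with Adam on binary cross-entropy for 10 epochs; batch size 32,
learning rate 1e-3; pixel intensities scaled to [0, 1].

Implemented directly in numpy: convolutions are im2col + matrix products, so
training runs on BLAS. Gradients for the first convolution's input are never
needed and are skipped. All weights are float32; initialization is He-normal
from a per-training seed, so training is deterministic for a fixed seed and
example order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

try:  # fused elementwise/pooling kernels; numpy fallbacks below are equivalent
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

_K = 3  # kernel size, fixed by the architecture


@dataclass(frozen=True)
class ModelSpec:
    n_filters1: int = 32
    n_filters2: int = 64
    kernel: int = 3
    pool: int = 2
    hidden_units: int = 64
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3

    def architecture_hash(self) -> str:
        """Hash of the architecture+training recipe; equal across arms."""
        payload = json.dumps(self.__dict__, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def conv_output_shape(h: int, w: int, k: int = _K) -> tuple[int, int]:
    if h < k or w < k:
        raise ValueError("input spatially smaller than the kernel")
    return h - k + 1, w - k + 1


def pool_output_shape(h: int, w: int, p: int = 2) -> tuple[int, int]:
    if h < p or w < p:
        raise ValueError("input spatially smaller than the pooling window")
    return h // p, w // p


def layer_shapes(spec: ModelSpec, input_shape: tuple[int, int, int] = (100, 180, 3)) -> list:
    """Output shape of every stage for a given input (valid conv, floor pool)."""
    h, w, _ = input_shape
    shapes = []
    h, w = conv_output_shape(h, w, spec.kernel)
    shapes.append((h, w, spec.n_filters1))
    h, w = pool_output_shape(h, w, spec.pool)
    shapes.append((h, w, spec.n_filters1))
    h, w = conv_output_shape(h, w, spec.kernel)
    shapes.append((h, w, spec.n_filters2))
    h, w = pool_output_shape(h, w, spec.pool)
    shapes.append((h, w, spec.n_filters2))
    shapes.append(h * w * spec.n_filters2)
    shapes.append(spec.hidden_units)
    shapes.append(1)
    return shapes


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N, H-k+1, W-k+1, k*k*C) patch matrix (kh, kw, C order)."""
    n, h, w, c = x.shape
    h2, w2 = h - k + 1, w - k + 1
    out = np.empty((n, h2, w2, k * k, c), dtype=x.dtype)
    pos = 0
    for di in range(k):
        for dj in range(k):
            out[:, :, :, pos, :] = x[:, di : di + h2, dj : dj + w2, :]
            pos += 1
    return out.reshape(n, h2, w2, k * k * c)


_POOL_OFFSETS = ((0, 0), (0, 1), (1, 0), (1, 1))


def _bias_relu_pool_np(a: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """In-place bias + ReLU on ``a``, returning the 2x2/stride-2 max pool."""
    a += bias
    np.maximum(a, 0.0, out=a)
    h2, w2 = a.shape[1] // 2, a.shape[2] // 2
    out = None
    for di, dj in _POOL_OFFSETS:
        s = a[:, di : 2 * h2 : 2, dj : 2 * w2 : 2, :]
        out = s.copy() if out is None else np.maximum(out, s, out=out)
    return out


def _pool_relu_grad_np(dout: np.ndarray, a: np.ndarray, pooled: np.ndarray) -> np.ndarray:
    """Pool gradient routed to the first maximal cell, masked by ReLU (a > 0)."""
    h2, w2 = pooled.shape[1], pooled.shape[2]
    dx = np.zeros_like(a)
    claimed = np.zeros(pooled.shape, dtype=bool)
    for di, dj in _POOL_OFFSETS:
        view = a[:, di : 2 * h2 : 2, dj : 2 * w2 : 2, :]
        m = (view == pooled) & ~claimed
        np.copyto(dx[:, di : 2 * h2 : 2, dj : 2 * w2 : 2, :], dout, where=m)
        claimed |= m
    dx *= a > 0
    return dx


def _col2im_np(dcols: np.ndarray, k: int, in_shape) -> np.ndarray:
    n, h, w, c = in_shape
    h2, w2 = h - k + 1, w - k + 1
    dcols = dcols.reshape(n, h2, w2, k * k, c)
    dx = np.zeros(in_shape, dtype=dcols.dtype)
    pos = 0
    for di in range(k):
        for dj in range(k):
            dx[:, di : di + h2, dj : dj + w2, :] += dcols[:, :, :, pos, :]
            pos += 1
    return dx


def _adam_update_np(p, g, m, v, lr_t, b1, b2, eps):
    m *= b1
    m += (1 - b1) * g
    v *= b2
    v += (1 - b2) * g * g
    p -= lr_t * m / (np.sqrt(v) + eps)


if _HAVE_NUMBA:

    @numba.njit(fastmath=False)
    def _bias_relu_pool_nb(a, bias, pooled):  # pragma: no cover - numba
        n, h, w, c = a.shape
        h2, w2 = h // 2, w // 2
        for img in range(n):
            for i in range(h):
                for j in range(w):
                    for ch in range(c):
                        val = a[img, i, j, ch] + bias[ch]
                        if val < 0.0:
                            val = 0.0
                        a[img, i, j, ch] = val
                        if i < 2 * h2 and j < 2 * w2:
                            if i % 2 == 0 and j % 2 == 0:
                                pooled[img, i // 2, j // 2, ch] = val
                            elif val > pooled[img, i // 2, j // 2, ch]:
                                pooled[img, i // 2, j // 2, ch] = val

    @numba.njit(fastmath=False)
    def _pool_relu_grad_nb(dout, a, dx):  # pragma: no cover - numba
        n, h, w, c = a.shape
        h2, w2 = dout.shape[1], dout.shape[2]
        for img in range(n):
            for i2 in range(h2):
                for j2 in range(w2):
                    for ch in range(c):
                        bi, bj = 2 * i2, 2 * j2
                        best = a[img, bi, bj, ch]
                        if a[img, bi, bj + 1, ch] > best:
                            best = a[img, bi, bj + 1, ch]
                            bjj = bj + 1
                        else:
                            bjj = bj
                        bii = bi
                        if a[img, bi + 1, bj, ch] > best:
                            best = a[img, bi + 1, bj, ch]
                            bii, bjj = bi + 1, bj
                        if a[img, bi + 1, bj + 1, ch] > best:
                            best = a[img, bi + 1, bj + 1, ch]
                            bii, bjj = bi + 1, bj + 1
                        if best > 0.0:
                            dx[img, bii, bjj, ch] = dout[img, i2, j2, ch]

    @numba.njit(fastmath=False)
    def _col2im_nb(dcols, k, dx):  # pragma: no cover - numba
        n, h2, w2, _, c = dcols.shape
        for img in range(n):
            for i in range(h2):
                for j in range(w2):
                    pos = 0
                    for di in range(k):
                        for dj in range(k):
                            for ch in range(c):
                                dx[img, i + di, j + dj, ch] += dcols[img, i, j, pos, ch]
                            pos += 1

    @numba.njit(fastmath=False)
    def _adam_update_nb(p, g, m, v, lr_t, b1, b2, eps):  # pragma: no cover - numba
        for i in range(p.size):
            mi = b1 * m[i] + (1 - b1) * g[i]
            vi = b2 * v[i] + (1 - b2) * g[i] * g[i]
            m[i] = mi
            v[i] = vi
            p[i] -= lr_t * mi / (np.sqrt(vi) + eps)


def _bias_relu_pool(a: np.ndarray, bias: np.ndarray) -> np.ndarray:
    if _HAVE_NUMBA:
        n, h, w, c = a.shape
        pooled = np.empty((n, h // 2, w // 2, c), dtype=a.dtype)
        _bias_relu_pool_nb(a, bias, pooled)
        return pooled
    return _bias_relu_pool_np(a, bias)


def _pool_relu_grad(dout: np.ndarray, a: np.ndarray, pooled: np.ndarray) -> np.ndarray:
    if _HAVE_NUMBA:
        dx = np.zeros_like(a)
        _pool_relu_grad_nb(dout, a, dx)
        return dx
    return _pool_relu_grad_np(dout, a, pooled)


def _conv_input_grad(dout: np.ndarray, wmat: np.ndarray, k: int, c_in: int, in_shape):
    """Gradient w.r.t. a conv input: one matmul, then col2im scatter-add."""
    n, h, w, _ = in_shape
    h2, w2 = h - k + 1, w - k + 1
    dcols = (dout @ wmat.T).reshape(n, h2, w2, k * k, c_in)
    if _HAVE_NUMBA:
        dx = np.zeros(in_shape, dtype=dcols.dtype)
        _col2im_nb(dcols, k, dx)
        return dx
    return _col2im_np(dcols, k, in_shape)


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        update = _adam_update_nb if _HAVE_NUMBA else _adam_update_np
        for k, g in grads.items():
            update(
                params[k].reshape(-1),
                np.ascontiguousarray(g, dtype=np.float32).reshape(-1),
                self.m[k].reshape(-1),
                self.v[k].reshape(-1),
                np.float32(lr_t),
                np.float32(self.b1),
                np.float32(self.b2),
                np.float32(self.eps),
            )


@dataclass
class TrainedModel:
    spec: ModelSpec
    params: dict
    loss_history: list = field(default_factory=list)
    input_shape: tuple = (100, 180, 3)

    def predict_scores(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Sigmoid scores strictly inside (0, 1), one per image."""
        x = _prepare(images, self.input_shape)
        out = np.empty(x.shape[0], dtype=np.float64)
        for s in range(0, x.shape[0], batch_size):
            z = _forward(x[s : s + batch_size], self.params, self.spec)[0]
            out[s : s + batch_size] = 1.0 / (1.0 + np.exp(-z.astype(np.float64)))
        return np.clip(out, 1e-7, 1.0 - 1e-7)


def _prepare(images: np.ndarray, input_shape) -> np.ndarray:
    x = np.asarray(images)
    if x.ndim == 3:
        x = x[None]
    if x.shape[1:] != tuple(input_shape):
        raise ValueError(f"expected images of shape {input_shape}, got {x.shape[1:]}")
    if x.dtype == np.uint8:
        x = x.astype(np.float32) / 255.0
    return x.astype(np.float32)


def _init_params(spec: ModelSpec, input_shape, rng: np.random.Generator) -> dict:
    k = spec.kernel
    c_in = input_shape[2]
    flat = layer_shapes(spec, input_shape)[4]

    def he(shape, fan_in):
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

    return {
        "w1": he((k * k * c_in, spec.n_filters1), k * k * c_in),
        "b1": np.zeros(spec.n_filters1, dtype=np.float32),
        "w2": he((k * k * spec.n_filters1, spec.n_filters2), k * k * spec.n_filters1),
        "b2": np.zeros(spec.n_filters2, dtype=np.float32),
        "w3": he((flat, spec.hidden_units), flat),
        "b3": np.zeros(spec.hidden_units, dtype=np.float32),
        "w4": he((spec.hidden_units, 1), spec.hidden_units),
        "b4": np.zeros(1, dtype=np.float32),
    }


def _forward(x: np.ndarray, params: dict, spec: ModelSpec, keep: bool = False):
    """Returns logits and, when ``keep``, the activations needed for backprop."""
    k = spec.kernel
    cols1 = _im2col(x, k)
    a1 = cols1 @ params["w1"]
    p1 = _bias_relu_pool(a1, params["b1"])
    cols2 = _im2col(p1, k)
    a2 = cols2 @ params["w2"]
    p2 = _bias_relu_pool(a2, params["b2"])
    flat = p2.reshape(x.shape[0], -1)
    h = np.maximum(flat @ params["w3"] + params["b3"], 0.0)
    z = (h @ params["w4"] + params["b4"])[:, 0]
    if not keep:
        return z, None
    cache = dict(cols1=cols1, a1=a1, p1=p1, cols2=cols2, a2=a2, p2=p2, flat=flat, h=h)
    return z, cache


def _backward(x, y, z, cache, params, spec: ModelSpec) -> dict:
    n = x.shape[0]
    k = spec.kernel
    dz = ((expit(z.astype(np.float64)) - y) / n).astype(np.float32)  # BCE w.r.t. logits
    h, flat = cache["h"], cache["flat"]
    grads = {
        "w4": h.T @ dz[:, None],
        "b4": dz.sum(keepdims=True),
    }
    dh = dz[:, None] @ params["w4"].T
    dh *= h > 0
    grads["w3"] = flat.T @ dh
    grads["b3"] = dh.sum(axis=0)
    dflat = dh @ params["w3"].T
    dp2 = dflat.reshape(cache["p2"].shape)
    da2 = _pool_relu_grad(dp2, cache["a2"], cache["p2"])
    cols2 = cache["cols2"]
    grads["w2"] = cols2.reshape(-1, cols2.shape[3]).T @ da2.reshape(-1, spec.n_filters2)
    grads["b2"] = da2.sum(axis=(0, 1, 2))
    dp1 = _conv_input_grad(da2, params["w2"], k, spec.n_filters1, cache["p1"].shape)
    da1 = _pool_relu_grad(dp1, cache["a1"], cache["p1"])
    cols1 = cache["cols1"]
    grads["w1"] = cols1.reshape(-1, cols1.shape[3]).T @ da1.reshape(-1, spec.n_filters1)
    grads["b1"] = da1.sum(axis=(0, 1, 2))
    return grads


def train(
    spec: ModelSpec,
    images: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    input_shape: tuple[int, int, int] = (100, 180, 3),
) -> TrainedModel:
    """Train the fixed CNN; deterministic for a fixed seed and example order."""
    x = _prepare(images, input_shape)
    y = np.asarray(labels, dtype=np.float32)
    if x.shape[0] != y.shape[0]:
        raise ValueError("images and labels disagree in length")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xC44)))
    params = _init_params(spec, input_shape, rng)
    opt = _Adam(params, spec.learning_rate)
    history = []
    n = x.shape[0]
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, spec.batch_size):
            sel = order[s : s + spec.batch_size]
            xb, yb = x[sel], y[sel]
            z, cache = _forward(xb, params, spec, keep=True)
            zb64 = z.astype(np.float64)
            loss = float(np.mean(np.logaddexp(0.0, zb64) - yb * zb64))
            losses.append(loss * len(sel))
            grads = _backward(xb, yb, z, cache, params, spec)
            opt.step(params, grads)
        history.append(sum(losses) / n)
    return TrainedModel(spec=spec, params=params, loss_history=history, input_shape=input_shape)
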