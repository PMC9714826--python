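"""Seeded numpy neural-network core.

The package trains three small models: a pixel-feature MLP, a miniature
encoder-decoder feature extractor and the two-layer convolutional ensemble
fuser.  This module implements exactly the layers those models need --
2-D convolution with stride and dilation, dense layers, bilinear
upsampling, ReLU and a class-weighted softmax cross-entropy -- together
with reverse-mode gradients and an Adam optimizer.

Everything is plain numpy.  Given a seed, initialisation, minibatch order
and therefore the trained weights are bit-reproducible on one platform.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "Dense",
    "ReLU",
    "BilinearUpsample",
    "Adam",
    "softmax",
    "weighted_softmax_xent",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def he_normal(rng, shape, fan_in, dtype, scale=1.0):
    return (rng.standard_normal(shape) * scale * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d:
    """Same-padded 2-D convolution (cross-correlation), NCHW layout.

    Supports stride and dilation with odd kernel sizes.  The forward and
    backward passes are expressed as one matmul per kernel tap, which keeps
    memory small and maps onto BLAS.
    """

    def __init__(self, rng, c_in, c_out, k=3, stride=1, dilation=1,
                 dtype=np.float32, init_scale=1.0):
        if k % 2 == 0:
            raise ValueError("Conv2d requires an odd kernel size")
        self.k, self.stride, self.dilation = k, stride, dilation
        self.pad = dilation * (k - 1) // 2
        self.W = Param(he_normal(rng, (c_out, c_in, k, k), c_in * k * k, dtype,
                                 init_scale))
        self.b = Param(np.zeros(c_out, dtype))
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def _out_hw(self, H, W):
        k, s, d, p = self.k, self.stride, self.dilation, self.pad
        Ho = (H + 2 * p - d * (k - 1) - 1) // s + 1
        Wo = (W + 2 * p - d * (k - 1) - 1) // s + 1
        return Ho, Wo

    def forward(self, x):
        B, C, H, W = x.shape
        k, s, d, p = self.k, self.stride, self.dilation, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        Ho, Wo = self._out_hw(H, W)
        y = np.zeros((B, Ho, Wo, self.W.value.shape[0]), x.dtype)
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i * d:i * d + (Ho - 1) * s + 1:s,
                        j * d:j * d + (Wo - 1) * s + 1:s]
                # (B,C,Ho,Wo) x (O,C) -> (B,Ho,Wo,O)
                y += np.tensordot(xs, self.W.value[:, :, i, j], axes=([1], [1]))
        y += self.b.value
        self._cache = (xp, (B, C, H, W), (Ho, Wo))
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, dy):
        xp, (B, C, H, W), (Ho, Wo) = self._cache
        k, s, d, p = self.k, self.stride, self.dilation, self.pad
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 3, 1))  # (B,Ho,Wo,O)
        self.b.grad += dyt.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                sl = (slice(None), slice(None),
                      slice(i * d, i * d + (Ho - 1) * s + 1, s),
                      slice(j * d, j * d + (Wo - 1) * s + 1, s))
                xs = xp[sl]
                self.W.grad[:, :, i, j] += np.tensordot(
                    dyt, xs, axes=([0, 1, 2], [0, 2, 3]))
                g = np.tensordot(dyt, self.W.value[:, :, i, j],
                                 axes=([3], [0]))  # (B,Ho,Wo,C)
                dxp[sl] += g.transpose(0, 3, 1, 2)
        self._cache = None
        if p == 0:
            return dxp
        return dxp[:, :, p:p + H, p:p + W]


class Dense:
    def __init__(self, rng, n_in, n_out, dtype=np.float32, init_scale=1.0):
        self.W = Param(he_normal(rng, (n_in, n_out), n_in, dtype, init_scale))
        self.b = Param(np.zeros(n_out, dtype))
        self._x = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.W.value.T
        self._x = None
        return dx


class ReLU:
    """Rectifier; ``leak_grad`` > 0 lets a small gradient pass where the
    forward output is clamped (the forward stays an exact ReLU).  Used
    where a clamped-everywhere region would otherwise stop training."""

    def __init__(self, leak_grad=0.0):
        self._m = None
        self.leak_grad = leak_grad

    params: list = []

    def forward(self, x):
        self._m = x > 0
        return np.where(self._m, x, x.dtype.type(0))

    def backward(self, dy):
        dx = np.where(self._m, dy, dy.dtype.type(self.leak_grad) * dy)
        self._m = None
        return dx


def _upsample_matrix(n_in, n_out, dtype):
    """Linear-interpolation matrix (n_out, n_in), half-pixel convention."""
    U = np.zeros((n_out, n_in), dtype)
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = (src - i0).astype(dtype)
    U[np.arange(n_out), i0] += 1 - f
    U[np.arange(n_out), i1] += f
    return U


class BilinearUpsample:
    """Bilinear resize expressed as two interpolation matrices.

    Being an explicit linear operator makes the gradient the exact
    transpose, with no resampling ambiguity.
    """

    def __init__(self, hw_in, hw_out, dtype=np.float32):
        self.Uh = _upsample_matrix(hw_in[0], hw_out[0], dtype)
        self.Uw = _upsample_matrix(hw_in[1], hw_out[1], dtype)

    params: list = []

    def forward(self, x):  # (B,C,H,W)
        t = np.tensordot(x, self.Uh, axes=([2], [1]))      # (B,C,W,Ho)
        y = np.tensordot(t, self.Uw, axes=([2], [1]))      # (B,C,Ho,Wo)
        return y

    def backward(self, dy):
        t = np.tensordot(dy, self.Uw, axes=([3], [0]))     # (B,C,Ho,W)
        dx = np.tensordot(t.transpose(0, 1, 3, 2), self.Uh,
                          axes=([3], [0]))                 # (B,C,W,H)
        return np.ascontiguousarray(dx.transpose(0, 1, 3, 2))


class Adam:
    """Adaptive-moment optimizer with bias correction."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (self.lr * (m / c1) /
                        (np.sqrt(v / c2) + self.eps)).astype(p.value.dtype)
            p.grad[...] = 0


def softmax(z, axis=1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_softmax_xent(logits, target, weight):
    """Weighted cross-entropy over flat samples.

    Parameters
    ----------
    logits : (N, K) array
    target : (N,) int array of class indices
    weight : (N,) non-negative per-sample weights (0 excludes a sample)

    Returns
    -------
    loss : float, weighted mean negative log-likelihood
    dlogits : (N, K) gradient of the loss w.r.t. ``logits``
    """
    p = softmax(logits.astype(np.float64), axis=1)
    n = logits.shape[0]
    wsum = float(weight.sum())
    if wsum <= 0:
        return 0.0, np.zeros_like(logits)
    idx = (np.arange(n), target)
    loss = float(-(weight * np.log(p[idx] + 1e-12)).sum() / wsum)
    d = p
    d[idx] -= 1.0
    d *= (weight / wsum)[:, None]
    return loss, d.astype(logits.dtype)


def image_xent(logits, target, weight):
    """Cross-entropy for (B,K,H,W) logits with per-pixel weights."""
    B, K, H, W = logits.shape
    flat = np.ascontiguousarray(logits.transpose(0, 2, 3, 1)).reshape(-1, K)
    loss, d = weighted_softmax_xent(flat, target.reshape(-1),
                                    weight.reshape(-1))
    dl = d.reshape(B, H, W, K).transpose(0, 3, 1, 2)
    return loss, np.ascontiguousarray(dl)


def state_arrays(layers):
    """Flatten the parameters of a layer list into an ordered dict."""
    out = {}
    for i, layer in enumerate(layers):
        for j, p in enumerate(layer.params):
            out[f"p{i}_{j}"] = p.value
    return out


def load_state_arrays(layers, arrays):
    for i, layer in enumerate(layers):
        for j, p in enumerate(layer.params):
            key = f"p{i}_{j}"
            if arrays[key].shape != p.value.shape:
                raise ValueError(f"shape mismatch for {key}")
            p.value = arrays[key].astype(p.value.dtype)
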