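"""Minimal CPU neural-network core for small 3D-CNN patch classifiers.

Implements exactly the pieces the two architectures need: 3D convolution
(same/valid padding, anisotropic stride), ReLU, inverted dropout, branch
concatenation, flatten, dense, a weighted binary cross-entropy head on
logits, and Adam.  Everything is plain numpy with explicit forward/backward
passes, which keeps training bit-reproducible for a given seed.

Convolutions use an offset-sum formulation: the kernel is unrolled into
one small GEMM per kernel offset acting on a strided view of the padded
input, both forward and backward.  For the tiny 5 x 5 x 92 patches this
avoids materializing any im2col matrix and keeps memory flat.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3D(Layer):
    """3D convolution over (N, D1, D2, D3, C) tensors.

    ``padding='same'`` (stride 1, odd kernels) preserves the spatial grid;
    ``padding='valid'`` shrinks it.  Weights use Glorot-uniform init.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int, int],
                 stride: tuple[int, int, int] = (1, 1, 1),
                 padding: str = "valid", *, rng: np.random.Generator):
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        fan_in = in_ch * int(np.prod(kernel))
        fan_out = out_ch * int(np.prod(kernel))
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-limit, limit,
                        size=(in_ch,) + tuple(kernel) + (out_ch,))
        self.w = Param(w.astype(np.float64))
        self.b = Param(np.zeros(out_ch))
        self.in_ch, self.out_ch = in_ch, out_ch

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _pad_widths(self) -> list[tuple[int, int]]:
        if self.padding == "same":
            return [((k - 1) // 2, (k - 1) // 2) for k in self.kernel]
        return [(0, 0)] * 3

    def _offset_slices(self):
        """Input-view slices per kernel offset, for the current output grid."""
        k1, k2, k3 = self.kernel
        s1, s2, s3 = self.stride
        o1, o2, o3 = self._out_spatial
        for a in range(k1):
            for b in range(k2):
                for c in range(k3):
                    yield (a, b, c), (
                        slice(None),
                        slice(a, a + s1 * o1, s1),
                        slice(b, b + s2 * o2, s2),
                        slice(c, c + s3 * o3, s3),
                        slice(None))

    def forward(self, x, train, rng):
        # offset-sum formulation: one small GEMM per kernel offset on a
        # strided view, avoiding a materialized im2col matrix
        pw = self._pad_widths()
        xp = np.pad(x, [(0, 0)] + pw + [(0, 0)])
        self._xp = xp
        self._out_spatial = tuple(
            (xp.shape[i + 1] - self.kernel[i]) // self.stride[i] + 1
            for i in range(3))
        n = x.shape[0]
        y = np.empty((n,) + self._out_spatial + (self.out_ch,))
        y[...] = self.b.value
        for (a, b, c), sl in self._offset_slices():
            y += xp[sl] @ self.w.value[:, a, b, c, :]
        return y

    def backward(self, grad):
        flat_g = grad.reshape(-1, self.out_ch)
        self.b.grad[...] = flat_g.sum(axis=0)
        dxp = np.zeros_like(self._xp)
        for (a, b, c), sl in self._offset_slices():
            xs = self._xp[sl].reshape(-1, self.in_ch)
            self.w.grad[:, a, b, c, :] = xs.T @ flat_g
            dxp[sl] += grad @ self.w.value[:, a, b, c, :].T
        pw = self._pad_widths()
        trim = tuple(slice(p[0], dxp.shape[i + 1] - p[1] or None)
                     for i, p in enumerate(pw))
        return dxp[(slice(None),) + trim + (slice(None),)]


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator):
        limit = np.sqrt(6.0 / (in_features + out_features))
        self.w = Param(rng.uniform(-limit, limit,
                                   size=(in_features, out_features)))
        self.b = Param(np.zeros(out_features))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad[...] = self._x.T @ grad
        self.b.grad[...] = grad.sum(axis=0)
        return grad @ self.w.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train, rng):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Branches(Layer):
    """Parallel sub-networks on the same input, concatenated channel-wise.

    All branches must preserve the spatial grid ('same' padding) so their
    outputs are concatenable.
    """

    def __init__(self, branches: list[Sequential]):
        self.branches = branches

    def params(self):
        return [p for b in self.branches for p in b.params()]

    def forward(self, x, train, rng):
        outs = [b.forward(x, train, rng) for b in self.branches]
        self._widths = [o.shape[-1] for o in outs]
        return np.concatenate(outs, axis=-1)

    def backward(self, grad):
        splits = np.cumsum(self._widths)[:-1]
        parts = np.split(grad, splits, axis=-1)
        return sum(b.backward(g) for b, g in zip(self.branches, parts))


class Network:
    """A feed-forward classifier ending in a single logit."""

    def __init__(self, body: Sequential, seed_sequence: np.random.SeedSequence):
        self.body = body
        self._dropout_rng = np.random.default_rng(seed_sequence)

    def params(self) -> list[Param]:
        return self.body.params()

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        rng = self._dropout_rng if train else None
        return self.body.forward(np.asarray(x, dtype=np.float64),
                                 train, rng)[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        self.body.backward(dlogit[:, None])

    def predict_proba(self, patches: np.ndarray,
                      batch_size: int = 1024) -> np.ndarray:
        """Sigmoid probabilities for (N, 5, 5, B) patches, in batches."""
        x = np.asarray(patches, dtype=np.float64)[..., None]
        out = np.empty(len(x))
        for i in range(0, len(x), batch_size):
            out[i:i + batch_size] = _sigmoid(
                self.forward_logits(x[i:i + batch_size], train=False))
        return out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def weighted_bce_with_logits(logits: np.ndarray, targets: np.ndarray,
                             weights: np.ndarray | None = None
                             ) -> tuple[float, np.ndarray]:
    """Mean of per-sample ``w * BCE`` and its gradient w.r.t. the logits.

    Uses the numerically stable ``softplus(z) - y * z`` form.  With all
    weights equal to 1 this is the plain binary cross-entropy.
    """
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    w = np.ones_like(z) if weights is None else np.asarray(weights, float)
    softplus = np.logaddexp(0.0, z)
    loss = float(np.mean(w * (softplus - y * z)))
    grad = w * (_sigmoid(z) - y) / len(z)
    return loss, grad


class Adam:
    def __init__(self, params: list[Param], learning_rate: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.99, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = learning_rate, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= lr_t * m / (np.sqrt(v) + self.eps)
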