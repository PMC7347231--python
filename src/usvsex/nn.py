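"""Minimal NumPy neural-network core used by the classifier family.

Implements exactly the building blocks the vocalization classifiers need:
2-D and 1-D convolutions ("same" padding, configurable stride, im2col +
BLAS matmul), fully connected layers, batch normalization on every layer,
ReLU, inverted dropout, Xavier (Glorot uniform) initialization, Adam, and
sigmoid/softmax heads with (optionally class-weighted) cross-entropy.

Everything runs in float32 on the CPU; all randomness (init, dropout,
batch order) is driven by explicit ``numpy.random.Generator`` objects, so
training is reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("v", "g", "m", "s")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=DTYPE)
        self.g = np.zeros_like(self.v)
        self.m = np.zeros_like(self.v)
        self.s = np.zeros_like(self.v)


def xavier_uniform(shape, fan_in, fan_out, rng) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def _same_pad(size: int, k: int, stride: int):
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + k - size, 0)
    before = total // 2
    return out, before, total - before


# ---------------------------------------------------------------------------
# layers


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, train=False, rng=None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Conv2D(Layer):
    """2-D cross-correlation, channels-last (B, H, W, C), "same" padding."""

    def __init__(self, in_ch, out_ch, kernel, stride, rng,
                 is_input_layer: bool = False):
        self.k = kernel
        self.stride = stride
        fan_in = kernel * kernel * in_ch
        fan_out = kernel * kernel * out_ch
        self.W = Param(xavier_uniform((kernel, kernel, in_ch, out_ch),
                                      fan_in, fan_out, rng))
        self.b = Param(np.zeros(out_ch))
        self.in_ch, self.out_ch = in_ch, out_ch
        # the gradient w.r.t. the raw input is not needed during training
        self.is_input_layer = is_input_layer

    def params(self):
        return [self.W, self.b]

    def _geometry(self, H, W):
        k, s = self.k, self.stride
        oh, pt, pb = _same_pad(H, k, s)
        ow, pl, pr = _same_pad(W, k, s)
        return oh, ow, (pt, pb), (pl, pr)

    def _shift_view(self, xp, kh, kw, oh, ow):
        s = self.stride
        return xp[:, kh:kh + (oh - 1) * s + 1:s,
                  kw:kw + (ow - 1) * s + 1:s, :]

    def forward(self, x, train=False, rng=None):
        """Convolution as a sum of k^2 shifted matmuls (one GEMM per kernel
        offset); the single-channel input layer uses im2col instead, where
        the rank-1 decomposition would degenerate."""
        k, s = self.k, self.stride
        B, H, W, C = x.shape
        oh, ow, (pt, pb), (pl, pr) = self._geometry(H, W)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        if C == 1:
            win = np.lib.stride_tricks.sliding_window_view(
                xp[..., 0], (k, k), axis=(1, 2))[:, ::s, ::s]
            col = win.reshape(B * oh * ow, k * k)
            y = col @ self.W.v.reshape(k * k, self.out_ch) + self.b.v
            self._cache = (col, None, x.shape, (pt, pl), (oh, ow))
            return y.reshape(B, oh, ow, self.out_ch)
        yf = np.tile(self.b.v.astype(DTYPE), (B * oh * ow, 1))
        for kh in range(k):
            for kw in range(k):
                t = np.ascontiguousarray(
                    self._shift_view(xp, kh, kw, oh, ow)).reshape(-1, C)
                yf += t @ self.W.v[kh, kw]
        self._cache = (None, xp, x.shape, (pt, pl), (oh, ow))
        return yf.reshape(B, oh, ow, self.out_ch)

    def backward(self, dy):
        col, xp, xshape, (pt, pl), (oh, ow) = self._cache
        B, H, W, C = xshape
        k = self.k
        dyf = np.ascontiguousarray(dy.reshape(-1, self.out_ch),
                                   dtype=DTYPE)
        if col is not None:
            self.W.g[...] = (col.T @ dyf).reshape(self.W.v.shape)
        else:
            for kh in range(k):
                for kw in range(k):
                    t = np.ascontiguousarray(
                        self._shift_view(xp, kh, kw, oh, ow)).reshape(-1, C)
                    self.W.g[kh, kw] = t.T @ dyf
        self.b.g[...] = dyf.sum(axis=0)
        self._cache = None
        if self.is_input_layer:
            return None
        return self.input_grad(dy, xshape, (pt, pl))

    def input_grad(self, dy, xshape, pads=None):
        """Adjoint (transposed-convolution) mapping of dy back to the input;
        also the back-projection primitive used by deconvolution analysis."""
        k, s = self.k, self.stride
        B, H, W, C = xshape
        oh, ow, (pt, pb), (pl, pr) = self._geometry(H, W)
        if pads is not None:
            pt, pl = pads
        dyf = np.ascontiguousarray(dy.reshape(-1, self.out_ch), dtype=DTYPE)
        dxp = np.zeros((B, H + pt + pb, W + pl + pr, C), dtype=DTYPE)
        for kh in range(k):
            for kw in range(k):
                contrib = (dyf @ self.W.v[kh, kw].T).reshape(B, oh, ow, C)
                self._shift_view(dxp, kh, kw, oh, ow)[...] += contrib
        return dxp[:, pt:pt + H, pl:pl + W]


class Conv1D(Layer):
    """1-D cross-correlation, channels-last (B, L, C), "same" padding."""

    def __init__(self, in_ch, out_ch, kernel, stride, rng):
        self.k = kernel
        self.stride = stride
        self.W = Param(xavier_uniform((kernel, in_ch, out_ch),
                                      kernel * in_ch, kernel * out_ch, rng))
        self.b = Param(np.zeros(out_ch))
        self.in_ch, self.out_ch = in_ch, out_ch

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        k, s = self.k, self.stride
        B, L, C = x.shape
        ol, pl, pr = _same_pad(L, k, s)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(
            xp, k, axis=1)[:, ::s]                     # (B,ol,C,k)
        col = win.reshape(B * ol, C * k)
        wmat = np.ascontiguousarray(
            self.W.v.transpose(1, 0, 2)).reshape(-1, self.out_ch)
        y = col @ wmat + self.b.v
        self._cache = (col, x.shape, pl, ol)
        return y.reshape(B, ol, self.out_ch)

    def backward(self, dy):
        col, xshape, pl, ol = self._cache
        B, L, C = xshape
        k, s = self.k, self.stride
        dyf = dy.reshape(-1, self.out_ch).astype(DTYPE)
        self.W.g[...] = (col.T @ dyf).reshape(
            C, k, self.out_ch).transpose(1, 0, 2)
        self.b.g[...] = dyf.sum(axis=0)
        self._cache = None
        z = np.zeros((B, (ol - 1) * s + 1, self.out_ch), dtype=DTYPE)
        z[:, ::s] = dy
        zp = np.pad(z, ((0, 0), (k - 1, k - 1), (0, 0)))
        wf = np.ascontiguousarray(
            self.W.v[::-1].transpose(2, 0, 1)).reshape(-1, C)
        win = np.lib.stride_tricks.sliding_window_view(zp, k, axis=1)
        lp = win.shape[1]
        colb = win.reshape(B * lp, self.out_ch * k)
        dxp = (colb @ wf).reshape(B, lp, C)
        return dxp[:, pl:pl + L]


class Dense(Layer):
    def __init__(self, in_dim, out_dim, rng):
        self.W = Param(xavier_uniform((in_dim, out_dim), in_dim, out_dim,
                                      rng))
        self.b = Param(np.zeros(out_dim))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W.v + self.b.v

    def backward(self, dy):
        dy = dy.astype(DTYPE)
        self.W.g[...] = self._x.T @ dy
        self.b.g[...] = dy.sum(axis=0)
        dx = dy @ self.W.v.T
        self._x = None
        return dx


class BatchNorm(Layer):
    """Normalizes over all axes but the last (channel) axis."""

    def __init__(self, n_ch, momentum=0.9, eps=1e-5):
        self.gamma = Param(np.ones(n_ch))
        self.beta = Param(np.zeros(n_ch))
        self.momentum = momentum
        self.eps = eps
        self.run_mean = np.zeros(n_ch, dtype=DTYPE)
        self.run_var = np.ones(n_ch, dtype=DTYPE)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (self.momentum * self.run_mean
                             + (1 - self.momentum) * mean).astype(DTYPE)
            self.run_var = (self.momentum * self.run_var
                            + (1 - self.momentum) * var).astype(DTYPE)
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv.astype(DTYPE), axes)
        return (self.gamma.v * xhat + self.beta.v).astype(DTYPE)

    def backward(self, dy):
        xhat, inv, axes = self._cache
        n = dy.size // dy.shape[-1]
        self.gamma.g[...] = (dy * xhat).sum(axis=axes)
        self.beta.g[...] = dy.sum(axis=axes)
        dxhat = dy * self.gamma.v
        dx = (inv / n) * (n * dxhat - dxhat.sum(axis=axes)
                          - xhat * (dxhat * xhat).sum(axis=axes))
        self._cache = None
        return dx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class Dropout(Layer):
    """Inverted dropout; probability is mutable so training protocols can
    change it between stages."""

    def __init__(self, p=0.0):
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.uniform(size=x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


# ---------------------------------------------------------------------------
# network + heads


class Network:
    """Sequential network with a sigmoid (binary) or softmax head."""

    def __init__(self, layers: list[Layer], head: str, n_out: int):
        if head not in ("sigmoid", "softmax"):
            raise ValueError("head must be 'sigmoid' or 'softmax'")
        if head == "sigmoid" and n_out != 1:
            raise ValueError("sigmoid head requires a single output")
        self.layers = layers
        self.head = head
        self.n_out = n_out

    # -- plumbing -----------------------------------------------------------

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def n_parameters(self) -> int:
        return int(sum(p.v.size for p in self.params()))

    def set_dropout(self, p: float):
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.p = p

    # -- forward / backward -------------------------------------------------

    def forward(self, x, train=False, rng=None):
        x = np.asarray(x, dtype=DTYPE)
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dlogits):
        d = dlogits.astype(DTYPE)
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def predict_proba(self, x, batch_size: int = 256):
        out = []
        x = np.asarray(x, dtype=DTYPE)
        for i in range(0, len(x), batch_size):
            z = self.forward(x[i:i + batch_size], train=False)
            out.append(sigmoid(z) if self.head == "sigmoid" else softmax(z))
        return np.concatenate(out, axis=0)

    def predict(self, x, batch_size: int = 256):
        p = self.predict_proba(x, batch_size)
        if self.head == "sigmoid":
            return (p[:, 0] >= 0.5).astype(int)
        return np.argmax(p, axis=1)

    # -- loss ---------------------------------------------------------------

    def loss_and_grad(self, logits, y, class_weights=None):
        """Cross-entropy loss (mean over the batch, optionally class
        weighted) and its gradient w.r.t. the logits."""
        y = np.asarray(y)
        n = len(y)
        if class_weights is None:
            w = np.ones(n, dtype=DTYPE)
        else:
            w = np.asarray(class_weights, dtype=DTYPE)[y]
        if self.head == "sigmoid":
            z = logits[:, 0]
            p = sigmoid(z)
            eps = 1e-7
            loss = -np.mean(w * (y * np.log(p + eps)
                                 + (1 - y) * np.log(1 - p + eps)))
            dz = (w * (p - y) / n)[:, None]
            return float(loss), dz.astype(DTYPE)
        p = softmax(logits)
        eps = 1e-7
        loss = -np.mean(w * np.log(p[np.arange(n), y] + eps))
        dz = p.copy()
        dz[np.arange(n), y] -= 1.0
        dz *= (w / n)[:, None]
        return float(loss), dz.astype(DTYPE)


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self, params: list[Param]):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p in params:
            p.m = self.b1 * p.m + (1 - self.b1) * p.g
            p.s = self.b2 * p.s + (1 - self.b2) * p.g ** 2
            p.v -= self.lr * (p.m / b1t) / (np.sqrt(p.s / b2t) + self.eps)
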