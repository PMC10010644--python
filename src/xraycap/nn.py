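"""Neural-network building blocks on top of :mod:`xraycap.autodiff`.

Layers follow the familiar Module convention: parameters are
``Tensor``s with ``requires_grad=True``, discovered recursively through
attributes, and optimised with :class:`Adam`.  Initialisation is driven
by an explicit ``numpy.random.Generator`` so every model in the package
is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- parameter discovery ------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor):
                # all Tensor attributes of a Module are parameters; a frozen
                # parameter keeps requires_grad=False and collects no grad
                yield prefix + name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix + name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for _, value in vars(self).items():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- (de)serialisation --------------------------------------------
    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng, bias: bool = True):
        super().__init__()
        s = 1.0 / np.sqrt(in_features)
        self.weight = parameter(rng.uniform(-s, s, size=(in_features, out_features)))
        self.bias = parameter(rng.uniform(-s, s, size=(out_features,))) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng):
        super().__init__()
        self.weight = parameter(rng.normal(0.0, 0.1, size=(num_embeddings, dim)))

    def forward(self, ids) -> Tensor:
        return self.weight[np.asarray(ids, dtype=np.int64)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gain = parameter(np.ones(dim))
        self.shift = parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        return centred / (var + self.eps).sqrt() * self.gain + self.shift


class Dropout(Module):
    """Inverted dropout; a ``Generator`` is supplied at construction."""

    def __init__(self, p: float, rng):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = self.rng.random(x.shape) < keep
        return x * Tensor(mask / keep)


class Conv2d(Module):
    """2-D convolution via explicit patch gathering (im2col)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng,
                 stride: int = 1, padding: int = 0):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        # He initialisation: keeps activation variance stable through ReLU stacks
        self.weight = parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                           size=(fan_in, out_ch)))
        self.bias = parameter(np.zeros(out_ch))
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {C}")
        K, S, P = self.kernel, self.stride, self.padding
        if P:
            x = pad2d(x, P)
            H, W = H + 2 * P, W + 2 * P
        Ho = (H - K) // S + 1
        Wo = (W - K) // S + 1
        i0 = np.repeat(np.arange(Ho) * S, Wo)
        j0 = np.tile(np.arange(Wo) * S, Ho)
        di = np.repeat(np.arange(K), K)
        dj = np.tile(np.arange(K), K)
        ii = i0[:, None] + di[None, :]          # (P_out, K*K)
        jj = j0[:, None] + dj[None, :]
        patches = x[:, :, ii, jj]               # (B, C, P_out, K*K)
        patches = patches.transpose((0, 2, 1, 3)).reshape((B, Ho * Wo, C * K * K))
        out = patches @ self.weight + self.bias  # (B, P_out, out_ch)
        return out.transpose((0, 2, 1)).reshape((B, self.out_ch, Ho, Wo))


def pad2d(x: Tensor, p: int) -> Tensor:
    """Zero-pad the two trailing spatial axes of a (B, C, H, W) tensor."""
    B, C, H, W = x.shape
    rows = concat([Tensor(np.zeros((B, C, p, W))), x, Tensor(np.zeros((B, C, p, W)))], axis=2)
    return concat([Tensor(np.zeros((B, C, H + 2 * p, p))), rows,
                   Tensor(np.zeros((B, C, H + 2 * p, p)))], axis=3)


def _pool_bins(in_size: int, out_size: int) -> np.ndarray:
    """Averaging matrix (out_size, in_size) with adaptive floor/ceil bins."""
    M = np.zeros((out_size, in_size))
    for i in range(out_size):
        lo = (i * in_size) // out_size
        hi = -(-((i + 1) * in_size) // out_size)  # ceil
        M[i, lo:hi] = 1.0 / (hi - lo)
    return M


def adaptive_avg_pool2d(x: Tensor, out_size: int) -> Tensor:
    """Average-pool a (B, C, H, W) tensor to (B, C, out, out)."""
    B, C, H, W = x.shape
    R = Tensor(_pool_bins(H, out_size))
    Ct = Tensor(_pool_bins(W, out_size).T)
    flat = x.reshape((B * C, H, W))
    pooled = R @ flat @ Ct
    return pooled.reshape((B, C, out_size, out_size))


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``.

    A threshold of 0 zeroes every gradient (and therefore freezes the
    model), which the degenerate-clip tests rely on.
    """
    params = [p for p in params if p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad ** 2).sum()) for p in params)))
    if max_norm <= 0.0:
        for p in params:
            p.grad[...] = 0.0
        return total
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale
    return total
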