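"""Minimal NumPy convolutional-network engine.

Implements exactly what the anomaly detectors need: 3x3 convolutions with
stride and zero padding (im2col), leaky-ReLU nonlinearities, explicit
forward caches so several forward passes can coexist (needed for the
symmetric objective and Grad-CAM), and SGD with momentum, weight decay and
cosine learning-rate decay. Gradients are hand-derived and verified against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "BatchNorm2d", "LeakyReLU", "Sequential", "SGD"]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """Unfold (N, C, H, W) into (N*Ho*Wo, C*k*k) patch rows."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int, ho: int, wo: int) -> np.ndarray:
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += d[..., i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w]


class Parameter:
    __slots__ = ("value", "grad", "momentum")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.momentum = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv2d:
    """2D convolution, 'same'-style zero padding, optional bias.

    Bias defaults to off: one-class objectives with bias terms admit the
    trivial solution of shifting every feature to zero, so the hypersphere
    losses are conventionally trained bias-free.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 bias: bool = False, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.weight = Parameter(w.astype(dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray):
        cols, ho, wo = _im2col(x, self.kernel, self.stride, self.pad)
        out = cols @ self.weight.value.T
        if self.bias is not None:
            out += self.bias.value
        n = x.shape[0]
        out = out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)
        cache = (cols, x.shape, ho, wo)
        return out, cache

    def backward(self, gout: np.ndarray, cache) -> np.ndarray:
        cols, x_shape, ho, wo = cache
        n = x_shape[0]
        g = gout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_ch)
        self.weight.grad += g.T @ cols
        if self.bias is not None:
            self.bias.grad += g.sum(axis=0)
        dcols = g @ self.weight.value
        return _col2im(dcols, x_shape, self.kernel, self.stride, self.pad, ho, wo)


class BatchNorm2d:
    """Per-channel batch normalization with a learned scale and no shift.

    Omitting the shift keeps the network free of additive terms, so the
    hypersphere objectives cannot collapse by translating every feature to
    the center. Running statistics (momentum 0.1) are used at inference.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.eps = eps
        self.bn_momentum = momentum
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.train_mode = True

    def parameters(self) -> list[Parameter]:
        return [self.gamma]

    def forward(self, x: np.ndarray):
        if self.train_mode:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.bn_momentum) * self.running_mean + self.bn_momentum * mu
            self.running_var = (1 - self.bn_momentum) * self.running_var + self.bn_momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat
        return out, (xhat, inv, self.train_mode)

    def backward(self, gout: np.ndarray, cache) -> np.ndarray:
        xhat, inv, was_training = cache
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3))
        g = gout * self.gamma.value[None, :, None, None]
        if not was_training:
            return g * inv[None, :, None, None]
        m = xhat.shape[0] * xhat.shape[2] * xhat.shape[3]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gx_sum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / m) * (m * g - gsum - xhat * gx_sum)


class LeakyReLU:
    def __init__(self, negative_slope: float = 0.1):
        self.slope = negative_slope

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray):
        mask = x >= 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, gout: np.ndarray, mask) -> np.ndarray:
        return np.where(mask, gout, self.slope * gout)


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def set_train_mode(self, train_mode: bool) -> None:
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                layer.train_mode = train_mode

    def forward(self, x: np.ndarray):
        """Return (output, cache). Caches are per-call, so interleaved
        forward passes (symmetric pairs, Grad-CAM probes) stay independent."""
        caches = []
        acts = [x]
        for layer in self.layers:
            x, c = layer.forward(x)
            caches.append(c)
            acts.append(x)
        return x, {"caches": caches, "activations": acts}

    def backward(self, gout: np.ndarray, cache, stop_at: int = 0) -> np.ndarray:
        """Backpropagate gout through layers [stop_at, end); accumulates
        parameter grads and returns the gradient at activations[stop_at]."""
        for i in range(len(self.layers) - 1, stop_at - 1, -1):
            gout = self.layers[i].backward(gout, cache["caches"][i])
        return gout

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.parameters()):
                out[f"layer{i}.p{j}"] = p.value
            if isinstance(layer, BatchNorm2d):
                out[f"layer{i}.running_mean"] = layer.running_mean
                out[f"layer{i}.running_var"] = layer.running_var
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.parameters()):
                p.value = np.asarray(state[f"layer{i}.p{j}"])
                p.grad = np.zeros_like(p.value)
                p.momentum = np.zeros_like(p.value)
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = np.asarray(state[f"layer{i}.running_mean"])
                layer.running_var = np.asarray(state[f"layer{i}.running_var"])


class SGD:
    """SGD with momentum, decoupled-style weight decay and cosine decay."""

    def __init__(self, params: list[Parameter], lr: float = 1e-2, momentum: float = 0.9,
                 weight_decay: float = 1e-4, total_steps: int | None = None):
        self.params = params
        self.lr0 = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.total_steps = total_steps
        self.step_count = 0

    def current_lr(self) -> float:
        if not self.total_steps:
            return self.lr0
        t = min(self.step_count, self.total_steps)
        return self.lr0 * 0.5 * (1.0 + np.cos(np.pi * t / self.total_steps))

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        lr = self.current_lr()
        for p in self.params:
            g = p.grad + self.weight_decay * p.value
            p.momentum = self.momentum * p.momentum + g
            p.value = p.value - lr * p.momentum
        self.step_count += 1
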