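"""Layers and optimization built on the autograd engine.

Provides just enough structure for the vessel-segmentation networks:
convolution layers with He-normal initialization, the embedded-Gaussian
non-local attention block, its two-scale wrapper, and Adam.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

DEFAULT_DTYPE = np.float32


def he_normal(rng: np.random.Generator, shape, fan_in: int, dtype=DEFAULT_DTYPE) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Module:
    """Base class: children and parameters discovered by attribute walk."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{i}."))
        return out


class Conv2d(Module):
    """3x3 (or kxk) convolution, stride 1, "same" padding, optional ReLU.

    ``leak`` > 0 switches the activation to leaky ReLU; small narrow
    layers in unnormalized networks otherwise die easily under Adam.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 kernel: int = 3, relu: bool = True, zero_init: bool = False,
                 leak: float = 0.0, dtype=DEFAULT_DTYPE):
        fan_in = cin * kernel * kernel
        if zero_init:
            w = np.zeros((cout, cin, kernel, kernel), dtype=dtype)
        else:
            w = he_normal(rng, (cout, cin, kernel, kernel), fan_in, dtype)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)
        self.relu = relu
        self.leak = leak
        self.cin = cin
        self.cout = cout

    def __call__(self, x: Tensor) -> Tensor:
        out = ag.conv2d(x, self.weight, self.bias)
        if not self.relu:
            return out
        if self.leak:
            return ag.leaky_relu(out, self.leak)
        return ag.relu(out)


class NonLocalBlock(Module):
    """Embedded-Gaussian non-local attention with a residual connection.

    Every spatial position is re-expressed as a softmax-weighted mixture of
    all positions (affinity = softmax over pairwise embedded dot products),
    then projected back and added to the input.  The output projection is
    zero-initialized so the block starts as the identity.
    """

    def __init__(self, channels: int, rng: np.random.Generator, dtype=DEFAULT_DTYPE):
        inter = max(1, channels // 2)
        self.theta = Conv2d(channels, inter, rng, kernel=1, relu=False, dtype=dtype)
        self.phi = Conv2d(channels, inter, rng, kernel=1, relu=False, dtype=dtype)
        self.g = Conv2d(channels, inter, rng, kernel=1, relu=False, dtype=dtype)
        self.proj = Conv2d(inter, channels, rng, kernel=1, relu=False,
                           zero_init=True, dtype=dtype)
        self.channels = channels
        self.inter = inter

    def affinity(self, x: Tensor) -> Tensor:
        """Row-stochastic (N, HW, HW) attention matrix for input (N,C,H,W)."""
        n, c, h, w = x.shape
        theta = ag.reshape(self.theta(x), (n, self.inter, h * w))
        phi = ag.reshape(self.phi(x), (n, self.inter, h * w))
        scores = ag.matmul(ag.transpose(theta, (0, 2, 1)), phi)
        return ag.softmax(scores)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        aff = self.affinity(x)
        g = ag.reshape(self.g(x), (n, self.inter, h * w))
        y = ag.matmul(g, ag.transpose(aff, (0, 2, 1)))
        y = ag.reshape(y, (n, self.inter, h, w))
        return ag.add(x, self.proj(y))


class MultiScaleAttention(Module):
    """Non-local attention applied to the deepest feature map at two scales.

    For each scale ``s`` the map is average-pooled by ``s``, passed through
    its own non-local block, and resized back; the per-scale outputs are
    summed and mixed by a final 1x1 convolution.  With zero-initialized
    non-local projections and an identity-initialized mixer the module
    starts close to ``len(scales) x`` identity, which keeps early training
    well-conditioned.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 scales=(1, 2), dtype=DEFAULT_DTYPE):
        self.scales = tuple(int(s) for s in scales)
        if any(s < 1 for s in self.scales):
            raise ValueError(f"attention scales must be >= 1, got {scales}")
        self.blocks = [NonLocalBlock(channels, rng, dtype) for _ in self.scales]
        self.mix = Conv2d(channels, channels, rng, kernel=1, relu=False, dtype=dtype)
        # identity-ish start: mix(sum of residual branches) ~ input
        eye = np.zeros_like(self.mix.weight.data)
        for c in range(channels):
            eye[c, c, 0, 0] = 1.0 / len(self.scales)
        self.mix.weight.data = eye
        self.channels = channels

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        smax = max(self.scales)
        if h < smax or w < smax:
            raise ValueError(
                f"feature map {h}x{w} smaller than attention scale {smax}")
        branches = []
        for s, block in zip(self.scales, self.blocks):
            z = ag.avgpool(x, s)
            z = block(z)
            z = ag.bilinear_resize(z, h, w)
            branches.append(z)
        total = branches[0]
        for z in branches[1:]:
            total = ag.add(total, z)
        return self.mix(total)


class Adam:
    """Adam optimizer (Kingma & Ba) over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
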