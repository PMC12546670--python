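"""Neural-network modules built on the autodiff core.

Conventions follow the common deep-learning layout: batches first, channels
second.  Spectra are ``(B, C, L)``, images ``(B, C, H, W)``.  All weights are
He-normal initialized from an explicit ``numpy.random.Generator`` so that a
seed fully determines the network.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


def conv_out_len(length, kernel, stride, pad):
    """Output length of a strided convolution (floor convention)."""
    return (length + 2 * pad - kernel) // stride + 1


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        """Unique trainable tensors (weight-tied modules deduplicated)."""
        seen, out = set(), []
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def buffers(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and not value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.buffers(prefix + name + ".")

    def train(self):
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self):
        state = {}
        for name, p in self.named_parameters():
            state.setdefault(name, p.data.copy())
        for name, b in self.buffers():
            state[name] = b.data.copy()
        return state

    def load_state_dict(self, state):
        named = dict(self.named_parameters())
        named.update(dict(self.buffers()))
        missing = set(named) - set(state)
        if missing:
            raise ValueError(f"state dict is missing entries: {sorted(missing)[:5]} ...")
        for name, t in named.items():
            if t.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {t.data.shape} vs {state[name].shape}")
            t.data = state[name].astype(t.data.dtype).copy()


def _he(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class LeakyReLU(Module):
    def __init__(self, slope=0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return ad.leaky_relu(x, self.slope)


class Sigmoid(Module):
    def forward(self, x):
        return ad.sigmoid(x)


class Flatten(Module):
    def forward(self, x):
        return ad.reshape(x, (x.shape[0], -1))


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Linear(Module):
    def __init__(self, in_features, out_features, rng, bias=True):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.weight = Tensor(_he(rng, (in_features, out_features), in_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x):
        out = ad.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv1d(Module):
    def __init__(self, in_ch, out_ch, kernel, rng, stride=1, pad=0, bias=True):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.weight = Tensor(_he(rng, (out_ch, in_ch * kernel), in_ch * kernel),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x):
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        B = x.shape[0]
        cols = ad.im2col1d(x, self.kernel, self.stride, self.pad)
        Lo = cols.shape[2]
        # fold the batch into the gemm: one (out_ch, Ck) x (Ck, B*Lo) product
        cols = ad.reshape(ad.transpose(cols, (1, 0, 2)), (cols.shape[1], -1))
        out = ad.matmul(self.weight, cols)            # (out_ch, B*Lo)
        out = ad.transpose(ad.reshape(out, (self.out_ch, B, Lo)), (1, 0, 2))
        if self.bias is not None:
            out = out + ad.reshape(self.bias, (1, self.out_ch, 1))
        return out


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, rng, stride=1, pad=0, bias=True):
        super().__init__()
        kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = (kh, kw), stride, pad
        fan = in_ch * kh * kw
        self.weight = Tensor(_he(rng, (out_ch, fan), fan), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x):
        B, C, H, W = x.shape
        kh, kw = self.kernel
        Ho = conv_out_len(H, kh, self.stride, self.pad)
        Wo = conv_out_len(W, kw, self.stride, self.pad)
        cols = ad.im2col2d(x, self.kernel, self.stride, self.pad)
        cols = ad.reshape(ad.transpose(cols, (1, 0, 2)), (cols.shape[1], -1))
        out = ad.matmul(self.weight, cols)            # (out_ch, B*Ho*Wo)
        out = ad.transpose(ad.reshape(out, (self.out_ch, B, Ho * Wo)), (1, 0, 2))
        if self.bias is not None:
            out = out + ad.reshape(self.bias, (1, self.out_ch, 1))
        return ad.reshape(out, (B, self.out_ch, Ho, Wo))


class DepthwiseConv2d(Module):
    """Per-channel 2-D convolution (groups == channels)."""

    def __init__(self, channels, kernel, rng, stride=1, pad=0, bias=False):
        super().__init__()
        self.channels, self.kernel = channels, kernel
        self.stride, self.pad = stride, pad
        fan = kernel * kernel
        self.weight = Tensor(_he(rng, (channels, fan), fan), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x):
        B, C, H, W = x.shape
        k = self.kernel
        Ho = conv_out_len(H, k, self.stride, self.pad)
        Wo = conv_out_len(W, k, self.stride, self.pad)
        cols = ad.im2col2d(x, k, self.stride, self.pad)      # (B, C*k*k, L)
        cols = ad.reshape(cols, (B, C, k * k, Ho * Wo))
        w = ad.reshape(self.weight, (1, C, k * k, 1))
        out = ad.reduce_sum(cols * w, axis=2)                # (B, C, L)
        if self.bias is not None:
            out = out + ad.reshape(self.bias, (1, C, 1))
        return ad.reshape(out, (B, C, Ho, Wo))


class MaxPool2d(Module):
    def __init__(self, kernel, stride, pad=0):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x):
        B, C, H, W = x.shape
        k = self.kernel
        Ho = conv_out_len(H, k, self.stride, self.pad)
        Wo = conv_out_len(W, k, self.stride, self.pad)
        cols = ad.im2col2d(x, k, self.stride, self.pad)
        cols = ad.reshape(cols, (B, C, k * k, Ho * Wo))
        out = ad.reduce_max(cols, axis=2)
        return ad.reshape(out, (B, C, Ho, Wo))


class GlobalAvgPool(Module):
    """Mean over all spatial axes -> (B, C)."""

    def forward(self, x):
        axes = tuple(range(2, x.ndim))
        return ad.reduce_mean(x, axis=axes)


class BatchNorm(Module):
    """Batch normalization over all axes except the channel axis (dim 1)."""

    def __init__(self, num_features, momentum=0.1, eps=1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(num_features, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, np.float32), requires_grad=True)
        self.running_mean = Tensor(np.zeros(num_features, np.float32))
        self.running_var = Tensor(np.ones(num_features, np.float32))

    def forward(self, x):
        shape = (1, self.num_features) + (1,) * (x.ndim - 2)
        axes = (0,) + tuple(range(2, x.ndim))
        if self.training:
            m = ad.reduce_mean(x, axis=axes, keepdims=True)
            v = ad.reduce_mean((x - m) * (x - m), axis=axes, keepdims=True)
            mom = self.momentum
            self.running_mean.data = ((1 - mom) * self.running_mean.data
                                      + mom * m.data.reshape(-1))
            self.running_var.data = ((1 - mom) * self.running_var.data
                                     + mom * v.data.reshape(-1))
        else:
            m = Tensor(self.running_mean.data.reshape(shape))
            v = Tensor(self.running_var.data.reshape(shape))
        xhat = (x - m) * ad.power(v + self.eps, -0.5)
        return xhat * ad.reshape(self.gamma, shape) + ad.reshape(self.beta, shape)


class ChannelShuffle(Module):
    """Interleave channel groups: (B, g*c, ...) -> group-transposed order."""

    def __init__(self, groups=2):
        super().__init__()
        self.groups = groups

    def forward(self, x):
        B, C = x.shape[:2]
        rest = x.shape[2:]
        g = self.groups
        x = ad.reshape(x, (B, g, C // g) + rest)
        order = (0, 2, 1) + tuple(range(3, x.ndim))
        x = ad.transpose(x, order)
        return ad.reshape(x, (B, C) + rest)
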