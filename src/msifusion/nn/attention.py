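"""Attention blocks: CBAM-style channel attention, squeeze-and-excitation,
and the cross-modal attention (CMA) fusion used to merge the two branches.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import BatchNorm, Linear, Module


class ChannelAttention1d(Module):
    """Channel gate for (B, C, L) maps.

    Average- and max-pooled channel descriptors pass through one shared
    two-layer perceptron (C -> C/r -> C, ReLU between); the sigmoid of the
    summed responses gates each channel:

        w = sigmoid(MLP(avgpool(F)) + MLP(maxpool(F))),  out = w * F
    """

    def __init__(self, channels, rng, reduction=8):
        super().__init__()
        if channels % reduction:
            raise ValueError(f"channels ({channels}) must be divisible by "
                             f"reduction ratio ({reduction})")
        self.channels = channels
        self.fc1 = Linear(channels, channels // reduction, rng)
        self.fc2 = Linear(channels // reduction, channels, rng)

    def _mlp(self, z):
        return self.fc2(ad.relu(self.fc1(z)))

    def weights(self, x):
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        avg = ad.reduce_mean(x, axis=2)            # (B, C)
        mx = ad.reduce_max(x, axis=2)
        return ad.sigmoid(self._mlp(avg) + self._mlp(mx))

    def forward(self, x):
        w = self.weights(x)
        return x * ad.reshape(w, (w.shape[0], self.channels, 1))


class SEBlock(Module):
    """Squeeze-and-excitation channel rescaling for (B, C, H, W) maps.

    Squeeze: global average pool z_c; excite: s = sigmoid(W2 relu(W1 z));
    rescale: x~_c = s_c * u_c.
    """

    def __init__(self, channels, rng, reduction=16):
        super().__init__()
        if channels % reduction:
            raise ValueError(f"channels ({channels}) not divisible by r={reduction}")
        self.channels = channels
        self.fc1 = Linear(channels, channels // reduction, rng)
        self.fc2 = Linear(channels // reduction, channels, rng)

    def gates(self, x):
        z = ad.reduce_mean(x, axis=(2, 3))          # squeeze, (B, C)
        return ad.sigmoid(self.fc2(ad.relu(self.fc1(z))))

    def forward(self, x):
        s = self.gates(x)
        return x * ad.reshape(s, (s.shape[0], self.channels, 1, 1))


class CrossModalAttention(Module):
    """Fuse a 64-d image feature with a 64-d spectral feature.

    Both features are treated as length-C sequences. Four 1x1 projections
    (realized as linear maps, mathematically identical on 1x1 spatial maps)
    produce query Q from the image feature and key/value K, V from the
    spectral feature.  The attention matrix is the row-softmax of the scaled
    outer product Q K^T; the attended value is added back onto the image
    feature through a residual connection:

        A = softmax(Q K^T / scale),  Z = A V,  fused = F_image + W_out Z

    followed (by default) by batch normalization and leaky ReLU.
    ``scale`` is sqrt(C) ("sqrt" mode, standard scaled dot-product) or C
    ("dim" mode, the form as printed).
    """

    def __init__(self, dim, rng, scale="sqrt", post_norm=True, leaky_slope=0.01):
        super().__init__()
        if scale not in ("sqrt", "dim"):
            raise ValueError("scale must be 'sqrt' or 'dim'")
        self.dim = dim
        self.scale = np.sqrt(dim) if scale == "sqrt" else float(dim)
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)
        self.post_norm = post_norm
        self.bn = BatchNorm(dim) if post_norm else None
        self.act = leaky_slope

    def attention_matrix(self, f_image, f_spectral):
        q = self.q_proj(f_image)                    # (B, C)
        k = self.k_proj(f_spectral)
        logits = (ad.reshape(q, (-1, self.dim, 1))
                  * ad.reshape(k, (-1, 1, self.dim))) * (1.0 / self.scale)
        return ad.softmax(logits, axis=-1)          # rows sum to 1

    def forward(self, f_image, f_spectral):
        if f_image.shape[1] != self.dim or f_spectral.shape[1] != self.dim:
            raise ValueError(
                f"both features must be {self.dim}-dimensional, got "
                f"{f_image.shape[1]} and {f_spectral.shape[1]}")
        attn = self.attention_matrix(f_image, f_spectral)
        v = self.v_proj(f_spectral)
        z = ad.matmul(attn, ad.reshape(v, (-1, self.dim, 1)))
        z = ad.reshape(z, (-1, self.dim))
        fused = f_image + self.out_proj(z)          # residual connection
        if self.post_norm:
            fused = ad.leaky_relu(self.bn(fused), self.act)
        return fused
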