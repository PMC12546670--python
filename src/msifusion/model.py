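"""The spectral/image fusion classifier.

Architecture
------------
* **Spectral branch** — six 1-D conv/BN/ReLU layers (channels
  1-16-32-64-128-256-512, kernels 7/7/5/5/3/3, stride 2, padding 1), CBAM
  channel attention on the final feature map, flatten, FC to 256 then 128,
  and a shared FC to 64.  At the default 480-band input the per-layer
  lengths are 238/117/58/28/14/7 and the flattened size is 3584.
* **Image branch** — a registered 2-D backbone (ShuffleNetV2 by default),
  an SE block on the final feature stage, global average pooling, FC to
  128, and the (weight-tied) shared FC to 64.
* **Fusion** — cross-modal attention: the image feature queries the
  spectral feature's keys/values; the attended value re-enters through a
  residual connection, then batch norm and leaky ReLU.  Without attention,
  fusion is concatenation + linear + batch norm + leaky ReLU.
* **Head** — linear map to class logits; probabilities via softmax.

Ablation variants (spectral-only, image-only, fusion without attention)
share every remaining component with the full model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .nn import autodiff as ad


@dataclass(frozen=True)
class ConvLayerSpec:
    in_channels: int
    out_channels: int
    kernel: int
    stride: int
    padding: int
    batch_norm: bool = True
    activation: str = "relu"


# The six-layer 1-D stack (kernel sizes 7/7/5/5/3/3, all stride 2, pad 1).
SPECTRAL_CONV_LAYERS = (
    ConvLayerSpec(1, 16, 7, 2, 1),
    ConvLayerSpec(16, 32, 7, 2, 1),
    ConvLayerSpec(32, 64, 5, 2, 1),
    ConvLayerSpec(64, 128, 5, 2, 1),
    ConvLayerSpec(128, 256, 3, 2, 1),
    ConvLayerSpec(256, 512, 3, 2, 1),
)


@dataclass
class SpectralBranchConfig:
    layers: tuple = SPECTRAL_CONV_LAYERS
    input_length: int = 480
    fc1_out: int = 256
    fc2_out: int = 128
    attention_reduction: int = 8

    def layer_lengths(self):
        """Feature length after each conv layer."""
        L = self.input_length
        out = []
        for spec in self.layers:
            L = nn.conv_out_len(L, spec.kernel, spec.stride, spec.padding)
            if L <= 0:
                raise ValueError(
                    f"input_length {self.input_length} collapses to zero at "
                    f"a conv layer")
            out.append(L)
        return out

    @property
    def flatten_length(self):
        return self.layers[-1].out_channels * self.layer_lengths()[-1]


@dataclass
class ModelSpec:
    """Single source of truth for the architecture."""

    mode: str = "fusion"                  # 'fusion' | 'spectral' | 'image'
    backbone: str = "shufflenet_v2"
    num_classes: int = 12
    spectral: SpectralBranchConfig = field(default_factory=SpectralBranchConfig)
    use_branch_attention: bool = True     # CBAM (1-D) + SE (2-D)
    use_cma: bool = True                  # cross-modal attention fusion
    se_reduction: int = 16
    fusion_dim: int = 64
    cma_scale: str = "sqrt"               # 'sqrt' -> sqrt(C'), 'dim' -> C'
    cma_post_norm: bool = True
    leaky_slope: float = 0.01
    tie_shared_fc: bool = True

    def __post_init__(self):
        if self.mode not in ("fusion", "spectral", "image"):
            raise ValueError("mode must be 'fusion', 'spectral', or 'image'")

    def to_json(self, path=None):
        d = asdict(self)
        text = json.dumps(d, indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text):
        d = json.loads(text)
        spec = d.pop("spectral", None)
        obj = cls(**d)
        if spec is not None:
            layers = tuple(ConvLayerSpec(**l) for l in spec.pop("layers"))
            obj.spectral = SpectralBranchConfig(layers=layers, **spec)
        return obj


def ablation_specs(base: ModelSpec | None = None):
    """The four-model ablation lattice sharing one base configuration."""
    base = base or ModelSpec()
    return {
        "spectral": replace(base, mode="spectral"),
        "image": replace(base, mode="image"),
        "fusion_no_attention": replace(base, mode="fusion",
                                       use_branch_attention=False,
                                       use_cma=False),
        "fusion": replace(base, mode="fusion", use_branch_attention=True,
                          use_cma=True),
    }


class SpectralBranch(nn.Module):
    def __init__(self, cfg: SpectralBranchConfig, rng, use_attention=True):
        super().__init__()
        self.cfg = cfg
        blocks = []
        for spec in cfg.layers:
            blocks.append(nn.Conv1d(spec.in_channels, spec.out_channels,
                                    spec.kernel, rng, stride=spec.stride,
                                    pad=spec.padding))
            if spec.batch_norm:
                blocks.append(nn.BatchNorm(spec.out_channels))
            blocks.append(nn.ReLU())
        self.convs = nn.Sequential(*blocks)
        self.attention = (nn.ChannelAttention1d(cfg.layers[-1].out_channels, rng,
                                                cfg.attention_reduction)
                          if use_attention else None)
        self.fc1 = nn.Linear(cfg.flatten_length, cfg.fc1_out, rng)
        self.fc2 = nn.Linear(cfg.fc1_out, cfg.fc2_out, rng)

    def forward(self, x):
        if x.shape[-1] != self.cfg.input_length:
            raise ValueError(
                f"spectral branch expects length {self.cfg.input_length}, "
                f"got {x.shape[-1]}")
        if x.ndim == 2:
            x = ad.reshape(x, (x.shape[0], 1, x.shape[1]))
        h = self.convs(x)
        if self.attention is not None:
            h = self.attention(h)
        h = ad.reshape(h, (h.shape[0], -1))
        h = ad.relu(self.fc1(h))
        return ad.relu(self.fc2(h))      # (B, 128); shared FC applied by caller

    def conv_feature_shapes(self):
        lengths = self.cfg.layer_lengths()
        return [(spec.out_channels, L)
                for spec, L in zip(self.cfg.layers, lengths)]


class ImageBranch(nn.Module):
    def __init__(self, spec: ModelSpec, rng, use_attention=True):
        super().__init__()
        self.backbone = nn.build_backbone(spec.backbone, rng)
        ch = self.backbone.out_channels
        self.se = nn.SEBlock(ch, rng, spec.se_reduction) if use_attention else None
        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(ch, 128, rng)

    def forward(self, x):
        h = self.backbone(x)
        if self.se is not None:
            h = self.se(h)
        h = self.pool(h)
        return ad.relu(self.fc(h))       # (B, 128)


class MSIFusionNet(nn.Module):
    """Full two-branch network (or a unimodal ablation of it)."""

    def __init__(self, spec: ModelSpec, rng=None):
        super().__init__()
        rng = np.random.default_rng(0) if rng is None else rng
        self.spec = spec
        attn = spec.use_branch_attention
        self.spectral_branch = (SpectralBranch(spec.spectral, rng, attn)
                                if spec.mode != "image" else None)
        self.image_branch = (ImageBranch(spec, rng, attn)
                             if spec.mode != "spectral" else None)
        self.shared_fc = nn.Linear(128, spec.fusion_dim, rng)
        self.shared_fc_image = (self.shared_fc if spec.tie_shared_fc
                                else nn.Linear(128, spec.fusion_dim, rng))
        if spec.mode == "fusion":
            if spec.use_cma:
                self.fuse = nn.CrossModalAttention(
                    spec.fusion_dim, rng, scale=spec.cma_scale,
                    post_norm=spec.cma_post_norm,
                    leaky_slope=spec.leaky_slope)
            else:
                self.fuse_fc = nn.Linear(2 * spec.fusion_dim, spec.fusion_dim, rng)
                self.fuse_bn = nn.BatchNorm(spec.fusion_dim)
        self.classifier = nn.Linear(spec.fusion_dim, spec.num_classes, rng)

    def _spectral_features(self, spectra):
        return ad.relu(self.shared_fc(self.spectral_branch(spectra)))

    def _image_features(self, images):
        return ad.relu(self.shared_fc_image(self.image_branch(images)))

    def forward_logits(self, spectra=None, images=None):
        mode = self.spec.mode
        if mode in ("fusion", "spectral") and spectra is None:
            raise ValueError(f"mode {mode!r} requires spectra")
        if mode in ("fusion", "image") and images is None:
            raise ValueError(f"mode {mode!r} requires images")
        if mode == "spectral":
            feat = self._spectral_features(spectra)
        elif mode == "image":
            feat = self._image_features(images)
        else:
            if spectra.shape[0] != images.shape[0]:
                raise ValueError("unpaired batch: spectra and images differ "
                                 "in batch size")
            f_img = self._image_features(images)
            f_spec = self._spectral_features(spectra)
            if self.spec.use_cma:
                feat = self.fuse(f_img, f_spec)
            else:
                h = self.fuse_fc(ad.concat([f_img, f_spec], axis=1))
                feat = ad.leaky_relu(self.fuse_bn(h), self.spec.leaky_slope)
        return self.classifier(feat)

    def forward(self, spectra=None, images=None):
        """Class probabilities (rows sum to 1)."""
        return nn.softmax(self.forward_logits(spectra, images), axis=1)

    def features(self, spectra=None, images=None):
        """The 64-d representation entering the classifier head."""
        mode = self.spec.mode
        if mode == "spectral":
            return self._spectral_features(spectra).data
        if mode == "image":
            return self._image_features(images).data
        f_img = self._image_features(images)
        f_spec = self._spectral_features(spectra)
        if self.spec.use_cma:
            return self.fuse(f_img, f_spec).data
        h = self.fuse_fc(ad.concat([f_img, f_spec], axis=1))
        return ad.leaky_relu(self.fuse_bn(h), self.spec.leaky_slope).data


def build_model(spec: ModelSpec, seed=0) -> MSIFusionNet:
    return MSIFusionNet(spec, np.random.default_rng(seed))


def count_parameters(model_or_spec):
    """(trainable parameter count, float32 checkpoint size in MiB).

    Size is ``count * 4 bytes / 2**20`` rounded to two decimals — the
    relation the printed model-size column obeys.
    """
    model = (build_model(model_or_spec) if isinstance(model_or_spec, ModelSpec)
             else model_or_spec)
    count = int(sum(p.data.size for p in model.parameters()))
    return count, float32_size_mib(count)


def float32_size_mib(n_params: int) -> float:
    return round(n_params * 4 / 2 ** 20, 2)


def spectral_branch_param_count(cfg: SpectralBranchConfig,
                                include_attention=True) -> int:
    """Closed-form trainable-parameter count of the spectral branch
    (conv weights + BN affine pairs + FC layers + channel-attention MLP)."""
    total = 0
    for spec in cfg.layers:
        total += spec.out_channels * spec.in_channels * spec.kernel
        total += spec.out_channels              # conv bias
        if spec.batch_norm:
            total += 2 * spec.out_channels      # BN affine pair
    flat = cfg.flatten_length
    total += flat * cfg.fc1_out + cfg.fc1_out
    total += cfg.fc1_out * cfg.fc2_out + cfg.fc2_out
    if include_attention:
        C, r = cfg.layers[-1].out_channels, cfg.attention_reduction
        total += C * (C // r) + C // r          # fc1 of the shared MLP
        total += (C // r) * C + C               # fc2
    return total


def architecture_summary(model: MSIFusionNet) -> pd.DataFrame:
    """Per-layer table: name, shape, parameter count."""
    rows = [{"layer": name, "shape": str(p.data.shape),
             "n_params": int(p.data.size)}
            for name, p in model.named_parameters()]
    return pd.DataFrame(rows)


def save_checkpoint(model: MSIFusionNet, path: str) -> None:
    np.savez_compressed(path, spec=model.spec.to_json(),
                        **{k.replace(".", "__"): v
                           for k, v in model.state_dict().items()})


def load_checkpoint(path: str) -> MSIFusionNet:
    with np.load(path, allow_pickle=False) as z:
        spec = ModelSpec.from_json(str(z["spec"]))
        state = {k.replace("__", "."): z[k] for k in z.files if k != "spec"}
    model = build_model(spec)
    model.load_state_dict(state)
    return model
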