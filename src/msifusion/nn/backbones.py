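"""2-D backbone registry for the image branch.

Every backbone is a module mapping ``(B, 3, H, W)`` to a channel-last feature
map ``(B, C_out, h, w)``; the branch head (SE block, global pool, fully
connected layers) is attached by the model builder.  Registered backbones:

``shufflenet_v2``
    Native ShuffleNetV2 1.0x: stem conv + maxpool, three stages of units with
    channel split / depthwise conv / channel shuffle, and a final 1x1 conv to
    1024 channels.
``vgg16``
    The 13-convolution VGG16 trunk (no classifier head).
``tiny``
    A three-layer strided CNN (64 output channels) for fast experiments on
    small images; used throughout the scaled-down synthetic studies.
"""

from __future__ import annotations

from .autodiff import Tensor
from . import autodiff as ad
from .layers import (BatchNorm, ChannelShuffle, Conv2d, DepthwiseConv2d,
                     MaxPool2d, Module, ReLU, Sequential)


def _conv_bn_relu(cin, cout, k, rng, stride=1, pad=0):
    return Sequential(Conv2d(cin, cout, k, rng, stride=stride, pad=pad, bias=False),
                      BatchNorm(cout), ReLU())


class ShuffleUnit(Module):
    """ShuffleNetV2 building block.

    stride 1: channel split; one half passes through 1x1 -> dw3x3 -> 1x1;
    halves are concatenated and shuffled.
    stride 2: both halves are transformed (spatial downsampling), doubling
    the channel count.
    """

    def __init__(self, cin, cout, stride, rng):
        super().__init__()
        self.stride = stride
        branch = cout // 2
        if stride == 1:
            assert cin == cout, "stride-1 unit keeps channel count"
            self.main = Sequential(
                _conv_bn_relu(branch, branch, 1, rng),
                DepthwiseConv2d(branch, 3, rng, stride=1, pad=1),
                BatchNorm(branch),
                _conv_bn_relu(branch, branch, 1, rng),
            )
            self.proj = None
        else:
            self.main = Sequential(
                _conv_bn_relu(cin, branch, 1, rng),
                DepthwiseConv2d(branch, 3, rng, stride=2, pad=1),
                BatchNorm(branch),
                _conv_bn_relu(branch, branch, 1, rng),
            )
            self.proj = Sequential(
                DepthwiseConv2d(cin, 3, rng, stride=2, pad=1),
                BatchNorm(cin),
                _conv_bn_relu(cin, branch, 1, rng),
            )
        self.shuffle = ChannelShuffle(2)

    def forward(self, x):
        if self.stride == 1:
            half = x.shape[1] // 2
            x1 = x[:, :half]
            x2 = x[:, half:]
            out = ad.concat([x1, self.main(x2)], axis=1)
        else:
            out = ad.concat([self.proj(x), self.main(x)], axis=1)
        return self.shuffle(out)


class ShuffleNetV2(Module):
    """ShuffleNetV2 at 1.0x width: stages (116, 232, 464), final conv 1024."""

    STAGE_CHANNELS = (116, 232, 464)
    STAGE_REPEATS = (4, 8, 4)
    out_channels = 1024

    def __init__(self, rng):
        super().__init__()
        self.stem = _conv_bn_relu(3, 24, 3, rng, stride=2, pad=1)
        self.pool = MaxPool2d(3, stride=2, pad=1)
        stages, cin = [], 24
        for cout, reps in zip(self.STAGE_CHANNELS, self.STAGE_REPEATS):
            units = [ShuffleUnit(cin, cout, 2, rng)]
            units += [ShuffleUnit(cout, cout, 1, rng) for _ in range(reps - 1)]
            stages.append(Sequential(*units))
            cin = cout
        self.stages = stages
        self.head = _conv_bn_relu(cin, self.out_channels, 1, rng)

    def forward(self, x):
        x = self.pool(self.stem(x))
        for stage in self.stages:
            x = stage(x)
        return self.head(x)


class VGG16Trunk(Module):
    """The 13 convolutional layers of VGG16 (classifier head omitted)."""

    CFG = (64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
           512, 512, 512, "M", 512, 512, 512, "M")
    out_channels = 512

    def __init__(self, rng):
        super().__init__()
        mods, cin = [], 3
        for v in self.CFG:
            if v == "M":
                mods.append(MaxPool2d(2, stride=2))
            else:
                mods.append(Conv2d(cin, v, 3, rng, stride=1, pad=1))
                mods.append(ReLU())
                cin = v
        self.features = Sequential(*mods)

    def forward(self, x):
        return self.features(x)


class TinyCNN(Module):
    """Three strided conv/BN/ReLU blocks; accepts any input >= 8x8."""

    out_channels = 64

    def __init__(self, rng):
        super().__init__()
        self.features = Sequential(
            _conv_bn_relu(3, 16, 3, rng, stride=2, pad=1),
            _conv_bn_relu(16, 32, 3, rng, stride=2, pad=1),
            _conv_bn_relu(32, 64, 3, rng, stride=2, pad=1),
        )

    def forward(self, x):
        return self.features(x)


BACKBONES = {
    "shufflenet_v2": ShuffleNetV2,
    "vgg16": VGG16Trunk,
    "tiny": TinyCNN,
}


def build_backbone(name, rng):
    """Instantiate a registered backbone; unknown names list the registry."""
    try:
        cls = BACKBONES[name]
    except KeyError:
        raise ValueError(
            f"unknown backbone {name!r}; registered: {sorted(BACKBONES)}"
        ) from None
    return cls(rng)
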