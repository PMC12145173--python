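"""Image branch: a modified multi-channel residual network over cell images.

The stem replaces the standard 7x7 input convolution: one depthwise 3x3
convolution branch per dilation rate (default rates 1, 2, 3) runs over the
raw channels, the branch outputs are summed, mixed by a pointwise (1x1)
convolution to ``stem_width`` channels (batch-norm + ReLU), then downsampled
by a stride-2 average pool and a 3x3/stride-2 max pool, matching the usual
stage-0 contract of H/4 x W/4 spatial size. Four bottleneck residual stages
follow (stride-2 transitions from stage 2 onward).

The classifier head does not use only the last stage: each stage's output is
globally average-pooled, the four pooled vectors are concatenated, and a
granularity-level attention gate — an elementwise sigmoid of an affine map of
the concatenation — reweights every feature using cross-stage context. A
projection layer then maps the gated vector to the final image feature
(default width 512) feeding a linear + softmax classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .datamodel import DEFAULT_CHANNELS
from .nn import Tensor, concat

__all__ = [
    "BackboneConfig",
    "DilatedDepthwiseStem",
    "Bottleneck",
    "GranularityAttention",
    "ImageBranch",
    "multi_stage_pool",
]


@dataclass
class BackboneConfig:
    """Architecture hyperparameters for the image branch.

    The ``full`` preset mirrors a standard 50-layer residual backbone; the
    ``tiny`` preset keeps the same topology at desk scale.
    """

    in_channels: int = 5
    channel_names: tuple = DEFAULT_CHANNELS
    stem_width: int = 64
    stage_widths: tuple = (256, 512, 1024, 2048)
    blocks_per_stage: tuple = (3, 4, 6, 3)
    dilation_rates: tuple = (1, 2, 3)
    feature_dim: int = 512
    n_classes: int = 10
    attention_gate: str = "sigmoid"  # or "softmax"

    @classmethod
    def tiny(cls, **kw):
        defaults = dict(
            stem_width=16,
            stage_widths=(32, 64, 128, 256),
            blocks_per_stage=(1, 1, 1, 1),
        )
        defaults.update(kw)
        return cls(**defaults)

    @property
    def concat_width(self) -> int:
        return sum(self.stage_widths)


class DilatedDepthwiseStem(nn.Module):
    """Parallel dilated depthwise branches -> sum -> pointwise conv -> BN/ReLU
    -> stride-2 downsample -> 3x3 max pool (total spatial reduction x4)."""

    def __init__(self, config: BackboneConfig, rng, dtype=np.float32):
        super().__init__()
        c = config.in_channels
        self.branches = [
            nn.Conv2d(c, c, 3, rng, padding=r, dilation=r, groups=c, bias=False, dtype=dtype)
            for r in config.dilation_rates
        ]
        self.pointwise = nn.Conv2d(c, config.stem_width, 1, rng, bias=False, dtype=dtype)
        self.bn = nn.BatchNorm(config.stem_width, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        merged = None
        for branch in self.branches:
            y = branch(x)
            merged = y if merged is None else merged + y
        y = self.bn(self.pointwise(merged)).relu()
        # stride-2 downsample (2x2 average pool) then 3x3/stride-2 max pool
        n, c, h, w = y.shape
        y = y.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
        return nn.max_pool2d(y, 3, 2, 1)


class Bottleneck(nn.Module):
    """Standard 1x1 -> 3x3 -> 1x1 bottleneck residual block (reduction 4)."""

    def __init__(self, in_ch, out_ch, rng, stride=1, dtype=np.float32):
        super().__init__()
        mid = out_ch // 4
        self.conv1 = nn.Conv2d(in_ch, mid, 1, rng, bias=False, dtype=dtype)
        self.bn1 = nn.BatchNorm(mid, dtype=dtype)
        self.conv2 = nn.Conv2d(mid, mid, 3, rng, stride=stride, padding=1, bias=False, dtype=dtype)
        self.bn2 = nn.BatchNorm(mid, dtype=dtype)
        self.conv3 = nn.Conv2d(mid, out_ch, 1, rng, bias=False, dtype=dtype)
        self.bn3 = nn.BatchNorm(out_ch, dtype=dtype)
        if stride != 1 or in_ch != out_ch:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride, bias=False, dtype=dtype)
            self.bn_proj = nn.BatchNorm(out_ch, dtype=dtype)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y)).relu()
        y = self.bn3(self.conv3(y))
        shortcut = x if self.proj is None else self.bn_proj(self.proj(x))
        return (y + shortcut).relu()


class GranularityAttention(nn.Module):
    """Elementwise gate alpha = f(W . OS + b) over the concatenated pooled
    stage features; output = alpha (*) OS."""

    def __init__(self, width, rng, gate="sigmoid", dtype=np.float32):
        super().__init__()
        self.linear = nn.Linear(width, width, rng, dtype=dtype)
        self.gate = gate

    def scores(self, os: Tensor) -> Tensor:
        z = self.linear(os)
        if self.gate == "softmax":
            return z.softmax(axis=-1)
        return z.sigmoid()

    def forward(self, os: Tensor) -> Tensor:
        return self.scores(os) * os


def multi_stage_pool(stage_maps) -> Tensor:
    """Global average pooling of each stage map, concatenated in stage order."""
    pooled = [m.mean(axis=(2, 3)) for m in stage_maps]
    return concat(pooled, axis=1)


class ImageBranch(nn.Module):
    """Stem + 4 residual stages + multi-stage pooling + granularity attention
    + projection to the final image feature + linear/softmax classifier."""

    def __init__(
        self,
        config: BackboneConfig | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        self.config = cfg = config or BackboneConfig()
        rng = rng or np.random.default_rng(0)
        self.stem = DilatedDepthwiseStem(cfg, rng, dtype)
        self.stages = []
        in_ch = cfg.stem_width
        for i, (width, n_blocks) in enumerate(zip(cfg.stage_widths, cfg.blocks_per_stage)):
            blocks = []
            for b in range(n_blocks):
                stride = 2 if (i > 0 and b == 0) else 1
                blocks.append(Bottleneck(in_ch, width, rng, stride=stride, dtype=dtype))
                in_ch = width
            self.stages.append(nn.Sequential(*blocks))
        self.attention = GranularityAttention(cfg.concat_width, rng, cfg.attention_gate, dtype)
        self.projection = nn.Linear(cfg.concat_width, cfg.feature_dim, rng, dtype=dtype)
        self.classifier = nn.Linear(cfg.feature_dim, cfg.n_classes, rng, dtype=dtype)

    def stage_maps(self, x) -> list:
        """Run stem and stages; returns the four stage outputs."""
        x = Tensor.as_tensor(x)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, got {x.shape[1]}"
            )
        y = self.stem(x)
        maps = []
        for stage in self.stages:
            y = stage(y)
            maps.append(y)
        return maps

    def features(self, x) -> Tensor:
        """Final image feature, (N, feature_dim)."""
        os = multi_stage_pool(self.stage_maps(x))
        return self.projection(self.attention(os))

    def forward(self, x) -> dict:
        feat = self.features(x)
        logits = self.classifier(feat)
        return {"feature": feat, "logits": logits}

    def predict_scores(self, x) -> np.ndarray:
        """Softmax class probabilities, (N, n_classes)."""
        return self.forward(x)["logits"].softmax(axis=1).data
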