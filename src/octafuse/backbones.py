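"""3D classification backbones: ResNet50, DenseNet121 and EfficientNetB0.

Each canonical 2D architecture is converted to 3D by replacing every 2D
convolution/pooling with its cubic counterpart, preserving the stage layout.
A ``width_mult`` knob uniformly scales channel counts (floor of 8 channels)
so the networks remain trainable on a CPU at small volume sizes.  All models
are trained from scratch — no pretrained weights exist for these 3D variants.

Every backbone exposes, besides the plain ``forward`` pass, a 4-level feature
pyramid (stage outputs at successively halved spatial resolution plus the
globally pooled feature vector) used by the hierarchical fusion models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

ARCHS = ("resnet50_3d", "densenet121_3d", "efficientnetb0_3d")

# fixed intensity normalisation applied at network entry; OCTA volumes are
# nonnegative with typical intensities around 0.3-0.5 of the dynamic range
INPUT_CENTER = 0.35
INPUT_SCALE = 0.35


def _normalize_input(x: nn.Tensor) -> nn.Tensor:
    return nn.Tensor((x.data - INPUT_CENTER) / INPUT_SCALE)


@dataclass
class BackboneSpec:
    """Declarative description of a classification backbone."""

    arch: str = "resnet50_3d"
    in_channels: int = 2
    n_classes: int = 6
    width_mult: float = 1.0

    def validate(self) -> None:
        if self.arch not in ARCHS:
            raise ValueError(f"unknown arch {self.arch!r}; choose from {ARCHS}")
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0 < self.width_mult <= 1:
            raise ValueError("width_mult must lie in (0, 1]")


@dataclass
class FeaturePyramid:
    """Per-stage feature maps plus the global pooled vector."""

    stages: list = field(default_factory=list)
    pooled: nn.Tensor | None = None


def _c(ch: int, wm: float) -> int:
    """Scale a channel count, keeping at least 8 channels."""
    return max(8, int(round(ch * wm)))


def n_parameters(model: nn.Module) -> int:
    return sum(p.data.size for p in model.parameters())


# ---------------------------------------------------------------------------
# ResNet50-3D
# ---------------------------------------------------------------------------

class Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, in_ch, planes, stride, rng):
        super().__init__()
        out_ch = planes * self.expansion
        self.conv1 = nn.Conv3d(in_ch, planes, 1, rng=rng)
        self.bn1 = nn.BatchNorm3d(planes)
        self.conv2 = nn.Conv3d(planes, planes, 3, stride, 1, rng=rng)
        self.bn2 = nn.BatchNorm3d(planes)
        self.conv3 = nn.Conv3d(planes, out_ch, 1, rng=rng)
        self.bn3 = nn.BatchNorm3d(out_ch)
        # zero-init the last BN scale so each block starts as the identity,
        # which markedly speeds up optimisation of the 50-layer stack
        self.bn3.gamma.data[...] = 0.0
        self.down = None
        if stride != 1 or in_ch != out_ch:
            self.down = nn.Sequential(nn.Conv3d(in_ch, out_ch, 1, stride, rng=rng),
                                      nn.BatchNorm3d(out_ch))

    def forward(self, x):
        identity = self.down(x) if self.down is not None else x
        h = nn.relu(self.bn1(self.conv1(x)))
        h = nn.relu(self.bn2(self.conv2(h)))
        h = self.bn3(self.conv3(h))
        return nn.relu(nn.add(h, identity))


class ResNet50_3D(nn.Module):
    layers = (3, 4, 6, 3)

    def __init__(self, spec: BackboneSpec, rng):
        super().__init__()
        wm = spec.width_mult
        c0 = _c(64, wm)
        self.stem = nn.Sequential(nn.Conv3d(spec.in_channels, c0, 7, 2, 3, rng=rng),
                                  nn.BatchNorm3d(c0), nn.ReLU())
        self.stages = []
        in_ch = c0
        self.stage_channels = []
        for i, n_blocks in enumerate(self.layers):
            planes = _c(64 * 2 ** i, wm)
            blocks = []
            for j in range(n_blocks):
                stride = 2 if (j == 0 and i > 0) else 1
                blocks.append(Bottleneck(in_ch, planes, stride, rng))
                in_ch = planes * Bottleneck.expansion
            self.stages.append(nn.Sequential(*blocks))
            self.stage_channels.append(in_ch)
        self.pooled_dim = in_ch
        self.head = nn.Linear(in_ch, spec.n_classes, rng=rng)

    def forward_features(self, x) -> FeaturePyramid:
        h = self.stem(_normalize_input(x))
        h = nn.maxpool3d(h, 3, 2, 1)
        pyr = FeaturePyramid()
        for stage in self.stages:
            h = stage(h)
            pyr.stages.append(h)
        pyr.pooled = nn.global_avgpool3d(h)
        return pyr

    def forward(self, x):
        return self.head(self.forward_features(x).pooled)


# ---------------------------------------------------------------------------
# DenseNet121-3D
# ---------------------------------------------------------------------------

class DenseLayer(nn.Module):
    def __init__(self, in_ch, growth, bn_size, rng):
        super().__init__()
        mid = bn_size * growth
        self.bn1 = nn.BatchNorm3d(in_ch)
        self.conv1 = nn.Conv3d(in_ch, mid, 1, rng=rng)
        self.bn2 = nn.BatchNorm3d(mid)
        self.conv2 = nn.Conv3d(mid, growth, 3, 1, 1, rng=rng)

    def forward(self, x):
        h = self.conv1(nn.relu(self.bn1(x)))
        h = self.conv2(nn.relu(self.bn2(h)))
        return nn.concat([x, h], axis=1)


class Transition(nn.Module):
    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.bn = nn.BatchNorm3d(in_ch)
        self.conv = nn.Conv3d(in_ch, out_ch, 1, rng=rng)

    def forward(self, x):
        return nn.avgpool3d(self.conv(nn.relu(self.bn(x))), 2, 2)


class DenseNet121_3D(nn.Module):
    block_config = (6, 12, 24, 16)

    def __init__(self, spec: BackboneSpec, rng):
        super().__init__()
        wm = spec.width_mult
        growth = _c(32, wm)
        bn_size = 4
        ch = _c(64, wm)
        self.stem = nn.Sequential(nn.Conv3d(spec.in_channels, ch, 7, 2, 3, rng=rng),
                                  nn.BatchNorm3d(ch), nn.ReLU())
        self.blocks = []
        self.transitions = []
        self.stage_channels = []
        for i, n_layers in enumerate(self.block_config):
            layers = []
            for _ in range(n_layers):
                layers.append(DenseLayer(ch, growth, bn_size, rng))
                ch += growth
            self.blocks.append(nn.Sequential(*layers))
            self.stage_channels.append(ch)
            if i < len(self.block_config) - 1:
                self.transitions.append(Transition(ch, ch // 2, rng))
                ch //= 2
        self.final_bn = nn.BatchNorm3d(ch)
        self.pooled_dim = ch
        self.head = nn.Linear(ch, spec.n_classes, rng=rng)

    def forward_features(self, x) -> FeaturePyramid:
        h = self.stem(_normalize_input(x))
        h = nn.maxpool3d(h, 3, 2, 1)
        pyr = FeaturePyramid()
        for i, block in enumerate(self.blocks):
            h = block(h)
            pyr.stages.append(h)
            if i < len(self.transitions):
                h = self.transitions[i](h)
        h = nn.relu(self.final_bn(h))
        pyr.pooled = nn.global_avgpool3d(h)
        return pyr

    def forward(self, x):
        return self.head(self.forward_features(x).pooled)


# ---------------------------------------------------------------------------
# EfficientNetB0-3D
# ---------------------------------------------------------------------------

class SqueezeExcite(nn.Module):
    def __init__(self, ch, se_ch, rng):
        super().__init__()
        self.fc1 = nn.Linear(ch, se_ch, rng=rng)
        self.fc2 = nn.Linear(se_ch, ch, rng=rng)
        self.ch = ch

    def forward(self, x):
        s = nn.global_avgpool3d(x)
        s = nn.sigmoid(self.fc2(nn.silu(self.fc1(s))))
        return nn.mul(x, nn.reshape(s, (x.shape[0], self.ch, 1, 1, 1)))


class MBConv(nn.Module):
    def __init__(self, in_ch, out_ch, expand, kernel, stride, se_div, rng):
        super().__init__()
        mid = in_ch * expand
        self.expand = None
        if expand != 1:
            self.expand = nn.Sequential(nn.Conv3d(in_ch, mid, 1, rng=rng),
                                        nn.BatchNorm3d(mid), nn.SiLU())
        self.dw = nn.DepthwiseConv3d(mid, kernel, stride, kernel // 2, rng=rng)
        self.dw_bn = nn.BatchNorm3d(mid)
        self.se = SqueezeExcite(mid, max(1, in_ch // se_div), rng)
        self.project = nn.Conv3d(mid, out_ch, 1, rng=rng)
        self.project_bn = nn.BatchNorm3d(out_ch)
        self.use_skip = stride == 1 and in_ch == out_ch
        if self.use_skip:
            self.project_bn.gamma.data[...] = 0.0

    def forward(self, x):
        h = self.expand(x) if self.expand is not None else x
        h = nn.silu(self.dw_bn(self.dw(h)))
        h = self.se(h)
        h = self.project_bn(self.project(h))
        return nn.add(h, x) if self.use_skip else h


class EfficientNetB0_3D(nn.Module):
    # (expand_ratio, channels, repeats, stride, kernel)
    cfg = ((1, 16, 1, 1, 3), (6, 24, 2, 2, 3), (6, 40, 2, 2, 5),
           (6, 80, 3, 2, 3), (6, 112, 3, 1, 5), (6, 192, 4, 2, 5),
           (6, 320, 1, 1, 3))
    # pyramid taps after these stage indices: strides 4, 8, 16, 32
    tap_after = (1, 2, 4, 6)

    def __init__(self, spec: BackboneSpec, rng):
        super().__init__()
        wm = spec.width_mult
        ch = _c(32, wm)
        self.stem = nn.Sequential(nn.Conv3d(spec.in_channels, ch, 3, 2, 1, rng=rng),
                                  nn.BatchNorm3d(ch), nn.SiLU())
        self.stage_blocks = []
        self.stage_channels = []
        for expand, c, reps, stride, kernel in self.cfg:
            out_ch = _c(c, wm)
            blocks = []
            for j in range(reps):
                blocks.append(MBConv(ch, out_ch, expand, kernel,
                                     stride if j == 0 else 1, 4, rng))
                ch = out_ch
            self.stage_blocks.append(nn.Sequential(*blocks))
        self.stage_channels = [_c(self.cfg[i][1], wm) for i in self.tap_after]
        head_ch = _c(1280, wm)
        self.head_conv = nn.Sequential(nn.Conv3d(ch, head_ch, 1, rng=rng),
                                       nn.BatchNorm3d(head_ch), nn.SiLU())
        self.pooled_dim = head_ch
        self.head = nn.Linear(head_ch, spec.n_classes, rng=rng)

    def forward_features(self, x) -> FeaturePyramid:
        h = self.stem(_normalize_input(x))
        pyr = FeaturePyramid()
        for i, stage in enumerate(self.stage_blocks):
            h = stage(h)
            if i in self.tap_after:
                pyr.stages.append(h)
        h = self.head_conv(h)
        pyr.pooled = nn.global_avgpool3d(h)
        return pyr

    def forward(self, x):
        return self.head(self.forward_features(x).pooled)


# ---------------------------------------------------------------------------
# factory
# ---------------------------------------------------------------------------

_BUILDERS = {
    "resnet50_3d": ResNet50_3D,
    "densenet121_3d": DenseNet121_3D,
    "efficientnetb0_3d": EfficientNetB0_3D,
}


def build_backbone(spec: BackboneSpec, seed: int = 0) -> nn.Module:
    """Build a backbone with deterministic, seeded initial parameters."""
    spec.validate()
    rng = np.random.default_rng(seed)
    model = _BUILDERS[spec.arch](spec, rng)
    model.spec = spec
    return model


def extract_feature_pyramid(model: nn.Module, x: nn.Tensor) -> FeaturePyramid:
    """Run the backbone and return its multiscale feature pyramid.

    The pyramid is consistent with the plain forward pass: applying the
    model head to ``pyramid.pooled`` reproduces the forward logits.
    """
    x = nn.astensor(x)
    if x.shape[1] != model.spec.in_channels:
        raise ValueError(
            f"input has {x.shape[1]} channels, model expects {model.spec.in_channels}")
    return model.forward_features(x)
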