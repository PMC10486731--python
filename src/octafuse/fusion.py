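"""Multimodal fusion topologies for OCTA severity grading.

Single-acquisition fusion combines the registered structure and flow channels
of one scan at one of four levels:

* input fusion — channel concatenation into a single backbone;
* feature fusion — one backbone per channel, pooled features concatenated
  before a single fully connected decision head;
* decision fusion — one full classifier per channel, class probabilities
  combined by averaging or renormalised elementwise maximum;
* hierarchical fusion — two modality branches plus a third fusion branch
  that, at each of the four feature-pyramid scales, merges the channel
  concatenation of both branch feature maps (1x1x1 projection) into its own
  downsampling stack; the decision head sees all three pooled vectors.

Cross-acquisition fusion combines the *unregistered* high-resolution and
ultra-widefield scans of the same eye, either at the feature level (a joint
network assembled from the two pretrained per-acquisition hierarchical
models, fine-tuned fully or head-only) or at the decision level.  The
proposed hybrid model is hierarchical fusion within each acquisition plus
decision averaging across acquisitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbones import BackboneSpec, build_backbone
from .synthetic import ValidationError

logger = logging.getLogger(__name__)

FUSION_LEVELS = ("input", "feature", "decision", "hierarchical")
DECISION_RULES = ("avg", "max")
CROSS_STRATEGIES = ("feature_finetune_full", "feature_finetune_head",
                    "decision_avg", "decision_max")


@dataclass
class FusionSpec:
    """Declarative description of a fusion topology."""

    level: str = "hierarchical"
    branch_specs: list = field(default_factory=list)   # one BackboneSpec per modality
    decision_rule: str = "avg"
    cross_acquisition: str | None = None

    def validate(self) -> None:
        if self.level not in FUSION_LEVELS:
            raise ValidationError(f"unknown fusion level {self.level!r}")
        if self.decision_rule not in DECISION_RULES:
            raise ValidationError(f"unknown decision rule {self.decision_rule!r}")
        if self.cross_acquisition is not None and \
                self.cross_acquisition not in CROSS_STRATEGIES:
            raise ValidationError(
                f"unknown cross-acquisition strategy {self.cross_acquisition!r}")
        if self.level == "input":
            if len(self.branch_specs) != 1:
                raise ValidationError("input fusion uses exactly one backbone")
        elif len(self.branch_specs) < 2:
            raise ValidationError(f"{self.level} fusion needs one branch per modality")


def _as_input(x) -> nn.Tensor:
    return nn.astensor(x)


class FusionModel(nn.Module):
    """Common surface: forward -> logits, training_loss, predict_proba."""

    n_classes = 6

    def training_loss(self, x, y) -> nn.Tensor:
        return nn.cross_entropy(self.forward(x), y)

    def predict_proba(self, x) -> np.ndarray:
        self.eval()
        with nn.no_grad():
            logits = self.forward(x if isinstance(x, tuple) else _as_input(x))
        return nn.softmax(logits.data)


# ---------------------------------------------------------------------------
# single-acquisition topologies
# ---------------------------------------------------------------------------

class InputFusionModel(FusionModel):
    """Single backbone on the channel-concatenated modalities."""

    def __init__(self, backbone):
        super().__init__()
        self.backbone = backbone
        self.in_channels = backbone.spec.in_channels

    def forward(self, x):
        x = _as_input(x)
        if x.shape[1] != self.in_channels:
            raise ValidationError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}")
        return self.backbone(x)


class FeatureFusionModel(FusionModel):
    """Per-modality branches; pooled features concatenated into one FC head."""

    def __init__(self, branches, head):
        super().__init__()
        self.branches = branches
        self.head = head
        self.branch_channels = [b.spec.in_channels for b in branches]

    def _split(self, x):
        # inputs are leaves, so channel slices can be detached safely
        xs, c0 = [], 0
        for c in self.branch_channels:
            xs.append(nn.Tensor(x.data[:, c0:c0 + c]))
            c0 += c
        return xs

    def branch_features(self, xs):
        return [b.forward_features(x).pooled for b, x in zip(self.branches, xs)]

    def forward_multi(self, xs):
        """Branches may receive different grids (unregistered inputs)."""
        xs = [_as_input(x) for x in xs]
        return self.head(nn.concat(self.branch_features(xs), axis=1))

    def forward(self, x):
        x = _as_input(x)
        if x.shape[1] != sum(self.branch_channels):
            raise ValidationError("channel count does not match branch channels")
        return self.forward_multi(self._split(x))


class DecisionFusionModel(FusionModel):
    """Independent per-modality classifiers; probabilities fused post hoc."""

    def __init__(self, branches, rule="avg"):
        super().__init__()
        self.branches = branches
        self.rule = rule
        self.branch_channels = [b.spec.in_channels for b in branches]

    def _split_np(self, x):
        xs, c0 = [], 0
        for c in self.branch_channels:
            xs.append(x[:, c0:c0 + c])
            c0 += c
        return xs

    def forward(self, x):
        # joint logits are not defined for decision fusion; average branch
        # logits only as a convenience for shape contracts
        x = _as_input(x)
        outs = [b(nn.Tensor(xi)) for b, xi in zip(self.branches, self._split_np(x.data))]
        acc = outs[0]
        for o in outs[1:]:
            acc = nn.add(acc, o)
        return nn.mul(acc, nn.Tensor(np.float32(1.0 / len(outs))))

    def training_loss(self, x, y):
        x = _as_input(x)
        losses = [nn.cross_entropy(b(nn.Tensor(xi)), y)
                  for b, xi in zip(self.branches, self._split_np(x.data))]
        acc = losses[0]
        for l in losses[1:]:
            acc = nn.add(acc, l)
        return acc

    def predict_proba(self, x):
        self.eval()
        x = _as_input(x)
        with nn.no_grad():
            probs = [nn.softmax(b(nn.Tensor(xi)).data)
                     for b, xi in zip(self.branches, self._split_np(x.data))]
        return np.stack([fuse_decisions(list(ps), self.rule)
                         for ps in zip(*probs)])


class HierarchicalFusionModel(FusionModel):
    """Two modality branches plus a multiscale fusion branch.

    At scale ``s`` the fusion branch computes
    ``f_s = relu(stage_s(f_{s-1}) + proj_s(concat(b1_s, b2_s)))`` where
    ``proj_s`` is a 1x1x1 convolution to the fusion width and ``stage_s`` a
    stride-2 3x3x3 convolution (absent at the first scale).  The decision
    head consumes ``[b1 pooled, b2 pooled, fusion pooled]``.
    """

    def __init__(self, branch1, branch2, projections, fusion_stages,
                 fusion_bns, head):
        super().__init__()
        self.branch1, self.branch2 = branch1, branch2
        self.projections = projections
        self.fusion_stages = fusion_stages
        self.fusion_bns = fusion_bns
        self.head = head
        self.branch_channels = [branch1.spec.in_channels, branch2.spec.in_channels]

    def trunk_features(self, x):
        """(B, 3 * pooled) features: both branch poolings plus fusion pooling."""
        x = _as_input(x)
        c1 = self.branch_channels[0]
        x1 = nn.Tensor(x.data[:, :c1])
        x2 = nn.Tensor(x.data[:, c1:c1 + self.branch_channels[1]])
        py1 = self.branch1.forward_features(x1)
        py2 = self.branch2.forward_features(x2)
        if len(py1.stages) != len(py2.stages):
            raise ValidationError("branches have mismatched stage counts")
        f = None
        for s, (a, b) in enumerate(zip(py1.stages, py2.stages)):
            m = self.projections[s](nn.concat([a, b], axis=1))
            if f is None:
                f = nn.relu(m)
            else:
                t = self.fusion_bns[s - 1](self.fusion_stages[s - 1](f))
                f = nn.relu(nn.add(t, m))
        pf = nn.global_avgpool3d(f)
        return nn.concat([py1.pooled, py2.pooled, pf], axis=1)

    def forward(self, x):
        return self.head(self.trunk_features(x))


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_input_fusion(spec: FusionSpec, seed: int = 0) -> InputFusionModel:
    spec.validate()
    if spec.level != "input":
        raise ValidationError("spec.level must be 'input'")
    return InputFusionModel(build_backbone(spec.branch_specs[0], seed))


def build_feature_fusion(spec: FusionSpec, seed: int = 0) -> FeatureFusionModel:
    spec.validate()
    branches = [build_backbone(bs, seed + i) for i, bs in enumerate(spec.branch_specs)]
    rng = np.random.default_rng(seed + 1000)
    head = nn.Linear(sum(b.pooled_dim for b in branches),
                     spec.branch_specs[0].n_classes, rng=rng)
    return FeatureFusionModel(branches, head)


def build_decision_fusion(spec: FusionSpec, seed: int = 0) -> DecisionFusionModel:
    spec.validate()
    branches = [build_backbone(bs, seed + i) for i, bs in enumerate(spec.branch_specs)]
    return DecisionFusionModel(branches, spec.decision_rule)


def build_hierarchical_fusion(spec: FusionSpec, seed: int = 0) -> HierarchicalFusionModel:
    spec.validate()
    if spec.level != "hierarchical":
        raise ValidationError("spec.level must be 'hierarchical'")
    b1 = build_backbone(spec.branch_specs[0], seed)
    b2 = build_backbone(spec.branch_specs[1], seed + 1)
    if len(b1.stage_channels) != len(b2.stage_channels):
        raise ValidationError("branches have mismatched stage counts")
    rng = np.random.default_rng(seed + 2000)
    widths = b1.stage_channels                    # fusion width = branch width
    projections, stages, bns = [], [], []
    for s, w in enumerate(widths):
        cat = b1.stage_channels[s] + b2.stage_channels[s]
        projections.append(nn.Sequential(nn.Conv3d(cat, w, 1, rng=rng),
                                         nn.BatchNorm3d(w)))
        if s > 0:
            stages.append(nn.Conv3d(widths[s - 1], w, 3, 2, 1, rng=rng))
            bns.append(nn.BatchNorm3d(w))
    head = nn.Linear(b1.pooled_dim + b2.pooled_dim + widths[-1],
                     spec.branch_specs[0].n_classes, rng=rng)
    return HierarchicalFusionModel(b1, b2, projections, stages, bns, head)


def build_fusion_model(spec: FusionSpec, seed: int = 0) -> FusionModel:
    spec.validate()
    return {"input": build_input_fusion, "feature": build_feature_fusion,
            "decision": build_decision_fusion,
            "hierarchical": build_hierarchical_fusion}[spec.level](spec, seed)


# ---------------------------------------------------------------------------
# decision-level probability fusion
# ---------------------------------------------------------------------------

def fuse_decisions(probs, rule: str = "avg") -> np.ndarray:
    """Combine class-probability vectors by averaging or renormalised maximum.

    Both rules are symmetric in argument order and return a valid probability
    vector; the elementwise maximum is renormalised to sum to one.
    """
    if len(probs) == 0:
        raise ValidationError("cannot fuse an empty list of probability vectors")
    if rule not in DECISION_RULES:
        raise ValidationError(f"unknown decision rule {rule!r}")
    mat = np.asarray(probs, dtype=np.float64)
    if mat.ndim != 2 or np.any(mat < -1e-9) or \
            np.any(np.abs(mat.sum(axis=1) - 1.0) > 1e-5):
        raise ValidationError("inputs must be probability vectors")
    if rule == "avg":
        return mat.mean(axis=0)
    m = mat.max(axis=0)
    return m / m.sum()


# ---------------------------------------------------------------------------
# cross-acquisition fusion
# ---------------------------------------------------------------------------

class CrossFeatureFusionModel(FusionModel):
    """Joint network over both acquisitions, assembled from two pretrained
    per-acquisition hierarchical models with a fresh concatenation head."""

    def __init__(self, model_hr, model_uwf, head):
        super().__init__()
        self.model_hr, self.model_uwf = model_hr, model_uwf
        self.head = head
        self.freeze_trunk = False

    def trunks(self, x_hr, x_uwf):
        if self.freeze_trunk:
            with nn.no_grad():
                f1 = self.model_hr.trunk_features(x_hr)
                f2 = self.model_uwf.trunk_features(x_uwf)
            return nn.Tensor(f1.data), nn.Tensor(f2.data)
        return self.model_hr.trunk_features(x_hr), self.model_uwf.trunk_features(x_uwf)

    def forward(self, x):
        x_hr, x_uwf = x
        f1, f2 = self.trunks(_as_input(x_hr), _as_input(x_uwf))
        return self.head(nn.concat([f1, f2], axis=1))

    def head_parameters(self):
        return self.head.parameters()


def build_cross_feature_fusion(model_hr: HierarchicalFusionModel,
                               model_uwf: HierarchicalFusionModel,
                               seed: int = 0) -> CrossFeatureFusionModel:
    rng = np.random.default_rng(seed)
    d = model_hr.head.weight.data.shape[1] + model_uwf.head.weight.data.shape[1]
    head = nn.Linear(d, model_hr.n_classes, rng=rng)
    return CrossFeatureFusionModel(model_hr, model_uwf, head)


def cross_feature_finetune(model: CrossFeatureFusionModel,
                           mode: str) -> CrossFeatureFusionModel:
    """Configure fine-tuning: 'full' trains everything, 'head_only' freezes
    both pretrained trunks and trains only the new decision head."""
    if mode not in ("full", "head_only"):
        raise ValidationError("mode must be 'full' or 'head_only'")
    head_ids = {id(p) for p in model.head_parameters()}
    for p in model.parameters():
        p.requires_grad = (mode == "full") or id(p) in head_ids
    model.freeze_trunk = mode == "head_only"
    return model


def build_hybrid_model(per_acquisition: dict, cross_rule: str = "avg") -> "HybridModel":
    """Assemble the proposed hybrid model from per-acquisition models."""
    return HybridModel(per_acquisition, cross_rule)


class HybridModel:
    """Hierarchical fusion per acquisition + decision fusion across them.

    Eye-level prediction decision-fuses the two acquisition-level aggregated
    probability vectors (averaging for the proposed configuration).  When one
    acquisition is missing at predict time the model falls back to the single
    available branch and logs a warning.
    """

    def __init__(self, per_acquisition: dict, rule: str = "avg"):
        if rule not in DECISION_RULES:
            raise ValidationError(f"unknown decision rule {rule!r}")
        if not per_acquisition:
            raise ValidationError("need at least one per-acquisition model")
        self.models = dict(per_acquisition)
        self.rule = rule

    def available(self, volumes: dict) -> list[str]:
        acqs = [a for a in self.models if a in volumes]
        if not acqs:
            raise ValidationError("no acquisition available for prediction")
        if len(acqs) < len(self.models):
            missing = sorted(set(self.models) - set(acqs))
            logger.warning("missing acquisition(s) %s; falling back to %s",
                           missing, acqs)
        return acqs

    def fuse(self, probs_by_acq: dict, scores_by_acq: dict):
        """Fuse acquisition-level aggregated probabilities and task scores."""
        probs = [probs_by_acq[a] for a in sorted(probs_by_acq)]
        scores = np.asarray([scores_by_acq[a] for a in sorted(scores_by_acq)])
        fused_p = fuse_decisions(probs, self.rule)
        fused_s = scores.mean(axis=0) if self.rule == "avg" else scores.max(axis=0)
        return fused_p, fused_s
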