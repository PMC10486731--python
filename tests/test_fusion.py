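"""Fusion topology contracts and decision-fusion algebra."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octafuse import nn
from octafuse.backbones import BackboneSpec, n_parameters
from octafuse.fusion import (FusionSpec, HybridModel, build_cross_feature_fusion,
                             build_decision_fusion, build_feature_fusion,
                             build_fusion_model, build_hierarchical_fusion,
                             build_hybrid_model, build_input_fusion,
                             cross_feature_finetune, fuse_decisions)
from octafuse.synthetic import ValidationError


def _bs(c, n_classes=6):
    return BackboneSpec("resnet50_3d", c, n_classes, 0.25)


RNG = np.random.default_rng(0)
X = RNG.standard_normal((2, 2, 16, 16, 16)).astype(np.float32)


class TestInputFusion:
    def test_accepts_channel_concatenated_modalities(self):
        m = build_input_fusion(FusionSpec("input", [_bs(2)]), 0).eval()
        assert m.predict_proba(X).shape == (2, 6)

    def test_channel_count_mismatch_rejected(self):
        m = build_input_fusion(FusionSpec("input", [_bs(2)]), 0)
        with pytest.raises(ValidationError):
            m(nn.Tensor(X[:, :1]))

    def test_channel_order_matters(self):
        m = build_input_fusion(FusionSpec("input", [_bs(2)]), 0).eval()
        with nn.no_grad():
            a = m(nn.Tensor(X)).data
            b = m(nn.Tensor(X[:, ::-1].copy())).data
        assert not np.allclose(a, b)

    def test_duplicated_modality_accepted(self):
        m = build_input_fusion(FusionSpec("input", [_bs(2)]), 0).eval()
        doubled = np.concatenate([X[:, 1:], X[:, 1:]], axis=1)
        assert np.all(np.isfinite(m.predict_proba(doubled)))


class TestFeatureFusion:
    def test_head_consumes_concatenated_pooled_features(self):
        m = build_feature_fusion(FusionSpec("feature", [_bs(1), _bs(1)]), 0)
        d1, d2 = m.branches[0].pooled_dim, m.branches[1].pooled_dim
        assert m.head.weight.data.shape == (6, d1 + d2)

    def test_forward_is_linear_head_over_branch_features(self):
        m = build_feature_fusion(FusionSpec("feature", [_bs(1), _bs(1)]), 0).eval()
        with nn.no_grad():
            logits = m(nn.Tensor(X)).data
            f1 = m.branches[0].forward_features(nn.Tensor(X[:, :1])).pooled.data
            f2 = m.branches[1].forward_features(nn.Tensor(X[:, 1:])).pooled.data
        manual = np.concatenate([f1, f2], 1) @ m.head.weight.data.T + m.head.bias.data
        np.testing.assert_allclose(logits, manual, atol=1e-5)

    def test_branches_accept_different_grids(self):
        m = build_feature_fusion(FusionSpec("feature", [_bs(1), _bs(1)]), 0).eval()
        xa = RNG.standard_normal((1, 1, 16, 16, 16)).astype(np.float32)
        xb = RNG.standard_normal((1, 1, 24, 16, 24)).astype(np.float32)
        with nn.no_grad():
            out = m.forward_multi([nn.Tensor(xa), nn.Tensor(xb)])
        assert out.shape == (1, 6)


class TestDecisionFusionAlgebra:
    def test_average_of_two_vectors(self):
        got = fuse_decisions([[0.2, 0.8, 0, 0, 0, 0], [0.6, 0.4, 0, 0, 0, 0]], "avg")
        np.testing.assert_allclose(got, [0.4, 0.6, 0, 0, 0, 0])

    def test_max_renormalizes(self):
        got = fuse_decisions([[0.6, 0.4, 0, 0, 0, 0], [0.2, 0.8, 0, 0, 0, 0]], "max")
        np.testing.assert_allclose(got, np.array([0.6, 0.8, 0, 0, 0, 0]) / 1.4)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            fuse_decisions([], "avg")

    @given(st.lists(st.lists(st.floats(0.01, 1.0), min_size=6, max_size=6),
                    min_size=1, max_size=5),
           st.sampled_from(["avg", "max"]))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_fusion_stays_on_simplex_and_is_symmetric(self, rows, rule):
        probs = [np.array(r) / np.sum(r) for r in rows]
        out = fuse_decisions(probs, rule)
        assert out.shape == (6,)
        assert np.all(out >= 0) and abs(out.sum() - 1) < 1e-9
        np.testing.assert_allclose(out, fuse_decisions(probs[::-1], rule))
        np.testing.assert_allclose(fuse_decisions([probs[0]] * 3, rule), probs[0])


@pytest.fixture(scope="module")
def model():
    return build_hierarchical_fusion(
        FusionSpec("hierarchical", [_bs(1), _bs(1)]), 0)


@pytest.fixture(scope="module")
def joint():
    h1 = build_hierarchical_fusion(FusionSpec("hierarchical", [_bs(1), _bs(1)]), 1)
    h2 = build_hierarchical_fusion(FusionSpec("hierarchical", [_bs(1), _bs(1)]), 2)
    return build_cross_feature_fusion(h1, h2, 3)


class TestHierarchicalFusion:

    def test_four_merge_points_and_head_width(self, model):
        assert len(model.projections) == 4
        pooled = (model.branch1.pooled_dim + model.branch2.pooled_dim +
                  model.branch1.stage_channels[-1])
        assert model.head.weight.data.shape == (6, pooled)

    def test_forward_finite_probabilities(self, model):
        p = model.predict_proba(X)
        assert np.all(np.isfinite(p))
        np.testing.assert_allclose(p.sum(1), 1, atol=1e-6)

    def test_strictly_more_parameters_than_feature_fusion(self, model):
        ff = build_feature_fusion(FusionSpec("feature", [_bs(1), _bs(1)]), 0)
        assert n_parameters(model) > n_parameters(ff)

    def test_zeroed_fusion_branch_reduces_to_feature_fusion(self, model):
        import copy
        m = copy.deepcopy(model).eval()
        for seq in m.projections:
            for layer in seq.layers:
                for p in layer.parameters():
                    p.data[...] = 0
        for conv, bn in zip(m.fusion_stages, m.fusion_bns):
            for p in conv.parameters() + bn.parameters():
                p.data[...] = 0
        with nn.no_grad():
            feats = m.trunk_features(nn.Tensor(X)).data
            logits = m(nn.Tensor(X)).data
        d1, d2 = m.branch1.pooled_dim, m.branch2.pooled_dim
        # the fusion slice of the trunk is exactly zero ...
        assert np.abs(feats[:, d1 + d2:]).max() == 0
        # ... so the logits equal a feature-fusion head on the branch slices
        manual = feats[:, :d1 + d2] @ m.head.weight.data[:, :d1 + d2].T + \
            m.head.bias.data
        np.testing.assert_allclose(logits, manual, atol=1e-5)

    def test_mismatched_stage_counts_rejected(self):
        with pytest.raises(ValidationError):
            # 2-branch spec required
            build_hierarchical_fusion(FusionSpec("hierarchical", [_bs(1)]), 0)


class TestHybridModel:
    def test_identical_branch_outputs_pass_through_under_avg(self):
        hybrid = build_hybrid_model({"hr6": None, "uwf15": None}, "avg")
        p = np.array([0.1, 0.2, 0.3, 0.2, 0.1, 0.1])
        s = np.array([0.9, 0.7, 0.4, 0.2])
        fused_p, fused_s = hybrid.fuse({"hr6": p, "uwf15": p},
                                       {"hr6": s, "uwf15": s})
        np.testing.assert_allclose(fused_p, p)
        np.testing.assert_allclose(fused_s, s)

    def test_avg_rule_is_symmetric_and_is_the_mean(self):
        hybrid = build_hybrid_model({"hr6": None, "uwf15": None}, "avg")
        pa = np.array([0.5, 0.5, 0, 0, 0, 0.0])
        pb = np.array([0, 0, 0, 0, 0.5, 0.5])
        sa, sb = np.array([1, 0, 0, 0.0]), np.array([0, 0, 0, 1.0])
        f1, s1 = hybrid.fuse({"hr6": pa, "uwf15": pb}, {"hr6": sa, "uwf15": sb})
        f2, s2 = hybrid.fuse({"hr6": pb, "uwf15": pa}, {"hr6": sb, "uwf15": sa})
        np.testing.assert_allclose(f1, (pa + pb) / 2)
        np.testing.assert_allclose(f1, f2)
        np.testing.assert_allclose(s1, s2)

    def test_missing_acquisition_falls_back_with_warning(self, caplog):
        hybrid = HybridModel({"hr6": object(), "uwf15": object()}, "avg")
        with caplog.at_level(logging.WARNING, logger="octafuse.fusion"):
            acqs = hybrid.available({"hr6": object()})
        assert acqs == ["hr6"]
        assert any("missing acquisition" in r.message for r in caplog.records)
        with pytest.raises(ValidationError):
            hybrid.available({})


class TestCrossFeatureFusion:
    def test_head_only_trains_exactly_the_head(self, joint):
        cross_feature_finetune(joint, "head_only")
        trainable = [p for p in joint.parameters() if p.requires_grad]
        assert {id(p) for p in trainable} == {id(p) for p in joint.head_parameters()}

        xu = RNG.standard_normal((2, 2, 24, 16, 24)).astype(np.float32)
        before = [p.data.copy() for p in joint.model_hr.parameters()]
        opt = nn.Adam(joint.parameters(), lr=1e-2)
        joint.train()
        loss = joint.training_loss((X, xu), np.array([0, 3]))
        loss.backward()
        opt.step()
        for b, p in zip(before, joint.model_hr.parameters()):
            np.testing.assert_array_equal(b, p.data)   # trunks frozen solid

    def test_full_finetune_reaches_every_parameter(self, joint):
        cross_feature_finetune(joint, "full")
        # a couple of steps first so zero-initialised block scales open up
        xu = RNG.standard_normal((2, 2, 24, 16, 24)).astype(np.float32)
        opt = nn.Adam(joint.parameters(), lr=1e-2)
        joint.train()
        for _ in range(2):
            joint.zero_grad()
            loss = joint.training_loss((X, xu), np.array([0, 3]))
            loss.backward()
            opt.step()
        # the per-branch and per-acquisition decision heads are bypassed by
        # the joint head and take no part in the computation
        unused = {id(p) for m in (joint.model_hr, joint.model_uwf)
                  for h in (m.head, m.branch1.head, m.branch2.head)
                  for p in h.parameters()}
        grads = [p.grad for p in joint.parameters() if id(p) not in unused]
        assert all(g is not None for g in grads)
        assert sum(np.any(g != 0) for g in grads) / len(grads) > 0.9
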