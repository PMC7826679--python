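"""Worked examples, brute-force oracle equivalence and invariants for the
LFA / ADA / ARL operations and the assembled network."""

import numpy as np
import pytest

from farnet import ARLParams, BackboneConfig, FARNet
from farnet.nn import Tensor
from farnet.relation import (
    ARL,
    LFA,
    SEGate,
    fuse,
    predict_head,
    relation_features,
    relation_scores,
    relation_weights,
    se_excite,
    se_reweight,
    se_squeeze,
    spatial_softmax,
)


# ------------------------------------------------------------------ LFA


class TestLFA:
    def test_output_channels_and_spatial_size(self, rng):
        lfa = LFA(64, 8, mid_channels=16, rng=rng)
        x = Tensor(rng.normal(size=(2, 64, 8, 8)))
        s = lfa(x)
        assert s.shape == (2, 8, 8, 8)

    def test_channel_mismatch_raises(self, rng):
        lfa = LFA(64, 8, mid_channels=16, rng=rng)
        with pytest.raises(ValueError, match="channel"):
            lfa(Tensor(rng.normal(size=(1, 32, 8, 8))))

    def test_spatial_softmax_uniform_case(self):
        s = np.full((1, 3, 8, 8), 2.5)
        a = spatial_softmax(s).data
        np.testing.assert_allclose(a, 1.0 / 64, atol=1e-12)

    def test_spatial_softmax_worked_example(self):
        # 2×2 channel [[0, ln 2], [0, 0]] → [[0.2, 0.4], [0.2, 0.2]]
        s = np.array([[[[0.0, np.log(2.0)], [0.0, 0.0]]]])
        a = spatial_softmax(s).data[0, 0]
        np.testing.assert_allclose(a, [[0.2, 0.4], [0.2, 0.2]], atol=1e-12)

    def test_spatial_softmax_shift_invariance(self, rng):
        s = rng.normal(size=(2, 4, 5, 5))
        np.testing.assert_allclose(
            spatial_softmax(s).data, spatial_softmax(s + 137.5).data, atol=1e-9
        )

    def test_spatial_softmax_rejects_nonfinite(self):
        bad = np.zeros((1, 1, 2, 2))
        bad[0, 0, 0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            spatial_softmax(bad)

    def test_channels_sum_to_one_on_random_instances(self, rng):
        for _ in range(100):
            s = rng.normal(scale=rng.uniform(0.1, 10), size=(1, 8, 8, 8))
            sums = spatial_softmax(s).data.sum(axis=(2, 3))
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)
            assert (spatial_softmax(s).data >= 0).all()


# ------------------------------------------------------------------ ADA


class TestADA:
    def test_squeeze_is_spatial_mean(self):
        a = np.ones((1, 2, 8, 8))
        np.testing.assert_allclose(se_squeeze(a).data, 1.0)
        spike = np.zeros((1, 1, 8, 8))
        spike[0, 0, 3, 4] = 64.0
        np.testing.assert_allclose(se_squeeze(spike).data, 1.0)

    def test_squeeze_of_normalized_channel_is_constant(self, rng):
        a = spatial_softmax(rng.normal(size=(3, 8, 8, 8)))
        np.testing.assert_allclose(se_squeeze(a).data, 1.0 / 64, atol=1e-12)

    def test_excite_zero_params_give_half(self, rng):
        gate = SEGate(8, rng=rng)
        gate.fc1.weight.data[...] = 0
        gate.fc2.weight.data[...] = 0
        z = rng.normal(size=(5, 8))
        np.testing.assert_allclose(se_excite(z, gate).data, 0.5)

    def test_excite_open_interval(self, rng):
        gate = SEGate(8, rng=rng)
        s = se_excite(rng.normal(scale=3, size=(10, 8)), gate).data
        assert (s > 0).all() and (s < 1).all()

    def test_excite_dimension_mismatch(self, rng):
        gate = SEGate(8, rng=rng)
        with pytest.raises(ValueError):
            se_excite(np.zeros((1, 5)), gate)

    def test_reweight(self, rng):
        a = rng.normal(size=(2, 3, 4, 4))
        ones = np.ones((2, 3))
        np.testing.assert_array_equal(se_reweight(a, ones).data, a)
        np.testing.assert_array_equal(se_reweight(a, np.zeros((2, 3))).data, 0.0)
        single = np.array([[[[2.0]]]])
        np.testing.assert_allclose(se_reweight(single, np.array([[0.25]])).data, 0.5)
        with pytest.raises(ValueError):
            se_reweight(a, np.ones((2, 4)))


# ------------------------------------------------------------------ ARL


def brute_force_arl(fa: np.ndarray, w_q, w_k, w_v, denom: float):
    """Triple-loop reference for scores, weights and relation features."""
    n, c, hw = fa.shape
    ws = np.zeros((n, c, c))
    for i in range(n):
        for m in range(c):
            for l in range(c):
                ws[i, m, l] = (w_k.T @ fa[i, m]) @ (w_q.T @ fa[i, l]) / denom
    w = np.zeros((n, c, c))
    for i in range(n):
        for l in range(c):
            exps = {m: np.exp(ws[i, m, l]) for m in range(c) if m != l}
            z = sum(exps.values())
            for m, e in exps.items():
                w[i, m, l] = e / z
    fr = np.zeros((n, c, hw))
    for i in range(n):
        for l in range(c):
            for m in range(c):
                if m != l:
                    fr[i, l] += w[i, m, l] * (w_v.T @ fa[i, m])
    return ws, w, fr


class TestARLOracle:
    @pytest.mark.parametrize("c,hw,dk", [(2, 4, 3), (5, 16, 8), (8, 16, 16)])
    def test_vectorized_equals_brute_force(self, c, hw, dk, rng):
        arl = ARL(hw, c, ARLParams(dk=dk), rng=rng)
        fa = rng.normal(size=(3, c, hw))
        fr, w, ws = arl(Tensor(fa))
        ws_ref, w_ref, fr_ref = brute_force_arl(
            fa, arl.w_q.data, arl.w_k.data, arl.w_v.data, np.sqrt(dk)
        )
        off = 1 - np.eye(c)
        np.testing.assert_allclose(ws.data * off, ws_ref * off, atol=1e-6)
        np.testing.assert_allclose(w.data, w_ref, atol=1e-6)
        np.testing.assert_allclose(fr.data, fr_ref, atol=1e-6)

    def test_per_label_params_match_shared_loop(self, rng):
        c, hw, dk = 4, 9, 5
        arl = ARL(hw, c, ARLParams(dk=dk, per_label_params=True), rng=rng)
        fa = rng.normal(size=(2, c, hw))
        fr, w, ws = arl(Tensor(fa))
        # reference: per query label l use that label's own maps
        ws_ref = np.zeros((2, c, c))
        for i in range(2):
            for l in range(c):
                for m in range(c):
                    ws_ref[i, m, l] = (
                        (arl.w_k.data[l].T @ fa[i, m]) @ (arl.w_q.data[l].T @ fa[i, l])
                    ) / np.sqrt(dk)
        off = 1 - np.eye(c)
        np.testing.assert_allclose(ws.data * off, ws_ref * off, atol=1e-6)
        fr_ref = np.zeros((2, c, hw))
        for i in range(2):
            for l in range(c):
                for m in range(c):
                    if m != l:
                        fr_ref[i, l] += w.data[i, m, l] * (arl.w_v.data[l].T @ fa[i, m])
        np.testing.assert_allclose(fr.data, fr_ref, atol=1e-6)


class TestARLWorkedExamples:
    def test_identical_channels_give_constant_offdiagonal(self, rng):
        arl = ARL(4, 3, ARLParams(dk=2), rng=rng)
        arl.w_k.data[...] = arl.w_q.data
        fa = np.tile(rng.normal(size=(1, 1, 4)), (1, 3, 1))
        ws = relation_scores(fa, arl).data[0]
        off = ~np.eye(3, dtype=bool)
        assert np.ptp(ws[off]) < 1e-12

    def test_orthogonal_channels_zero_score(self):
        arl = ARL(2, 2, ARLParams(dk=2, scale="sqrt_dk"), rng=np.random.default_rng(0))
        arl.w_q.data[...] = np.eye(2)
        arl.w_k.data[...] = np.eye(2)
        fa = np.array([[[1.0, 0.0], [0.0, 2.0]]])
        ws = relation_scores(fa, arl).data[0]
        assert ws[1, 0] == pytest.approx(0.0)  # fA_2 ⟂ fA_1

    def test_weights_uniform_when_scores_equal(self):
        ws = np.zeros((1, 5, 5))
        w = relation_weights(ws).data[0]
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(w[off], 1.0 / 4)
        np.testing.assert_allclose(np.diag(w), 0.0)

    def test_two_labels_weight_is_one(self):
        w = relation_weights(np.zeros((1, 2, 2))).data[0]
        assert w[1, 0] == pytest.approx(1.0)
        assert w[0, 1] == pytest.approx(1.0)

    def test_three_label_softmax_worked_example(self):
        ws = np.zeros((1, 3, 3))
        ws[0, 1, 0] = np.log(2.0)  # wS_21 = ln 2
        ws[0, 2, 0] = 0.0
        w = relation_weights(ws).data[0]
        assert w[1, 0] == pytest.approx(2.0 / 3.0)
        assert w[2, 0] == pytest.approx(1.0 / 3.0)

    def test_weights_need_two_labels(self):
        with pytest.raises(ValueError):
            relation_weights(np.zeros((1, 1, 1)))

    def test_columns_sum_to_one_on_random_instances(self, rng):
        for _ in range(100):
            ws = rng.normal(scale=rng.uniform(0.5, 5), size=(1, 8, 8))
            w = relation_weights(ws).data[0]
            np.testing.assert_allclose(w.sum(axis=0), 1.0, atol=1e-6)
            assert (w >= 0).all()

    def test_relation_features_identity_value_map(self, rng):
        # C = 2, W_V = identity → fR_1 = fA_2
        arl = ARL(3, 2, ARLParams(dk=2), rng=rng)
        arl.w_v.data[...] = np.eye(3)
        fa = rng.normal(size=(1, 2, 3))
        w = relation_weights(np.zeros((1, 2, 2)))
        fr = relation_features(fa, w, arl).data
        np.testing.assert_allclose(fr[0, 0], fa[0, 1], atol=1e-12)
        np.testing.assert_allclose(fr[0, 1], fa[0, 0], atol=1e-12)

    def test_relation_features_weighted_sum_by_hand(self, rng):
        # C = 3, W_V = I, w_21 = 2/3, w_31 = 1/3, fA_2 ≡ 3, fA_3 ≡ 0 → fR_1 ≡ 2
        arl = ARL(4, 3, ARLParams(dk=2), rng=rng)
        arl.w_v.data[...] = np.eye(4)
        fa = np.zeros((1, 3, 4))
        fa[0, 1] = 3.0
        w = np.zeros((1, 3, 3))
        w[0, 1, 0], w[0, 2, 0] = 2.0 / 3.0, 1.0 / 3.0
        fr = relation_features(fa, Tensor(w), arl).data
        np.testing.assert_allclose(fr[0, 0], 2.0, atol=1e-12)

    def test_zero_features_give_zero_relations(self, rng):
        arl = ARL(4, 3, ARLParams(dk=2), rng=rng)
        fa = np.zeros((2, 3, 4))
        fr, _, _ = arl(Tensor(fa))
        np.testing.assert_array_equal(fr.data, 0.0)

    def test_scale_variants_and_validation(self):
        assert ARLParams(dk=64, scale="sqrt_dk").denominator == pytest.approx(8.0)
        assert ARLParams(dk=64, scale="dk").denominator == pytest.approx(64.0)
        with pytest.raises(ValueError):
            ARLParams(dk=0)
        with pytest.raises(ValueError):
            ARLParams(scale="cube")


# ------------------------------------------------------- fusion and head


class TestFusionHead:
    def test_fuse_sum_and_commutativity(self, rng):
        fa = rng.normal(size=(1, 2, 3, 3))
        fr = rng.normal(size=(1, 2, 3, 3))
        np.testing.assert_allclose(fuse(fa, fr).data, fa + fr)
        np.testing.assert_allclose(fuse(fr, fa).data, fuse(fa, fr).data)
        np.testing.assert_array_equal(fuse(fa, np.zeros_like(fa)).data, fa)
        with pytest.raises(ValueError):
            fuse(fa, rng.normal(size=(1, 2, 2, 2)))

    def test_head_zero_and_constant_channels(self):
        fm = np.zeros((1, 2, 8, 8))
        fm[0, 1] = 1.7
        logits, conf = predict_head(fm)
        assert conf.data[0, 0] == pytest.approx(0.5)
        assert conf.data[0, 1] == pytest.approx(1 / (1 + np.exp(-1.7)))

    def test_head_spiked_channel(self):
        fm = np.zeros((1, 1, 8, 8))
        fm[0, 0, 2, 5] = 64.0
        logits, conf = predict_head(fm)
        assert logits.data[0, 0] == pytest.approx(1.0)
        assert conf.data[0, 0] == pytest.approx(0.7311, abs=1e-4)


# ----------------------------------------------------- assembled network


class TestFARNet:
    def test_deterministic_inference_and_range(self, tiny_net, image_batch):
        a = tiny_net.predict(image_batch)
        b = tiny_net.predict(image_batch)
        np.testing.assert_array_equal(a, b)
        assert (a >= 0).all() and (a <= 1).all()

    def test_without_arl_equals_pooled_gated_features(self, image_batch):
        net = FARNet(BackboneConfig(arch="tiny"), n_labels=8, without_arl=True, seed=3).eval()
        out = net.forward_full(image_batch)
        np.testing.assert_allclose(
            out["logits"].data, out["fA"].data.mean(axis=(2, 3)), atol=1e-12
        )
        assert "fR" not in out

    def test_without_ada_passes_aggregated_features(self, image_batch):
        net = FARNet(BackboneConfig(arch="tiny"), n_labels=8, without_ada=True, seed=3).eval()
        out = net.forward_full(image_batch)
        np.testing.assert_array_equal(out["fA"].data, out["A"].data)

    def test_baseline_is_backbone_pool_linear(self, image_batch):
        net = FARNet(
            BackboneConfig(arch="tiny"),
            n_labels=8,
            without_lfa=True,
            without_ada=True,
            without_arl=True,
            seed=3,
        ).eval()
        out = net.forward_full(image_batch)
        pooled = out["X"].data.mean(axis=(2, 3))
        expected = pooled @ net.baseline_head.weight.data + net.baseline_head.bias.data
        np.testing.assert_allclose(out["logits"].data, expected, atol=1e-10)

    def test_without_lfa_alone_rejected(self):
        with pytest.raises(ValueError, match="without_lfa"):
            FARNet(BackboneConfig(arch="tiny"), n_labels=8, without_lfa=True)

    def test_label_permutation_equivariance(self, image_batch):
        """Permuting label order (with LFA last-layer filters, SE rows/cols and
        ARL per-label maps permuted accordingly) permutes the confidences."""
        net = FARNet(
            BackboneConfig(arch="tiny"),
            n_labels=5,
            arl_params=ARLParams(dk=8, per_label_params=True),
            seed=11,
        ).eval()
        perm = np.array([3, 0, 4, 1, 2])
        base = net.predict(image_batch)
        last = net.lfa.block.layers[2]
        last.conv.weight.data[...] = last.conv.weight.data[perm]
        last.bn.gamma.data[...] = last.bn.gamma.data[perm]
        last.bn.beta.data[...] = last.bn.beta.data[perm]
        last.bn.running_mean.data[...] = last.bn.running_mean.data[perm]
        last.bn.running_var.data[...] = last.bn.running_var.data[perm]
        for fc in (net.se.fc1, net.se.fc2):
            fc.weight.data[...] = fc.weight.data[np.ix_(perm, perm)]
            fc.bias.data[...] = fc.bias.data[perm]
        for wmat in (net.arl.w_q, net.arl.w_k, net.arl.w_v):
            wmat.data[...] = wmat.data[perm]
        permuted = net.predict(image_batch)
        np.testing.assert_allclose(permuted, base[:, perm], atol=1e-8)

    def test_gate_shutdown_leaves_relation_only_logits(self, image_batch):
        """Driving all SE gates to 0 removes the fA term from the pooled
        logit, leaving only the relation-feature contribution."""
        net = FARNet(BackboneConfig(arch="tiny"), n_labels=8, seed=5).eval()
        out = net.forward_full(image_batch)
        # force the gate to ~0 by saturating the second FC layer's bias
        net.se.fc2.bias.data[...] = -500.0
        shut = net.forward_full(image_batch)
        np.testing.assert_allclose(shut["fA"].data, 0.0, atol=1e-12)
        np.testing.assert_allclose(
            shut["logits"].data, shut["fR"].data.mean(axis=(2, 3)), atol=1e-12
        )
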