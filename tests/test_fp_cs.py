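"""Fingerprint-branch checks: padding layout, loss identities and gradients,
encoder sharing/independence, fusion and classifier contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from moafuse.fp_cs import (
    FingerprintBranch,
    FPBranchConfig,
    common_feature,
    common_loss,
    common_target,
    gram_matrix,
    pad_quad,
    specific_feature,
    specific_loss,
)
from moafuse.nn import Linear, Sequential, Tensor


def quad(*rows):
    return tuple(np.asarray(r, dtype=np.float64) for r in rows)


EX_QUAD = quad((2.0, 0.0), (0.0, 2.0), (0.0, 0.0), (2.0, 2.0))


class TestPadding:
    def test_each_type_occupies_its_block(self):
        padded = pad_quad(quad((1.0, 2.0), (3.0, 4.0), (5.0, 6.0), (7.0, 8.0)))
        assert np.allclose(padded[1].data, [0, 0, 3, 4, 0, 0, 0, 0])
        assert np.allclose(padded[0].data, [1, 2, 0, 0, 0, 0, 0, 0])
        assert np.allclose(padded[3].data, [0, 0, 0, 0, 0, 0, 7, 8])

    def test_pad_then_extract_block_round_trips(self):
        q = quad((1.0, 2.0), (3.0, 4.0), (5.0, 6.0), (7.0, 8.0))
        padded = pad_quad(q)
        for slot in range(4):
            assert np.allclose(padded[slot].data[2 * slot : 2 * slot + 2], q[slot])

    def test_all_zero_quad_pads_to_all_zero(self):
        padded = pad_quad(quad((0.0, 0.0), (0.0, 0.0), (0.0, 0.0), (0.0, 0.0)))
        assert all(np.all(p.data == 0) for p in padded)


class TestCommonSpace:
    def test_target_is_the_mean(self):
        assert np.allclose(common_target(EX_QUAD).data, [1.0, 1.0])

    def test_target_of_identical_vectors_is_that_vector(self):
        v = np.array([3.0, -1.0])
        assert np.allclose(common_target(quad(v, v, v, v)).data, v)

    def test_target_is_permutation_invariant(self, rng):
        q = tuple(rng.normal(size=3) for _ in range(4))
        perm = (q[2], q[0], q[3], q[1])
        assert np.allclose(common_target(q).data, common_target(perm).data)

    def test_loss_zero_iff_identical(self):
        v = np.array([1.0, 2.0])
        assert common_loss(quad(v, v, v, v)).item() == pytest.approx(0.0)
        assert common_loss(EX_QUAD).item() > 0

    def test_loss_on_worked_example_is_eight(self):
        # target (1,1); each vector at squared distance 2 from it
        assert common_loss(EX_QUAD).item() == pytest.approx(8.0)

    def test_loss_equals_pairwise_distance_identity(self, rng):
        for _ in range(100):
            q = tuple(rng.normal(size=5) for _ in range(4))
            pairwise = sum(
                np.sum((q[j] - q[k]) ** 2) for j in range(4) for k in range(j + 1, 4)
            )
            assert common_loss(q).item() == pytest.approx(pairwise / 4.0, abs=1e-9)

    def test_feature_is_sum_and_four_times_target(self, rng):
        q = tuple(rng.normal(size=4) for _ in range(4))
        assert np.allclose(common_feature(q).data, np.sum(q, axis=0))
        assert np.allclose(common_feature(q).data, 4.0 * common_target(q).data)
        assert np.allclose(common_feature(EX_QUAD).data, [4.0, 4.0])

    def test_loss_value_invariant_under_slot_relabeling(self, rng):
        q = tuple(rng.normal(size=6) for _ in range(4))
        perm = (q[3], q[1], q[0], q[2])
        assert common_loss(q).item() == pytest.approx(common_loss(perm).item())


class TestSpecificSpace:
    def test_orthonormal_rows_give_zero_loss(self):
        assert specific_loss(quad(*np.eye(4))).item() == pytest.approx(0.0)

    def test_four_identical_unit_rows_give_twelve(self):
        r = np.array([1.0, 0.0, 0.0, 0.0])
        assert specific_loss(quad(r, r, r, r)).item() == pytest.approx(12.0)

    def test_scaled_identity_gives_thirty_six(self):
        assert specific_loss(quad(*(2.0 * np.eye(4)))).item() == pytest.approx(36.0)

    def test_loss_nonnegative_on_random_quads(self, rng):
        for _ in range(20):
            q = tuple(rng.normal(size=6) for _ in range(4))
            assert specific_loss(q).item() >= 0.0

    def test_row_normalized_variant_ignores_row_scale(self, rng):
        q = tuple(rng.normal(size=5) for _ in range(4))
        scaled = tuple(3.0 * v for v in q)
        a = specific_loss(q, normalize_rows=True).item()
        b = specific_loss(scaled, normalize_rows=True).item()
        assert a == pytest.approx(b, rel=1e-9)

    def test_concatenation_order_and_round_trip(self):
        feat = specific_feature(quad([1.0], [2.0], [3.0], [4.0]))
        assert np.allclose(feat.data, [1, 2, 3, 4])
        q = quad([1.0, 5.0], [2.0, 6.0], [3.0, 7.0], [4.0, 8.0])
        feat = specific_feature(q)
        for t in range(4):
            assert np.allclose(feat.data[2 * t : 2 * t + 2], q[t])

    def test_gram_matrix_is_h_h_transpose(self, rng):
        q = tuple(rng.normal(size=3) for _ in range(4))
        h = np.stack(q)
        assert np.allclose(gram_matrix(q).data[0], h @ h.T)


class TestLossGradients:
    """Finite-difference vs autodiff on 4x4 toys."""

    def test_common_loss_gradient(self, rng):
        q0 = [rng.normal(size=4) for _ in range(4)]
        tensors = [Tensor(v, requires_grad=True) for v in q0]
        common_loss(tensors).backward()
        eps = 1e-6
        for t_idx, t in enumerate(tensors):
            num = np.zeros(4)
            for i in range(4):
                qp = [v.copy() for v in q0]
                qm = [v.copy() for v in q0]
                qp[t_idx][i] += eps
                qm[t_idx][i] -= eps
                num[i] = (common_loss(qp).item() - common_loss(qm).item()) / (2 * eps)
            assert np.abs(num - t.grad).max() / max(np.abs(num).max(), 1e-12) < 1e-4

    def test_specific_loss_gradient(self, rng):
        q0 = [rng.normal(size=4) for _ in range(4)]
        tensors = [Tensor(v, requires_grad=True) for v in q0]
        specific_loss(tensors).backward()
        eps = 1e-6
        for t_idx, t in enumerate(tensors):
            num = np.zeros(4)
            for i in range(4):
                qp = [v.copy() for v in q0]
                qm = [v.copy() for v in q0]
                qp[t_idx][i] += eps
                qm[t_idx][i] -= eps
                num[i] = (specific_loss(qp).item() - specific_loss(qm).item()) / (2 * eps)
            assert np.abs(num - t.grad).max() / max(np.abs(num).max(), 1e-12) < 1e-4


class TestBranchModules:
    LENGTHS = {"rdk": 16, "ecfp": 16, "pubchem": 12, "maccs": 8}
    CFG = FPBranchConfig(d=6, d_c=5, d_s=4, d_f=3, fpc_hidden=7, fps_hidden=7, fusion_hidden=5)

    def make(self, seed=0):
        return FingerprintBranch(4, self.LENGTHS, self.CFG, np.random.default_rng(seed),
                                 dtype=np.float64)

    def batch(self, rng, n=3):
        return tuple(
            (rng.random((n, L)) < 0.3).astype(np.float64)
            for L in (16, 16, 12, 8)
        )

    def test_embedder_is_affine_per_type(self, rng):
        model = self.make()
        q = self.batch(rng)
        emb = model.embedder(q)
        for lin, x, e in zip(model.embedder.linears, q, emb):
            assert np.allclose(e.data, x @ lin.weight.data + lin.bias.data)

    def test_identity_embedder_passes_through(self):
        lin = Linear(2, 2, np.random.default_rng(0), dtype=np.float64)
        lin.weight.data = np.eye(2)
        lin.bias.data = np.zeros(2)
        out = lin(Tensor(np.array([[1.0, 0.0]])))
        assert np.allclose(out.data, [[1.0, 0.0]])

    def test_common_encoder_shares_weights_across_views(self, rng):
        model = self.make()
        q = self.batch(rng)
        out = model(q)
        # feed view 0's padded embedding through the encoder used for view 2
        from moafuse.fp_cs import pad_quad

        padded = pad_quad(model.embedder(q))
        same = model.fpc(padded[0])
        assert np.allclose(same.data, out["common"][0].data)

    def test_two_layer_encoder_matches_hand_computation(self):
        rng0 = np.random.default_rng(0)
        enc = Sequential(Linear(3, 2, rng0, dtype=np.float64), __import__("moafuse.nn", fromlist=["ReLU"]).ReLU(), Linear(2, 2, rng0, dtype=np.float64))
        x = np.array([[1.0, -2.0, 0.5]])
        w1, b1 = enc.layers[0].weight.data, enc.layers[0].bias.data
        w2, b2 = enc.layers[2].weight.data, enc.layers[2].bias.data
        ref = np.maximum(x @ w1 + b1, 0) @ w2 + b2
        assert np.allclose(enc(Tensor(x)).data, ref)

    def test_specific_encoders_are_independent(self, rng):
        model = self.make()
        w0 = model.fps[0].layers[0].weight.data
        w1 = model.fps[1].layers[0].weight.data
        assert not np.allclose(w0, w1)

    def test_fused_width_and_score_validity(self, rng):
        model = self.make()
        out = model(self.batch(rng, n=5))
        assert out["fused"].shape == (5, 3)
        scores = model.predict_scores(self.batch(rng, n=5))
        assert scores.shape == (5, 4)
        assert np.all(scores >= 0)
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_classifier_gives_uniform_scores(self, rng):
        model = self.make()
        model.classifier.weight.data[:] = 0
        model.classifier.bias.data[:] = 0
        scores = model.predict_scores(self.batch(rng, n=2))
        assert np.allclose(scores, 0.25, atol=1e-12)

    def test_single_logit_softmax_closed_form(self):
        logits = Tensor(np.array([[1.0, 0.0, 0.0]]))
        p = logits.softmax(axis=1).data[0]
        e = np.exp(1.0)
        assert p[0] == pytest.approx(e / (e + 2.0))


def test_export_embeddings_writes_per_sample_features(tmp_path, rng):
    import pandas as pd

    from moafuse.fp_cs import export_embeddings

    cfg = TestBranchModules.CFG
    model = FingerprintBranch(4, TestBranchModules.LENGTHS, cfg, np.random.default_rng(0),
                              dtype=np.float64)
    quad = TestBranchModules().batch(rng, n=3)
    path = tmp_path / "emb.csv"
    export_embeddings(model, quad, ["a", "b", "c"], path)
    df = pd.read_csv(path)
    assert list(df["compound_id"]) == ["a", "b", "c"]
    # common (d_c) + specific (4*d_s) + fused (d_f) columns
    assert df.shape[1] == 1 + cfg.d_c + 4 * cfg.d_s + cfg.d_f


@settings(max_examples=30, deadline=None)
@given(
    arrays(np.float64, (4, 5), elements=st.floats(-10, 10, allow_nan=False))
)
def test_common_loss_identity_property(h):
    q = tuple(h)
    pairwise = sum(np.sum((q[j] - q[k]) ** 2) for j in range(4) for k in range(j + 1, 4))
    assert common_loss(q).item() == pytest.approx(pairwise / 4.0, abs=1e-8)
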