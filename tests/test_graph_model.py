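import numpy as np
import pytest

import gaitkit as gk
from gaitkit.autodiff import Tensor, graph_conv, temporal_conv
from gaitkit.graph import SkeletonGraph, base_normalized_adjacency
from gaitkit.model import EncoderConfig, STGCNEncoder, stgcn_block
from gaitkit.training import supcon_loss


def brute_force_normalized_adjacency(A, M):
    """Entrywise double-loop oracle for Lambda^{-1/2}((A+I)(x)M)Lambda^{-1/2}."""
    n = A.shape[0]
    AI = A + np.eye(n)
    deg = AI.sum(axis=1)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = AI[i, j] * M[i, j] / (np.sqrt(deg[i]) * np.sqrt(deg[j]))
    return out


def random_graph(rng, n):
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:
                A[i, j] = A[j, i] = 1.0
    return A


class TestNormalizedAdjacency:
    def test_two_node_path_closed_form(self):
        """On the 2-vertex path with unit mask, A+I is all-ones and both
        degrees are 2, so every operator entry is exactly 0.5."""
        g = SkeletonGraph(A=np.array([[0.0, 1.0], [1.0, 0.0]]),
                          M=np.ones((2, 2)))
        np.testing.assert_allclose(gk.build_normalized_adjacency(g),
                                   0.5 * np.ones((2, 2)), atol=1e-15)

    def test_edgeless_graph_is_identity(self):
        g = SkeletonGraph(A=np.zeros((4, 4)), M=np.ones((4, 4)))
        np.testing.assert_allclose(gk.build_normalized_adjacency(g), np.eye(4),
                                   atol=1e-15)

    def test_matches_brute_force_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 12))
            A = random_graph(rng, n)
            M = rng.uniform(0.5, 1.5, size=(n, n))
            g = SkeletonGraph(A=A, M=M)
            np.testing.assert_allclose(gk.build_normalized_adjacency(g),
                                       brute_force_normalized_adjacency(A, M),
                                       atol=1e-12)

    def test_coco_operator_symmetric_with_unit_mask_spectral_radius(self):
        g = SkeletonGraph()
        S = gk.build_normalized_adjacency(g)
        np.testing.assert_allclose(S, S.T, atol=1e-15)
        assert np.max(np.abs(np.linalg.eigvalsh(S))) <= 1.0 + 1e-12

    def test_invalid_graphs_rejected(self):
        with pytest.raises(ValueError):
            SkeletonGraph(A=np.array([[0.0, 1.0], [0.0, 0.0]]), M=np.ones((2, 2)))
        with pytest.raises(ValueError):
            SkeletonGraph(A=np.eye(2), M=np.ones((2, 2)))


class TestSTGCNBlock:
    def test_gamma1_identity_weights_reduces_to_graph_multiply(self):
        """With a 1-frame kernel, unit mask, identity channel mixing, no bias
        and no activation, the block is the pure spatial adjacency multiply
        (checked against an explicit loop)."""
        rng = np.random.default_rng(1)
        g = SkeletonGraph()
        S = base_normalized_adjacency(g)
        C, V, T = 3, 17, 11
        x = rng.normal(size=(2, C, V, T))
        W = np.eye(C)[:, :, None]  # (C, C, 1)
        out = stgcn_block(x, S, W, activation=False).data
        expected = np.zeros_like(x)
        for n in range(2):
            for c in range(C):
                for t in range(T):
                    expected[n, c, :, t] = S @ x[n, c, :, t]
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_zero_input_zero_preactivation(self):
        g = SkeletonGraph()
        S = base_normalized_adjacency(g)
        out = stgcn_block(np.zeros((1, 2, 17, 8)), S,
                          np.ones((4, 2, 3)), activation=False)
        assert np.all(out.data == 0)

    def test_stride_two_halves_time_ceil(self):
        g = SkeletonGraph()
        S = base_normalized_adjacency(g)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 2, 17, 9))
        out = stgcn_block(x, S, rng.normal(size=(4, 2, 3)), stride=2)
        assert out.shape == (1, 4, 17, 5)

    def test_channel_mismatch_raises(self):
        g = SkeletonGraph()
        S = base_normalized_adjacency(g)
        with pytest.raises(ValueError):
            stgcn_block(np.zeros((1, 3, 17, 8)), S, np.zeros((4, 2, 3)))


class TestAutodiffGradients:
    def test_conv_chain_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 3, 5, 7))
        S0 = rng.normal(size=(5, 5))
        W0 = rng.normal(size=(4, 3, 3))
        b0 = rng.normal(size=4)

        def value(W, b, S, stride):
            y = temporal_conv(graph_conv(Tensor(x), Tensor(S)), Tensor(W),
                              Tensor(b), stride=stride)
            return float((y * y).sum().data)

        for stride in (1, 2):
            W, b, S = Tensor(W0, True), Tensor(b0, True), Tensor(S0, True)
            y = temporal_conv(graph_conv(Tensor(x), S), W, b, stride=stride)
            (y * y).sum().backward()
            eps = 1e-6
            for arr, tensor in ((W0, W), (b0, b), (S0, S)):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in range(min(6, arr.size)):
                    mi = it.multi_index
                    plus, minus = arr.copy(), arr.copy()
                    plus[mi] += eps
                    minus[mi] -= eps
                    args_p = [plus if a is arr else a for a in (W0, b0, S0)]
                    args_m = [minus if a is arr else a for a in (W0, b0, S0)]
                    num = (value(*args_p, stride) - value(*args_m, stride)) / (2 * eps)
                    assert abs(num - tensor.grad[mi]) < 1e-4 * max(1, abs(num))
                    it.iternext()

    def test_batch_norm_and_projection_gradients(self):
        """Finite-difference check through the full encoder + loss."""
        rng = np.random.default_rng(4)
        enc = STGCNEncoder(EncoderConfig(channels=(4,), strides=(1,),
                                         temporal_kernel=3, embedding_dim=4,
                                         projection_hidden=5), seed=0)
        batch = rng.normal(size=(4, 3, 17, 6))
        labels = [0, 0, 1, 1]

        def value():
            return float(supcon_loss(enc.forward(batch, train=True),
                                     labels, 0.1).data)

        loss = supcon_loss(enc.forward(batch, train=True), labels, 0.1)
        loss.backward()
        eps = 1e-6
        for name in ("block0.W", "block0.M", "block0.bn_gamma", "proj.W2"):
            p = enc.params[name]
            grad = p.grad.copy()
            it = np.nditer(p.data, flags=["multi_index"])
            for _ in range(min(4, p.data.size)):
                mi = it.multi_index
                orig = p.data[mi]
                p.data[mi] = orig + eps
                vp = value()
                p.data[mi] = orig - eps
                vm = value()
                p.data[mi] = orig
                num = (vp - vm) / (2 * eps)
                assert abs(num - grad[mi]) < 1e-4 * max(1.0, abs(num)), name
                it.iternext()


@pytest.fixture(scope="module")
def encoder():
    return STGCNEncoder(EncoderConfig.small(), seed=0)


class TestEncoder:

    def test_embeddings_unit_norm(self, encoder):
        rng = np.random.default_rng(5)
        z = encoder.forward(rng.normal(size=(6, 3, 17, 54))).data
        np.testing.assert_allclose(np.linalg.norm(z, axis=1), 1.0, atol=1e-6)

    def test_inference_deterministic_and_duplicate_consistent(self, encoder):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(1, 3, 17, 54))
        batch = np.concatenate([x, x])
        z = encoder.forward(batch).data
        np.testing.assert_allclose(z[0], z[1], atol=1e-12)
        z2 = encoder.forward(batch).data
        np.testing.assert_array_equal(z, z2)

    def test_batch_order_equivariance(self, encoder):
        rng = np.random.default_rng(7)
        batch = rng.normal(size=(5, 3, 17, 54))
        perm = np.array([3, 0, 4, 1, 2])
        z = encoder.forward(batch).data
        zp = encoder.forward(batch[perm]).data
        np.testing.assert_allclose(zp, z[perm], atol=1e-12)

    def test_parameter_count_independent_of_identity_count(self, encoder):
        # no classification head: model size cannot depend on labels
        assert encoder.n_parameters() == STGCNEncoder(EncoderConfig.small(),
                                                      seed=1).n_parameters()

    def test_gradient_reaches_edge_importance_mask(self, encoder):
        rng = np.random.default_rng(8)
        batch = rng.normal(size=(4, 3, 17, 54))
        loss = supcon_loss(encoder.forward(batch, train=True), [0, 0, 1, 1], 0.1)
        for p in encoder.parameters():
            p.zero_grad()
        loss.backward()
        for i in range(len(encoder.cfg.channels)):
            g = encoder.params[f"block{i}.M"].grad
            assert g is not None and np.any(g != 0)

    def test_checkpoint_roundtrip(self, tmp_path, encoder):
        rng = np.random.default_rng(9)
        batch = rng.normal(size=(2, 3, 17, 54))
        before = encoder.forward(batch).data
        encoder.save(tmp_path / "ck.npz")
        loaded = STGCNEncoder.load(tmp_path / "ck.npz")
        np.testing.assert_array_equal(loaded.forward(batch).data, before)

    def test_bad_input_shape_rejected(self, encoder):
        with pytest.raises(ValueError):
            encoder.forward(np.zeros((2, 3, 16, 54)))
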