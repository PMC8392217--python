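"""3-D convolution, fusion, focal loss and the assembled network."""

import dataclasses

import numpy as np
import pytest

from cpinet import molgraph
from cpinet.network import (
    CPINetwork,
    NetworkConfig,
    conv3d,
    encode_dataset,
    focal_loss,
    fuse,
)


def naive_conv3d(x, w, b):
    """Six-nested-loop evaluation of the 3-D cross-correlation."""
    C, D, H, W_ = x.shape
    F, _, P, Q, R = w.shape
    out = np.zeros((F, D - P + 1, H - Q + 1, W_ - R + 1))
    for f in range(F):
        for X in range(out.shape[1]):
            for Y in range(out.shape[2]):
                for Z in range(out.shape[3]):
                    acc = 0.0
                    for m in range(C):
                        for i in range(P):
                            for j in range(Q):
                                for k in range(R):
                                    acc += w[f, m, i, j, k] * x[m, X + i, Y + j, Z + k]
                    out[f, X, Y, Z] = acc + b[f]
    return out


class TestConv3d:
    def test_zero_kernel_zero_output(self):
        x = np.random.default_rng(0).normal(size=(2, 5, 5, 5))
        out = conv3d(x, np.zeros((3, 2, 2, 2, 2)), np.zeros(3))
        assert not out.any()

    def test_delta_kernel_identity(self):
        x = np.random.default_rng(1).normal(size=(1, 4, 4, 4))
        out = conv3d(x, np.ones((1, 1, 1, 1, 1)), np.zeros(1))
        np.testing.assert_allclose(out, x)

    def test_matches_naive_oracle(self, rng):
        for _ in range(15):
            C = int(rng.integers(1, 3))
            D = int(rng.integers(2, 6))
            P = int(rng.integers(1, D + 1))
            F = int(rng.integers(1, 3))
            x = rng.normal(size=(C, D, D, D))
            w = rng.normal(size=(F, C, P, P, P))
            b = rng.normal(size=F)
            np.testing.assert_allclose(conv3d(x, w, b), naive_conv3d(x, w, b), atol=1e-10)

    def test_kernel_larger_than_input_rejected(self):
        with pytest.raises(ValueError):
            conv3d(np.zeros((1, 2, 2, 2)), np.zeros((1, 1, 3, 3, 3)), np.zeros(1))


class TestFuse:
    def test_concatenation_order(self):
        np.testing.assert_array_equal(fuse([1.0], [2.0], [3.0]), [1, 2, 3])

    def test_lengths_add(self, rng):
        out = fuse(rng.normal(size=128), rng.normal(size=96), rng.normal(size=128))
        assert out.shape == (352,)

    def test_missing_segment_requires_explicit_ablation(self):
        with pytest.raises(ValueError):
            fuse([1.0], None, [3.0])
        np.testing.assert_array_equal(fuse([1.0], None, [3.0], ablation=True), [1, 3])


class TestFocalLoss:
    def test_perfect_prediction_vanishes(self):
        assert focal_loss(1 - 1e-9, 1, gamma=2, pos_count=1, neg_count=1) < 1e-6

    def test_reference_value(self):
        # y=1, y'=0.5, gamma=2, P=N: -(1/2)(1/2)^2 ln(1/2)
        val = focal_loss(0.5, 1, gamma=2.0, pos_count=7, neg_count=7)
        assert val == pytest.approx(-0.5 * 0.25 * np.log(0.5), abs=1e-9)
        assert val == pytest.approx(0.086643, abs=1e-6)

    def test_gamma_zero_balanced_is_half_cross_entropy(self, rng):
        y_prob = rng.uniform(0.01, 0.99, size=50)
        y_true = rng.integers(0, 2, size=50)
        ours = focal_loss(y_prob, y_true, gamma=0.0, pos_count=3, neg_count=3)
        bce = -(y_true * np.log(y_prob) + (1 - y_true) * np.log(1 - y_prob)).mean()
        assert ours == pytest.approx(0.5 * bce, abs=1e-10)

    def test_nonnegative_and_decreasing_in_confidence(self, rng):
        probs = np.sort(rng.uniform(0.01, 0.99, size=20))
        losses = [focal_loss(p, 1, gamma=2.0, pos_count=2, neg_count=5) for p in probs]
        assert all(l >= 0 for l in losses)
        assert all(a >= b for a, b in zip(losses, losses[1:]))

    def test_class_coefficients_sum_to_one(self):
        P, N = 3987.0, 19879.0
        assert N / (P + N) + P / (P + N) == pytest.approx(1.0)

    def test_out_of_range_probability_clamped(self):
        assert np.isfinite(focal_loss(0.0, 1, gamma=2.0, pos_count=1, neg_count=1))
        assert np.isfinite(focal_loss(1.0, 0, gamma=2.0, pos_count=1, neg_count=1))


@pytest.fixture(scope="module")
def small_model():
    return CPINetwork(NetworkConfig.small(), seed=3)


@pytest.fixture(scope="module")
def small_batch():
    r = np.random.default_rng(5)
    grids = r.uniform(0, 1, size=(3, 8, 30, 30, 30))
    tokens = r.integers(0, 21, size=(3, 1000))
    graphs = [molgraph.build_graph(s) for s in ("CCO", "c1ccncc1", "CC(=O)O")]
    return grids, tokens, graphs


class TestCPINetwork:
    def test_prediction_is_deterministic_and_in_unit_interval(self, small_model, small_batch):
        grids, tokens, graphs = small_batch
        p1 = small_model.predict(grids=grids, tokens=tokens, graphs=graphs)
        p2 = small_model.predict(grids=grids, tokens=tokens, graphs=graphs)
        np.testing.assert_array_equal(p1, p2)
        assert ((p1 > 0) & (p1 < 1)).all()

    def test_zero_weight_head_outputs_half(self, small_batch):
        grids, tokens, graphs = small_batch
        model = CPINetwork(NetworkConfig.small(), seed=0)
        model.params["head.w2"].data[:] = 0.0
        model.params["head.b2"].data[:] = 0.0
        probs = model.predict(grids=grids, tokens=tokens, graphs=graphs)
        np.testing.assert_allclose(probs, 0.5)

    def test_residues_beyond_cutoff_do_not_change_output(self, small_model):
        r = np.random.default_rng(11)
        tokens_a = r.integers(1, 21, size=(1, 1000))
        tokens_b = tokens_a.copy()
        # the 1000-position window is the whole input: tokenization of a
        # longer sequence would have cut residue 1001 before reaching here
        from cpinet.seq_encoder import tokenize

        seq = "".join("ACDEFGHIKLMNPQRSTVWY"[(i * 7) % 20] for i in range(1002))
        t1 = tokenize(seq)
        t2 = tokenize(seq[:1000] + "WW")
        np.testing.assert_array_equal(t1, t2)
        out_a = small_model.forward_seq(tokens_a).data
        out_b = small_model.forward_seq(tokens_b).data
        np.testing.assert_array_equal(out_a, out_b)

    def test_default_config_dimensions(self):
        cfg = NetworkConfig()
        # 30 -> conv3 28 -> pool 14 -> conv3 12 -> pool 6 -> conv3 4 -> pool 2
        assert cfg.site_output_dim() == 128 * 2 ** 3
        # 1000 -> 996/2=498 -> 494/2=247 -> 243/2=121
        assert cfg.seq_output_dim() == 128 * 121
        assert cfg.mol_output_dim() == 64
        assert cfg.fusion_dim() == 1024 + 15488 + 64

    def test_ablation_configs_drop_segments(self, small_batch):
        grids, tokens, graphs = small_batch
        cfg = dataclasses.replace(NetworkConfig.small(), use_seq=False)
        model = CPINetwork(cfg, seed=1)
        probs = model.predict(grids=grids, graphs=graphs)
        assert probs.shape == (3,)
        with pytest.raises(ValueError):
            model.predict(grids=grids)  # molecular pathway input missing

    def test_checkpoint_roundtrip(self, tmp_path, small_model, small_batch):
        grids, tokens, graphs = small_batch
        before = small_model.predict(grids=grids, tokens=tokens, graphs=graphs)
        path = tmp_path / "ckpt"
        small_model.save(path)
        restored = CPINetwork.load(path)
        after = restored.predict(grids=grids, tokens=tokens, graphs=graphs)
        np.testing.assert_allclose(after, before, atol=1e-12)
        assert restored.config == small_model.config

    def test_leaky_relu_and_pooling_invariants(self, rng):
        from cpinet.autograd import Tensor

        x = rng.normal(size=(2, 3, 8))
        t = Tensor(x)
        lr = t.leaky_relu(0.01).data
        assert (lr >= 0.01 * x - 1e-12).all()
        pooled = Tensor(x).max_pool1d(2).data
        windows = x[:, :, :8].reshape(2, 3, 4, 2)
        assert (pooled[..., None] >= windows - 1e-12).all()


class TestTraining:
    def test_one_epoch_is_reproducible(self, tiny_targets, tiny_dataset):
        from cpinet import synthetic
        from cpinet.network import TrainConfig, train_model

        pairs, molecules, _ = tiny_dataset
        grids, tokens = synthetic.featurize_targets(tiny_targets)
        graphs = synthetic.featurize_molecules(molecules)
        data = encode_dataset(pairs, grids, tokens, graphs)
        cfg = TrainConfig(epochs=1, batch_size=8, learning_rate=1e-3, seed=9)
        h1 = train_model(CPINetwork(NetworkConfig.small(), seed=9), data, None, cfg)
        h2 = train_model(CPINetwork(NetworkConfig.small(), seed=9), data, None, cfg)
        assert h1[0]["loss"] == h2[0]["loss"]

    def test_batch_loss_matches_loss_module(self, tiny_targets, tiny_dataset):
        from cpinet import synthetic
        from cpinet.network import _focal_loss_tensor

        pairs, molecules, _ = tiny_dataset
        grids, tokens = synthetic.featurize_targets(tiny_targets)
        graphs = synthetic.featurize_molecules(molecules)
        data = encode_dataset(pairs, grids, tokens, graphs)
        model = CPINetwork(NetworkConfig.small(), seed=2)
        idx = np.arange(8)
        g, t, gr, y = data.batch(idx)
        probs = model.forward(grids=g, tokens=t, graphs=gr)
        tensor_loss = float(_focal_loss_tensor(probs, y, 2.0, 10, 6).data)
        func_loss = focal_loss(probs.data, y, gamma=2.0, pos_count=10, neg_count=6)
        assert tensor_loss == pytest.approx(func_loss, abs=1e-12)
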