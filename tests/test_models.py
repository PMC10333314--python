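"""Architecture shapes, parameter counts and forward-pass properties."""

import numpy as np
import pytest

from voxdep._nn import softmax
from voxdep.models import (
    Network,
    WindowClassifier,
    WindowRegressor,
    ce_forward,
    load_checkpoint,
    mkcnn_flat_size,
    save_checkpoint,
)


def _net(family, n_outputs=2, context=16, L=32, L2=None, seed=0, **kw):
    rng = np.random.default_rng(seed)
    return Network(family, n_outputs, context, L, rng, input_dim_b=L2, **kw)


class TestMKCNNShapes:
    @pytest.mark.parametrize("context,expected", [(16, 1500), (8, 300), (20, 2100)])
    def test_flat_size_arithmetic(self, context, expected):
        # valid convs: per branch k the time axis keeps (C-k+1) - 3 steps
        assert mkcnn_flat_size(context) == expected

    def test_context_seven_collapses_branch(self):
        with pytest.raises(ValueError):
            mkcnn_flat_size(7)
        with pytest.raises(ValueError):
            _net("mkcnn", context=7)

    def test_flat_size_formula_over_range(self):
        for C in range(8, 33):
            assert mkcnn_flat_size(C) == 50 * (((C - 2) - 3) + ((C - 3) - 3)
                                               + ((C - 4) - 3))

    def test_parameter_count_pinned(self):
        # C=16, L=512, detection head:
        # conv1: sum_k (k*512*50 + 50); conv2: 3*(4*50*50 + 50)
        # fc: 1500*100 + 100; head: 100*2 + 2
        net = _net("mkcnn", context=16, L=512)
        conv1 = sum(k * 512 * 50 + 50 for k in (3, 4, 5))
        conv2 = 3 * (4 * 50 * 50 + 50)
        fc = 1500 * 100 + 100
        head = 100 * 2 + 2
        assert net.n_parameters() == conv1 + conv2 + fc + head


class TestLSTM:
    def test_parameter_count_pinned(self):
        # L=256: layer1 (256+128)*512+512, layer2 (128+128)*512+512,
        # fc 128*100+100, head 100*2+2
        net = _net("lstm", L=256)
        expected = (384 * 512 + 512) + (256 * 512 + 512) + 12900 + 202
        assert net.n_parameters() == expected

    def test_last_timestep_shapes(self):
        net = _net("lstm", context=20, L=256)
        out = net.forward(np.random.default_rng(0).standard_normal((3, 20, 256)))
        assert out.shape == (3, 2)
        assert net.stream_a.block.out_dim == 128
        assert net.stream_a.fc.W.value.shape == (128, 100)

    def test_single_step_context_valid(self):
        net = _net("lstm", context=1, L=8)
        out = net.forward(np.zeros((2, 1, 8), dtype=np.float32))
        assert out.shape == (2, 2)

    def test_order_sensitivity(self, rng):
        net = _net("lstm", context=10, L=8)
        x = rng.standard_normal((1, 10, 8)).astype(np.float32)
        flipped = x[:, ::-1, :].copy()
        assert not np.allclose(net.forward(x), net.forward(flipped))


class TestDNN:
    def test_hidden_sizes(self):
        net = _net("dnn", L=192)
        dims = [lay.W.value.shape for lay in net.stream_a.layers
                if hasattr(lay, "W")]
        assert dims == [(192, 128), (128, 64), (64, 128)]

    def test_zero_weights_give_uniform_softmax(self):
        net = _net("dnn", L=16)
        for p in net.params():
            p.value[...] = 0.0
        probs = softmax(net.forward(np.ones((1, 16), dtype=np.float32)))
        assert probs[0] == pytest.approx([0.5, 0.5])

    def test_severity_head_single_output(self):
        net = _net("dnn", n_outputs=1, L=16)
        assert net.forward(np.zeros((4, 16), dtype=np.float32)).shape == (4, 1)


class TestFusion:
    def test_identity_branch_passes_other_through(self, rng):
        net = _net("ce_l", context=8, L=8, L2=6)
        x = rng.standard_normal((2, 8, 8)).astype(np.float32)
        xb = rng.standard_normal((2, 8, 6)).astype(np.float32)
        ha = net.stream_a.forward(x, train=False)
        hb = net.stream_b.forward(xb, train=False)
        fused_ref = net.head.forward(ha * hb, train=False)
        assert np.allclose(net.forward(x, x_b=xb), fused_ref)
        # multiplicative identity: all-ones branch A passes branch B through
        assert np.allclose(np.ones_like(ha) * hb, hb)

    def test_zero_branch_annihilates(self):
        net = _net("ce_l", context=8, L=8, L2=6)
        # silence branch A (zero FC weights and biases -> ReLU output 0)
        net.stream_a.fc.W.value[...] = 0.0
        net.stream_a.fc.b.value[...] = 0.0
        x = np.random.default_rng(0).standard_normal((2, 8, 8)).astype(np.float32)
        xb = np.random.default_rng(1).standard_normal((2, 8, 6)).astype(np.float32)
        out = net.forward(x, x_b=xb)
        head_bias_only = net.head.b.value[None, :].repeat(2, axis=0)
        assert np.allclose(out, head_bias_only, atol=1e-6)

    def test_two_stream_dims(self):
        # ECAPA-sized stream with an OpenSMILE-style stream at context 20
        net = _net("ce_l", context=20, L=256, L2=384)
        assert net.head.W.value.shape == (100, 2)
        out = ce_forward(np.zeros((20, 256)), np.zeros((20, 384)), net)
        assert out.shape == (2,)

    def test_context_mismatch_rejected(self):
        net = _net("ce_l", context=8, L=8, L2=6)
        with pytest.raises(ValueError):
            ce_forward(np.zeros((8, 8)), np.zeros((7, 6)), net)

    def test_scalar_fusion_option(self):
        net = _net("ce_l", context=8, L=8, L2=6, fusion="scalar")
        assert net.head.W.value.shape == (1, 2)


class TestEstimators:
    def _toy_windows(self, rng, n=40, C=8, L=12):
        X = rng.standard_normal((n, C, L)).astype(np.float32)
        y = (X[:, :, 0].mean(axis=1) > 0).astype(int)
        return X, y

    def test_detect_probabilities_sum_to_one(self, rng):
        X, y = self._toy_windows(rng)
        clf = WindowClassifier(family="mkcnn", epochs=2, batch_size=16).fit(X, y)
        p = clf.predict_proba(X)
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-6

    def test_same_seed_identical_training(self, rng):
        X, y = self._toy_windows(rng)
        runs = [WindowClassifier(family="lstm", epochs=3, batch_size=16,
                                 random_state=5).fit(X, y) for _ in range(2)]
        assert runs[0].loss_curve_ == runs[1].loss_curve_

    def test_single_class_training_rejected(self, rng):
        X, _ = self._toy_windows(rng)
        with pytest.raises(ValueError):
            WindowClassifier(family="dnn", pool=True, epochs=1).fit(
                X, np.zeros(len(X), dtype=int))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            WindowRegressor(family="dnn").fit(np.empty((0, 8)), np.empty(0))

    def test_regressor_maps_back_to_scale(self, rng):
        X = rng.standard_normal((60, 10)).astype(np.float32)
        y = 10 + 3 * X[:, 0]
        reg = WindowRegressor(family="dnn", epochs=30, batch_size=16,
                              random_state=0).fit(X, y)
        pred = reg.predict(X)
        assert abs(pred.mean() - y.mean()) < 2.0

    def test_sklearn_param_interface(self):
        clf = WindowClassifier(family="lstm", epochs=7)
        assert clf.get_params()["epochs"] == 7
        clf.set_params(epochs=9)
        assert clf.epochs == 9

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        X, y = self._toy_windows(rng)
        clf = WindowClassifier(family="mkcnn", epochs=2, batch_size=16).fit(X, y)
        path = tmp_path / "model.npz"
        save_checkpoint(clf, path)
        again = load_checkpoint(path)
        assert np.allclose(clf.predict_proba(X), again.predict_proba(X))
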