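"""Residual CNN, BCE loss, cross-validation plan and training behavior."""

import math

import numpy as np
import pandas as pd
import pytest

import morphnet as mn
from morphnet.nn import Adam, BatchNorm2d, Conv2d, Dense, ModelConfig, ResNetClassifier, sigmoid
from morphnet.nn.resnet import Bottleneck


def numeric_grad(f, x, eps=1e-4):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


class TestLayersGradients:
    """Backward passes agree with central finite differences."""

    def test_conv2d_input_and_weight_grads(self):
        rng = np.random.default_rng(0)
        conv = Conv2d(2, 3, 3, stride=2, bias=True, rng=rng)
        x = rng.normal(size=(2, 2, 7, 7)).astype(np.float64)
        w = rng.normal(size=conv.forward(x).shape)  # loss weights

        def loss():
            return float(np.sum(conv.forward(x) * w))

        y = conv.forward(x)
        gx = conv.backward(w.astype(np.float64))
        assert np.allclose(gx, numeric_grad(loss, x), atol=1e-5)
        conv.weight.grad[...] = 0
        conv.forward(x)
        conv.backward(w)
        assert np.allclose(
            conv.weight.grad, numeric_grad(loss, conv.weight.data), atol=1e-3
        )

    @pytest.mark.parametrize("training", [True, False])
    def test_batchnorm_grads(self, training):
        rng = np.random.default_rng(1)
        bn = BatchNorm2d(3)
        bn.running_mean[:] = rng.normal(size=3)
        bn.running_var[:] = rng.uniform(0.5, 2.0, size=3)
        bn.gamma.data[:] = rng.normal(1.0, 0.2, size=3)
        x = rng.normal(size=(4, 3, 3, 3)).astype(np.float64)
        w = rng.normal(size=(4, 3, 3, 3))
        rm, rv = bn.running_mean.copy(), bn.running_var.copy()

        def loss():
            bn.running_mean[:], bn.running_var[:] = rm, rv
            return float(np.sum(bn.forward(x, training=training) * w))

        loss()
        gx = bn.backward(w)
        assert np.allclose(gx, numeric_grad(loss, x), atol=1e-4)

    def test_bottleneck_input_grad(self):
        rng = np.random.default_rng(2)
        blk = Bottleneck(2, 4, stride=2, rng=rng, batch_norm=True)
        x = rng.normal(size=(3, 2, 6, 6)).astype(np.float64)
        w = rng.normal(size=(3, 4, 3, 3))

        def loss():
            return float(np.sum(blk.forward(x, training=False) * w))

        blk.forward(x, training=False)
        gx = blk.backward(w)
        assert np.allclose(gx, numeric_grad(loss, x), atol=1e-4)


class TestModel:
    def test_stage_spatial_sizes(self):
        cfg = ModelConfig()
        assert cfg.stage_sizes() == [108, 54, 27, 14, 7, 4]
        m = ResNetClassifier(cfg)
        x = np.zeros((1, 1, 108, 108), dtype=np.float32)
        m.forward_logits(x)
        sizes = [a.shape[-1] for a in m.stage_activations]
        assert sizes == [54, 27, 14, 7, 4]
        widths = [a.shape[1] for a in m.stage_activations]
        assert widths == [16, 32, 64, 128, 256]

    def test_output_strictly_in_unit_interval(self):
        m = ResNetClassifier(ModelConfig(input_size=32, channels_per_stage=(4, 4, 8, 8, 8)))
        x = np.random.default_rng(0).normal(size=(5, 1, 32, 32))
        p = m.predict_proba(x)
        assert np.all((p > 0) & (p < 1))

    def test_seeded_initialization_is_deterministic(self):
        a = ResNetClassifier(ModelConfig(seed=3))
        b = ResNetClassifier(ModelConfig(seed=3))
        assert all(
            np.array_equal(pa.data, pb.data)
            for pa, pb in zip(a.parameters(), b.parameters())
        )
        c = ResNetClassifier(ModelConfig(seed=4))
        assert any(
            not np.array_equal(pa.data, pc.data)
            for pa, pc in zip(a.parameters(), c.parameters())
        )

    def test_incompatible_input_size_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            ModelConfig(input_size=16)

    def test_dropout_disabled(self):
        with pytest.raises(ValueError, match="dropout"):
            ModelConfig(use_dropout=True)


class TestBCELoss:
    def test_closed_forms(self):
        assert mn.bce_loss(1, 0.5) == pytest.approx(math.log(2), abs=1e-12)
        assert mn.bce_loss(0, 0.5) == mn.bce_loss(1, 0.5)
        assert mn.bce_loss(1, 1 - 1e-7) == pytest.approx(0.0, abs=1e-6)
        assert mn.bce_loss(1, 1.0) < math.inf  # clamp keeps the loss finite

    def test_gradient_matches_finite_differences(self):
        for y in (0.0, 1.0):
            for p in (0.2, 0.5, 0.9):
                analytic = (p - y) / (p * (1 - p))
                eps = 1e-6
                fd = (mn.bce_loss(y, p + eps) - mn.bce_loss(y, p - eps)) / (2 * eps)
                assert fd == pytest.approx(analytic, abs=1e-5)

    def test_nonnegative(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1 - 1e-6, 100)
        y = rng.integers(0, 2, 100)
        assert np.all(mn.bce_loss(y, p) >= 0)


def _pheno(n):
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "dx": ["ASD" if i % 2 else "TC" for i in range(n)],
            "site": "X",
            "age": 12.0,
            "sex": "M",
        }
    )


class TestCVPlan:
    def test_partition_invariants(self):
        plan = mn.make_cv_plan(_pheno(100), n_folds=10, n_repeats=3, seed=0)
        for r in range(3):
            counts = np.bincount(plan.outer[r], minlength=11)[1:]
            assert counts.tolist() == [10] * 10  # equal outer groups
            non_test = plan.outer[r] != 10
            assert np.all(plan.inner[r][~non_test] == -1)
            inner_counts = np.bincount(plan.inner[r][non_test], minlength=10)
            assert np.all(np.abs(inner_counts - 9) <= 1)
            assert inner_counts.sum() == 90

    def test_uneven_sizes_differ_by_at_most_one(self):
        plan = mn.make_cv_plan(_pheno(47), n_folds=10, n_repeats=2, seed=1)
        counts = np.bincount(plan.outer[0], minlength=11)[1:]
        assert counts.max() - counts.min() <= 1 and counts.sum() == 47

    def test_split_is_disjoint_and_covers(self):
        plan = mn.make_cv_plan(_pheno(53), n_folds=5, n_repeats=4, seed=2)
        for r in range(4):
            tr, va, te = plan.split(r)
            all_idx = np.concatenate([tr, va, te])
            assert len(set(all_idx)) == 53
            assert not (set(te) & set(tr)) and not (set(te) & set(va))
            assert not (set(tr) & set(va))

    def test_deterministic_and_hashable(self):
        a = mn.make_cv_plan(_pheno(40), 5, 3, seed=9)
        b = mn.make_cv_plan(_pheno(40), 5, 3, seed=9)
        assert a.partition_hash() == b.partition_hash()
        c = mn.make_cv_plan(_pheno(40), 5, 3, seed=10)
        assert a.partition_hash() != c.partition_hash()

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            mn.make_cv_plan(_pheno(5), n_folds=10, n_repeats=1, seed=0)


def _toy_networks(n, size, separation, seed):
    """Symmetric matrices with a class-dependent block; labels alternate."""
    rng = np.random.default_rng(seed)
    nets, labels = [], []
    for i in range(n):
        y = i % 2
        m = rng.normal(0.5, 0.1, (size, size))
        if y:
            m[:6, :6] += separation
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 1.0)
        nets.append(mn.MorphNetwork(region_labels=list(range(1, size + 1)),
                                    matrix=m, subject_id=f"s{i}"))
        labels.append(y)
    return nets, labels


SMALL_MODEL = dict(input_size=32, channels_per_stage=(4, 8, 8, 16, 16))


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        nets, _ = _toy_networks(40, 32, separation=1.0, seed=0)
        pheno = _pheno(40)
        plan = mn.make_cv_plan(pheno, n_folds=4, n_repeats=1, seed=0)
        hyper = mn.Hyperparameters(learning_rate=1e-3, max_epochs=6, early_stop_patience=6)
        models, _ = mn.train(nets, pheno, plan, mn.ModelConfig(**SMALL_MODEL, seed=0), hyper)
        losses = models[0].training_log["train_loss"].to_numpy()
        assert np.all(np.diff(losses[:5]) < 0)

    def test_memorizes_toy_set(self):
        """Enough epochs on 16 subjects drives training accuracy to 1."""
        nets, labels = _toy_networks(16, 32, separation=0.3, seed=1)
        x = mn.networks_to_array(nets)
        y = np.array(labels, dtype=np.float64)
        model = ResNetClassifier(ModelConfig(**SMALL_MODEL, seed=1))
        hyper = mn.Hyperparameters(learning_rate=3e-3, batch_size=16,
                                   max_epochs=60, early_stop_patience=60)
        mn.train_single(model, x, y, x[:0], y[:0], hyper, np.random.default_rng(1))
        acc = np.mean((model.predict_proba(x) >= 0.5) == y)
        assert acc == 1.0

    def test_same_seed_reproduces_fold_results(self):
        nets, _ = _toy_networks(20, 32, separation=0.5, seed=2)
        pheno = _pheno(20)
        plan = mn.make_cv_plan(pheno, n_folds=4, n_repeats=1, seed=3)
        hyper = mn.Hyperparameters(learning_rate=1e-3, max_epochs=3, early_stop_patience=3)
        cfg = mn.ModelConfig(**SMALL_MODEL, seed=5)
        _, fr_a = mn.train(nets, pheno, plan, cfg, hyper)
        _, fr_b = mn.train(nets, pheno, plan, cfg, hyper)
        pd.testing.assert_frame_equal(fr_a, fr_b)

    def test_test_subjects_never_in_training(self):
        """ID audit: the test group is disjoint from train/val in every repeat."""
        pheno = _pheno(30)
        plan = mn.make_cv_plan(pheno, n_folds=5, n_repeats=6, seed=4)
        ids = np.array(plan.subject_ids)
        for r in range(6):
            tr, va, te = plan.split(r)
            assert not (set(ids[te]) & set(ids[tr]) | set(ids[te]) & set(ids[va]))


def test_adam_converges_on_quadratic():
    from morphnet.nn.layers import Parameter

    p = Parameter(np.array([5.0, -3.0]))
    opt = Adam([p], lr=0.1)
    for _ in range(500):
        opt.zero_grad()
        p.grad[...] = 2 * p.data
        opt.step()
    assert np.all(np.abs(p.data) < 1e-3)


def test_sigmoid_stable_at_extremes():
    z = np.array([-500.0, 0.0, 500.0])
    s = sigmoid(z)
    assert np.all(np.isfinite(s)) and s[0] == 0.0 or s[0] < 1e-100
    assert s[1] == 0.5 and s[2] == 1.0
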