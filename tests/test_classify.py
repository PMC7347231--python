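"""Network construction, augmentation, balancing, training mechanics,
cross-validation schemes and the ridge/SVM baselines."""

import numpy as np
import pytest

from usvsex import classify as cl
from usvsex import nn


class TestBuildNetwork:
    def test_first_layer_parameter_count(self):
        net = cl.build_network(cl.ConvNetSpec(), seed=0)
        conv1 = next(l for l in net.layers if isinstance(l, nn.Conv2D))
        n = conv1.W.v.size + conv1.b.v.size
        assert n == 10 * 10 * 1 * 256 + 256 == 25_856

    def test_conv_spec_structure(self):
        net = cl.build_network(cl.ConvNetSpec(units=8, fc_units=12), seed=0)
        convs = [l for l in net.layers if isinstance(l, nn.Conv2D)]
        assert [c.k for c in convs] == [10, 5, 3, 3, 3, 3]
        assert [c.stride for c in convs] == [2, 2, 1, 1, 1, 1]
        denses = [l for l in net.layers if isinstance(l, nn.Dense)]
        assert len(denses) == 4  # 3 FC + output
        bns = [l for l in net.layers if isinstance(l, nn.BatchNorm)]
        assert len(bns) == 9  # every conv and FC layer is normalized

    def test_conv_forward_output_shape(self):
        net = cl.build_network(cl.ConvNetSpec(units=4, fc_units=6), seed=0)
        x = np.zeros((2, 100, 100, 1), dtype=np.float32)
        out = net.forward(x)
        assert out.shape == (2, 1)

    def test_dense_forward_in_unit_interval(self):
        net = cl.build_network(cl.DenseNetSpec(), seed=0)
        p = net.predict_proba(np.random.default_rng(0).normal(size=(5, 9)))
        assert p.shape == (5, 1)
        assert np.all((p > 0) & (p < 1))

    def test_dense_spec_layer_sizes(self):
        net = cl.build_network(cl.DenseNetSpec(), seed=0)
        denses = [l for l in net.layers if isinstance(l, nn.Dense)]
        assert [d.W.v.shape for d in denses] == [
            (9, 70), (70, 70), (70, 70), (70, 70), (70, 1)]

    def test_peaks_head_dimension(self):
        head, n_out = cl.head_for_task("peaks")
        assert (head, n_out) == ("softmax", 4)
        net = cl.build_network(
            cl.ConvNetSpec(units=4, fc_units=6, head=head, n_out=n_out),
            seed=0)
        p = net.predict_proba(np.zeros((3, 100, 100, 1)))
        assert p.shape == (3, 4)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_semiconv_has_three_streams(self):
        net = cl.build_network(cl.SemiConvNetSpec(units=4, fc_units=8),
                               seed=0)
        assert len(net.stacks) == 3
        out = net.forward(np.zeros((2, 457), dtype=np.float32))
        assert out.shape == (2, 1)

    def test_sigmoid_head_requires_single_output(self):
        with pytest.raises(ValueError):
            nn.Network([], "sigmoid", 4)


class TestProtocols:
    def test_spectrogram_protocol_stages(self):
        p = cl.protocol_spectrogram()
        assert [s.epochs for s in p.stages] == [40, 25, 25]
        assert [s.dropout for s in p.stages] == [0.0, 0.5, 0.7]
        assert [s.lr for s in p.stages] == [1e-3, 1e-4, 1e-5]
        assert p.batch_size == 64

    def test_extended_protocol_four_stages(self):
        p = cl.protocol_extended()
        assert len(p.stages) == 4
        assert p.stages[-1].epochs == 100
        assert p.stages[-1].lr == pytest.approx(2e-6)

    def test_quadratic_decay_endpoints(self):
        p = cl.protocol_features()
        stage = p.stages[1]
        assert stage.lr_at(0.0) == pytest.approx(1e-3)
        assert stage.lr_at(1.0) == pytest.approx(1e-5)
        assert stage.lr_at(0.5) < stage.lr_at(0.25)


class TestAugment:
    def test_identity_config(self):
        cfg = cl.AugmentConfig(clip_frac=0.0, amp_range=(1.0, 1.0),
                               noise_var_range=(0.0, 0.0))
        img = np.random.default_rng(0).uniform(size=(100, 100)) * 0.5
        out = cl.augment_image(img, cfg, np.random.default_rng(1))
        assert np.allclose(out, img)

    def test_noise_std_at_max_variance(self):
        cfg = cl.AugmentConfig(clip_frac=0.0, amp_range=(1.0, 1.0),
                               noise_var_range=(0.01, 0.01))
        img = np.full((100, 100), 0.5)
        out = cl.augment_image(img, cfg, np.random.default_rng(0))
        assert np.std(out - img) == pytest.approx(0.1, rel=0.05)

    def test_deterministic_under_seed(self):
        cfg = cl.AugmentConfig()
        img = np.random.default_rng(2).uniform(size=(100, 100))
        a = cl.augment_image(img, cfg, np.random.default_rng(7))
        b = cl.augment_image(img, cfg, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_original_untouched(self):
        cfg = cl.AugmentConfig()
        img = np.random.default_rng(3).uniform(size=(100, 100))
        before = img.copy()
        cl.augment_image(img, cfg, np.random.default_rng(0))
        assert np.array_equal(img, before)

    def test_freq_marginal_stream_no_clip(self):
        cfg = cl.AugmentConfig(noise_var_range=(0.0, 0.0),
                               freq_amp_range=(1.2, 1.2))
        vec = np.random.default_rng(1).uniform(size=233)
        out = cl.augment_vector(vec, "freq_marginal", cfg,
                                np.random.default_rng(0))
        assert np.allclose(out, 1.2 * vec)


class TestClassWeights:
    def test_balanced_counts(self):
        w = cl.class_weights(np.array([0] * 100 + [1] * 100))
        assert np.allclose(w, [1.0, 1.0])

    def test_imbalanced_ratio(self):
        w = cl.class_weights(np.array([0] * 132 + [1] * 100))
        assert w[1] / w[0] == pytest.approx(1.32)

    def test_extreme_imbalance(self):
        w = cl.class_weights(np.array([0] + [1] * 999))
        assert w[0] / w[1] == pytest.approx(999.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cl.class_weights(np.zeros(10, dtype=int))


class TestTrain:
    def test_separable_toy_learned(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(-2, 0.3, size=(100, 5)),
                            rng.normal(2, 0.3, size=(100, 5))])
        y = np.array([0] * 100 + [1] * 100)
        net = cl.build_network(cl.DenseNetSpec(n_in=5), seed=0)
        proto = cl.TrainProtocol((cl.Stage(30, 1e-3, 0.0),))
        trace = cl.train(net, X, y, proto, seed=0)
        assert np.mean(net.predict(X) == y) >= 0.99
        # moving-average loss decreases
        k = len(trace) // 4
        assert np.mean(trace[-k:]) < np.mean(trace[:k])

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 9)).astype(np.float32)
        y = (rng.uniform(size=60) > 0.5).astype(int)
        proto = cl.TrainProtocol((cl.Stage(3, 1e-3, 0.5),))
        nets = []
        for _ in range(2):
            net = cl.build_network(cl.DenseNetSpec(), seed=5)
            cl.train(net, X, y, proto, seed=11)
            nets.append(net.predict_proba(X))
        assert np.array_equal(nets[0], nets[1])


class TestSplits:
    def test_leave_one_subject(self):
        individuals = np.repeat(np.arange(17), 5)
        folds = cl.split_leave_one_subject(individuals)
        assert len(folds) == 17
        for tr, te in folds:
            assert len(te) == 5
            assert len(np.intersect1d(individuals[tr],
                                      individuals[te])) == 0

    def test_random_folds_partition(self):
        folds = cl.split_random_folds(100, 10, seed=0)
        assert len(folds) == 10
        all_test = np.concatenate([te for _, te in folds])
        assert len(all_test) == 100
        assert len(np.unique(all_test)) == 100
        for _, te in folds:
            assert len(te) == 10

    def test_random_folds_deterministic(self):
        f1 = cl.split_random_folds(57, 10, seed=3)
        f2 = cl.split_random_folds(57, 10, seed=3)
        for (a, b), (c, d) in zip(f1, f2):
            assert np.array_equal(a, c) and np.array_equal(b, d)

    def test_shuffle_preserves_multiset(self):
        y = np.array([0] * 40 + [1] * 60)
        ys = cl.shuffle_labels(y, seed=0)
        assert sorted(ys) == sorted(y)
        assert not np.array_equal(ys, y)
        assert np.array_equal(cl.shuffle_labels(y, 5),
                              cl.shuffle_labels(y, 5))


class TestRidge:
    def test_exact_interpolation(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([0, 1])
        r = cl.RidgeClassifier(lam=0.0, balance=False).fit(X, y)
        assert np.array_equal(r.predict(X), y)
        assert np.allclose(r.decision_function(X), y, atol=1e-8)

    def test_huge_lambda_predicts_constant(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3))
        y = (rng.uniform(size=50) > 0.5).astype(int)
        r = cl.RidgeClassifier(lam=1e6, balance=False).fit(X, y)
        assert np.linalg.norm(r.w_) < 1e-3
        assert len(np.unique(r.predict(X))) == 1

    def test_matches_brute_force_normal_equations(self):
        X = np.array([[1.0, 2.0], [0.5, -1.0], [2.0, 0.5]])
        y = np.array([1.0, 0.0, 1.0])
        lam = 1.0
        r = cl.RidgeClassifier(lam=lam, balance=False).fit(X, y)
        w_ref = np.linalg.solve(X.T @ X + lam * np.eye(2), X.T @ y)
        assert np.allclose(r.w_, w_ref, atol=1e-10)

    def test_dual_equals_primal(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 30))  # d > n -> dual path
        y = (rng.uniform(size=10) > 0.5).astype(float)
        r = cl.RidgeClassifier(lam=2.0, balance=False).fit(X, y)
        w_ref = np.linalg.solve(X.T @ X + 2.0 * np.eye(30), X.T @ y)
        assert np.allclose(r.w_, w_ref, atol=1e-8)

    def test_singular_unregularized_rejected(self):
        X = np.zeros((2, 5))
        with pytest.raises(np.linalg.LinAlgError):
            cl.RidgeClassifier(lam=0.0, balance=False).fit(
                X, np.array([0.0, 1.0]))


class TestSvm:
    def test_linear_separable(self):
        X = np.array([[0.0, 0], [0, 1], [3, 0], [3, 1]] * 3)
        y = np.array([0, 0, 1, 1] * 3)
        clf = cl.svm_classify(X, y, kernel="linear", balance=False)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_xor_needs_quadratic(self):
        X = np.array([[1.0, 1], [-1, -1], [1, -1], [-1, 1]] * 5)
        y = np.array([0, 0, 1, 1] * 5)
        quad = cl.svm_classify(X, y, kernel="quadratic", balance=False,
                               C=10.0)
        assert np.mean(quad.predict(X) == y) == 1.0
        lin = cl.svm_classify(X, y, kernel="linear", balance=False)
        assert np.mean(lin.predict(X) == y) <= 0.75

    def test_prediction_invariant_to_duplicate_point(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        base = cl.svm_classify(X, y, kernel="linear", balance=False)
        X2 = np.vstack([X, X[:1]])
        y2 = np.concatenate([y, y[:1]])
        dup = cl.svm_classify(X2, y2, kernel="linear", balance=False)
        grid = rng.normal(size=(50, 4))
        assert np.array_equal(base.predict(grid), dup.predict(grid))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cl.svm_classify(np.zeros((5, 2)), np.zeros(5))


class TestEvaluate:
    class _Const:
        def __init__(self, value):
            self.value = value

        def predict(self, X):
            return np.full(len(X), self.value)

    def test_perfect_predictor(self):
        y = np.array([1] * 10)
        res = cl.evaluate(self._Const(1), np.zeros((10, 2)), y)
        assert res.percent_correct == 100.0

    def test_known_confusion_counts(self):
        assert cl.percent_correct_from_counts(45, 60) == pytest.approx(75.0)

    def test_random_17_class_near_chance(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 17, size=20_000)

        class _Rand:
            def predict(self, X):
                return np.random.default_rng(1).integers(0, 17,
                                                         size=len(X))

        res = cl.evaluate(_Rand(), np.zeros((len(y), 1)), y)
        assert res.percent_correct == pytest.approx(100 / 17, abs=0.5)

    def test_per_class_counts_sum(self):
        y = np.array([0, 0, 1, 1, 1])
        res = cl.evaluate(self._Const(0), np.zeros((5, 1)), y)
        assert sum(v["n"] for v in res.per_class.values()) == 5

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            cl.evaluate(self._Const(0), np.zeros((0, 1)), np.array([]))


class TestGradients:
    def test_numeric_gradient_small_convnet(self):
        """Analytic backprop matches central differences on a small net
        containing every layer type (float64 for the comparison)."""
        old = nn.DTYPE
        nn.DTYPE = np.float64
        try:
            rng = np.random.default_rng(5)
            layers = [nn.Conv2D(1, 3, 4, 2, rng), nn.BatchNorm(3),
                      nn.ReLU(),
                      nn.Conv2D(3, 4, 3, 1, rng), nn.BatchNorm(4),
                      nn.ReLU(), nn.Flatten(),
                      nn.Dense(4 * 5 * 5, 6, rng), nn.BatchNorm(6),
                      nn.ReLU(), nn.Dropout(0.3), nn.Dense(6, 1, rng)]
            net = nn.Network(layers, "sigmoid", 1)
            x = np.random.default_rng(0).standard_normal((5, 9, 9, 1))
            y = np.array([0, 1, 1, 0, 1])
            logits = net.forward(x, train=True,
                                 rng=np.random.default_rng(1))
            _, dz = net.loss_and_grad(logits, y)
            net.backward(dz)
            for p in net.params():
                flat = p.v.ravel()
                grad = p.g.ravel()
                for i in np.random.default_rng(2).integers(
                        0, flat.size, size=3):
                    eps, old_v = 1e-6, flat[i]
                    flat[i] = old_v + eps
                    l1, _ = net.loss_and_grad(net.forward(
                        x, train=True, rng=np.random.default_rng(1)), y)
                    flat[i] = old_v - eps
                    l2, _ = net.loss_and_grad(net.forward(
                        x, train=True, rng=np.random.default_rng(1)), y)
                    flat[i] = old_v
                    num = (l1 - l2) / (2 * eps)
                    if abs(num) + abs(grad[i]) > 1e-7:
                        assert abs(num - grad[i]) <= 1e-5 * (
                            abs(num) + abs(grad[i]) + 1.0)
        finally:
            nn.DTYPE = old
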