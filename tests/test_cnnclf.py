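import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from connstack.cnnclf import (
    BackboneError,
    TinyConvBackbone,
    TrainSchedule,
    TrainingError,
    ConfusionCounts,
    accuracy,
    build_head,
    confusion_counts,
    cross_validate,
    extract_features,
    feature_geometry,
    get_backbone_spec,
    min_max_scale,
    prepare_input,
    train_transfer,
)
from connstack.enhance import Stack3D


def make_stack(rng, n=16, sid="s"):
    return Stack3D(sid, "toy", "correlation", "enhanced", rng.standard_normal((n, n, 3)))


class TestFeatureGeometry:
    @pytest.mark.parametrize(
        "name,side,expected",
        [
            ("VGG16", 116, 3),
            ("InceptionV3", 116, 2),
            ("ResNet50", 116, 4),
            ("VGG19", 161, 5),
            ("ResNet152V2", 161, 6),
            ("InceptionV3", 200, 4),
            ("VGG16", 200, 6),
            ("ResNet50", 200, 7),
        ],
    )
    def test_printed_sides(self, name, side, expected):
        assert feature_geometry(name, side)[0] == expected

    @pytest.mark.parametrize("side", range(75, 225, 10))
    def test_vgg_is_floor_div32(self, side):
        assert feature_geometry("VGG16", side)[0] == side // 32

    @pytest.mark.parametrize("side", range(75, 225, 10))
    def test_resnet_is_ceil_div32(self, side):
        assert feature_geometry("ResNet50", side)[0] == -(-side // 32)

    def test_too_small_input_reports_minimum(self):
        with pytest.raises(BackboneError, match="75"):
            feature_geometry("InceptionV3", 60)

    def test_unknown_backbone(self):
        with pytest.raises(BackboneError, match="registered"):
            feature_geometry("AlexNet", 116)

    def test_tinyconv_never_claims_imagenet(self):
        with pytest.raises(BackboneError, match="ImageNet"):
            get_backbone_spec("TinyConv", weights="imagenet")


class TestPrepareInput:
    def test_scale_endpoints(self, rng):
        scaled = min_max_scale(make_stack(rng).channels)
        assert scaled.min() == pytest.approx(0.0)
        assert scaled.max() == pytest.approx(255.0)

    def test_monotone(self, rng):
        x = make_stack(rng).channels
        scaled = min_max_scale(x)
        i = np.unravel_index(np.argsort(x, axis=None), x.shape)
        assert np.all(np.diff(scaled[i]) >= 0)

    def test_scale_invariance(self, rng):
        st = make_stack(rng)
        st10 = Stack3D(st.subject_id, st.atlas, st.method, st.strategy, st.channels * 10)
        np.testing.assert_allclose(prepare_input(st), prepare_input(st10), atol=1e-12)

    def test_constant_stack_rejected(self):
        st = Stack3D("s", "a", "correlation", "plain", np.ones((5, 5, 3)))
        with pytest.raises(TrainingError, match="constant"):
            prepare_input(st)


class TestExtractFeatures:
    def test_tinyconv_shape(self, rng):
        feats = extract_features(rng.standard_normal((30, 30, 3)), "TinyConv")
        assert feats.shape == (3, 3, 32)

    def test_deterministic_in_seed(self, rng):
        x = rng.standard_normal((16, 16, 3))
        np.testing.assert_array_equal(
            extract_features(x, "TinyConv", seed=5),
            extract_features(x, "TinyConv", seed=5),
        )

    def test_named_backbone_unavailable_offline(self, rng):
        with pytest.raises(BackboneError, match="TinyConv"):
            extract_features(rng.standard_normal((116, 116, 3)), "VGG16")

    def test_too_small_input(self, rng):
        with pytest.raises(BackboneError, match=">="):
            extract_features(rng.standard_normal((4, 4, 3)), "TinyConv")


class TestHead:
    def test_param_count(self):
        head = build_head((3, 3, 32), dropout_rate=0.5)
        assert head.n_params == 3 * 3 * 32 + 1

    def test_output_is_probability(self, rng):
        head = build_head((2, 2, 4))
        p = head.predict_proba(rng.standard_normal((5, 2, 2, 4)))
        assert np.all((p > 0) & (p < 1))

    def test_zero_dropout_is_plain_linear(self, rng):
        head = build_head((2, 2, 2), dropout_rate=0.0)
        x = rng.standard_normal((4, 2, 2, 2))
        p1, _ = head.forward(x, rng=np.random.default_rng(0), train=True)
        p2 = head.predict_proba(x)
        np.testing.assert_allclose(p1, p2)

    def test_invalid_rate(self):
        with pytest.raises(TrainingError, match="dropout"):
            build_head((2, 2, 2), dropout_rate=1.0)


class TestAccuracy:
    def test_perfect(self):
        assert accuracy(ConfusionCounts(TP=5, TN=5)) == 1.0

    def test_eq1_substitution(self):
        assert accuracy(ConfusionCounts(TP=3, FP=1, TN=4, FN=2)) == pytest.approx(0.7)

    def test_always_wrong(self):
        assert accuracy(ConfusionCounts(FP=2, FN=3)) == 0.0

    def test_all_zero_undefined(self):
        with pytest.raises(TrainingError, match="undefined"):
            accuracy(ConfusionCounts())

    def test_counts_from_predictions(self):
        c = confusion_counts([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (c.TP, c.FN, c.TN, c.FP) == (2, 1, 1, 1)
        assert c.total == 5


def separable_features(rng, n=40, d=10):
    y = np.repeat([0, 1], n // 2)
    x = rng.standard_normal((n, d)) * 0.1
    x[:, 0] += y * 4.0 - 2.0
    return x.reshape(n, 1, 1, d), y.astype(float)


class TestTrainTransfer:
    def test_frozen_backbone_bit_identical(self, rng):
        x = rng.standard_normal((24, 16, 16, 3))
        y = np.repeat([0.0, 1.0], 12)
        backbone = TinyConvBackbone(seed=0)
        before = backbone.copy_params()
        sched = TrainSchedule(epochs_head=3)
        train_transfer(x[:20], y[:20], x[20:], y[20:], backbone=backbone,
                       schedule=sched, fine_tune=False, seed=0)
        for b, a in zip(before, backbone.params):
            np.testing.assert_array_equal(b, a)

    def test_finetune_changes_backbone(self, rng):
        x = rng.standard_normal((24, 16, 16, 3))
        y = np.repeat([0.0, 1.0], 12)
        backbone = TinyConvBackbone(seed=0)
        before = backbone.copy_params()
        sched = TrainSchedule(epochs_head=2, epochs_finetune=2)
        train_transfer(x[:20], y[:20], x[20:], y[20:], backbone=backbone,
                       schedule=sched, fine_tune=True, seed=0)
        assert any(not np.array_equal(b, a) for b, a in zip(before, backbone.params))

    def test_phase2_rate_below_phase1(self):
        sched = TrainSchedule()
        assert sched.lr_finetune < sched.lr_head
        with pytest.raises(TrainingError, match="below"):
            TrainSchedule(lr_head=1e-5, lr_finetune=1e-3)

    def test_separable_head_reaches_perfect_train_accuracy(self, rng):
        x, y = separable_features(rng)
        # independent convex oracle: sklearn logistic regression separates it
        flat = x.reshape(len(y), -1)
        oracle = LogisticRegression(C=1e6).fit(flat, y)
        assert oracle.score(flat, y) == 1.0

        class _Identity:
            params = []
            def forward(self, t, want_cache=False):
                return (t, []) if want_cache else t
            def feature_shape(self, side):
                return x.shape[1:]

        sched = TrainSchedule(epochs_head=300, dropout_rate=0.0, patience=50)
        model = train_transfer(x, y, x, y, backbone=_Identity(),
                               schedule=sched, fine_tune=False, seed=0)
        assert np.mean(model.predict(x) == y) == 1.0

    def test_single_class_rejected(self, rng):
        x = rng.standard_normal((8, 16, 16, 3))
        with pytest.raises(TrainingError, match="single class"):
            train_transfer(x, np.ones(8), x[:2], np.ones(2))

    def test_empty_train_rejected(self, rng):
        x = rng.standard_normal((0, 16, 16, 3))
        with pytest.raises(TrainingError, match="empty"):
            train_transfer(x, np.array([]), x, np.array([]))


class TestCrossValidate:
    def _cohort(self, rng, n_per_class=12, side=12):
        stacks, labels = [], []
        for i in range(2 * n_per_class):
            label = "case" if i % 2 else "control"
            st = make_stack(rng, n=side, sid=f"s{i}")
            stacks.append(st)
            labels.append(label)
        return stacks, labels

    def test_oracle_stub_gets_perfect_accuracy(self, rng):
        stacks, labels = self._cohort(rng)
        y = np.array([1 if l == "case" else 0 for l in labels])
        calls = {"n": 0}

        def oracle(train_x, train_y, test_x):
            # cheat: recover identity of test rows by matching against all tensors
            calls["n"] += 1
            from connstack.cnnclf.training import prepare_input as pi
            all_x = np.stack([pi(s) for s in stacks])
            preds = []
            for t in test_x:
                idx = int(np.argmin(np.sum((all_x - t) ** 2, axis=(1, 2, 3))))
                preds.append(y[idx])
            return preds

        report = cross_validate(stacks, labels, k=4, seed=0, predictor=oracle)
        assert calls["n"] == 4
        assert report.mean_accuracy == 1.0

    def test_folds_partition_subjects(self, rng):
        stacks, labels = self._cohort(rng)
        seen = []

        def spy(train_x, train_y, test_x):
            seen.append(len(test_x))
            return np.zeros(len(test_x), dtype=int)

        report = cross_validate(stacks, labels, k=4, seed=0, predictor=spy)
        assert len(report.per_fold) == 4
        assert sum(seen) == len(stacks)
        assert sum(c.total for c, _ in report.per_fold) == len(stacks)
        expected_mean = np.mean([a for _, a in report.per_fold])
        assert report.mean_accuracy == pytest.approx(expected_mean)

    def test_reproducible_fingerprint_and_folds(self, rng):
        stacks, labels = self._cohort(rng, n_per_class=10)
        sched = TrainSchedule(epochs_head=2)
        r1 = cross_validate(stacks, labels, k=5, seed=3, schedule=sched)
        r2 = cross_validate(stacks, labels, k=5, seed=3, schedule=sched)
        assert r1.fingerprint == r2.fingerprint
        assert [(c.TP, c.FP, c.TN, c.FN) for c, _ in r1.per_fold] == [
            (c.TP, c.FP, c.TN, c.FN) for c, _ in r2.per_fold
        ]
        assert r1.mean_accuracy == r2.mean_accuracy

    def test_too_few_subjects(self, rng):
        stacks, labels = self._cohort(rng, n_per_class=3)
        with pytest.raises(TrainingError, match="at least"):
            cross_validate(stacks, labels, k=10)

    def test_stack_builder_called_per_fold(self, rng):
        stacks, labels = self._cohort(rng, n_per_class=8)
        fit_sets = []

        def builder(train_idx):
            fit_sets.append(tuple(sorted(train_idx)))
            return stacks

        def stub(train_x, train_y, test_x):
            return np.zeros(len(test_x), dtype=int)

        cross_validate(stacks, labels, k=4, seed=0, stack_builder=builder, predictor=stub)
        assert len(fit_sets) == 4
        n = len(stacks)
        for fs in fit_sets:
            assert len(fs) == n - n // 4  # test fold excluded from the fit
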