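"""Splits, metrics, CI arithmetic, noise, training loop, checkpoints."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pidsan.pidsan4 import Pidsan4, Pidsan4Config, weighted_cross_entropy
from pidsan.train_eval import (
    CiResult, DataBundle, SplitSpec, add_gaussian_noise, confusion_and_metrics,
    evaluate, kfold_plan, load_checkpoint, save_checkpoint, sem_ci,
    stratified_split, train_loop,
)


class TestStratifiedSplit:
    def test_exact_partition_and_balance(self):
        labels = np.array([0] * 500 + [1] * 500)
        tr, te, va = stratified_split(labels, SplitSpec(70, 20, 10, seed=3))
        assert len(tr) == 700 and len(te) == 200 and len(va) == 100
        union = np.concatenate([tr, te, va])
        assert len(np.unique(union)) == 1000
        for part, size in ((tr, 700), (te, 200), (va, 100)):
            assert abs((labels[part] == 0).sum() - size / 2) <= 1

    def test_bad_percentages_rejected(self):
        with pytest.raises(ValueError, match="sum to 100"):
            SplitSpec(60, 30, 20)

    def test_seed_reproducibility(self):
        labels = np.tile([0, 1], 50)
        a = stratified_split(labels, SplitSpec(seed=5))
        b = stratified_split(labels, SplitSpec(seed=5))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_adversarial_class_ratio_within_one_sample(self):
        labels = np.array([0] * 90 + [1] * 10)
        tr, te, va = stratified_split(labels, SplitSpec(50, 40, 10, seed=1))
        assert len(tr) + len(te) + len(va) == 100
        for part, frac in ((tr, 0.5), (te, 0.4), (va, 0.1)):
            assert abs((labels[part] == 1).sum() - 10 * frac) <= 1


class TestKfold:
    def test_folds_partition_with_stratification(self):
        labels = np.tile([0, 1], 50)
        folds = kfold_plan(labels, k=10, seed=2)
        assert len(folds) == 10
        all_idx = np.concatenate(folds)
        assert len(all_idx) == 100 and len(np.unique(all_idx)) == 100
        for fold in folds:
            assert len(fold) == 10
            assert abs((labels[fold] == 0).sum() - 5) <= 1

    def test_k_too_large_or_small_rejected(self):
        labels = np.tile([0, 1], 4)
        with pytest.raises(ValueError, match="k"):
            kfold_plan(labels, k=1)
        with pytest.raises(ValueError, match="class count"):
            kfold_plan(labels, k=6)


class TestMetrics:
    def test_perfect_predictions(self):
        rep = confusion_and_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        for field in ("accuracy", "sensitivity", "specificity", "precision",
                      "f_measure", "g_mean"):
            assert getattr(rep, field) == 1.0

    def test_hand_computed_confusion(self):
        # TP=9, FN=1, TN=8, FP=2
        y_true = [1] * 10 + [0] * 10
        y_pred = [1] * 9 + [0] + [1] * 2 + [0] * 8
        rep = confusion_and_metrics(y_true, y_pred)
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (9, 1, 2, 8)
        assert rep.sensitivity == pytest.approx(0.9)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.precision == pytest.approx(0.8181818, abs=1e-6)
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.f_measure == pytest.approx(0.8571429, abs=1e-6)
        assert rep.g_mean == pytest.approx(0.8485281, abs=1e-6)

    def test_no_predicted_positives_flagged(self):
        with pytest.warns(UserWarning, match="zero denominator"):
            rep = confusion_and_metrics([1, 0, 1], [0, 0, 0])
        assert rep.precision == 0.0
        assert "precision" in rep.undefined

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion_and_metrics([0, 1], [0, 1, 1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    def test_metric_identities(self, tp, fn, fp, tn):
        y_true = [1] * (tp + fn) + [0] * (tn + fp)
        y_pred = [1] * tp + [0] * fn + [1] * fp + [0] * tn
        if not y_true:
            return
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = confusion_and_metrics(y_true, y_pred)
        assert rep.g_mean ** 2 == pytest.approx(rep.sensitivity * rep.specificity,
                                                abs=1e-12)
        if rep.precision + rep.sensitivity > 0 and "precision" not in rep.undefined \
                and "sensitivity" not in rep.undefined:
            harmonic = 2 * rep.precision * rep.sensitivity / (rep.precision + rep.sensitivity)
            assert rep.f_measure == pytest.approx(harmonic, abs=1e-12)
        assert rep.tp + rep.tn + rep.fp + rep.fn == len(y_true)


# published precision / SEM pairs whose printed 95% CIs are internally
# consistent with p +/- 1.96*SEM at three decimals
CONSISTENT_CI_ROWS = [
    ("inceptionv3", 0.895, 0.00665, 0.882, 0.908),
    ("resnet50", 0.852, 0.00779, 0.837, 0.867),
    ("mobilenetv2", 0.877, 0.00718, 0.863, 0.891),
    ("modified_vit", 0.889, 0.00686, 0.876, 0.902),
]


class TestSemCi:
    def test_basic_proportion(self):
        res = sem_ci(0.5, n=100)
        assert res.sem == pytest.approx(0.05)
        assert res.lower == pytest.approx(0.402)
        assert res.upper == pytest.approx(0.598)

    @pytest.mark.parametrize("name,p,sem,lo,hi", CONSISTENT_CI_ROWS)
    def test_published_rows_reproduce_to_three_decimals(self, name, p, sem, lo, hi):
        res = sem_ci(p, sem_override=sem)
        assert round(res.lower, 3) == lo
        assert round(res.upper, 3) == hi

    def test_sem_from_n_2131_differs_from_published_sem(self):
        """Recomputing sqrt(p(1-p)/N) at N=2131 does not reproduce the
        published SEM column; the computed values are the asserted ones."""
        computed_inception = sem_ci(0.895, n=2131).sem
        assert computed_inception == pytest.approx(0.00664, abs=5e-6)
        assert round(computed_inception, 5) != 0.00665
        computed_pidsan = sem_ci(0.883, n=2131).sem
        assert computed_pidsan == pytest.approx(0.00696, abs=5e-6)
        assert round(computed_pidsan, 5) != 0.00698

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sem_ci(1.2, n=10)
        with pytest.raises(ValueError):
            sem_ci(0.5)


class TestGaussianNoise:
    def test_zero_level_identity(self, rng):
        img = rng.random((10, 10, 3))
        np.testing.assert_array_equal(add_gaussian_noise(img, 0.0, seed=1), img)

    def test_noise_std_matches_level(self):
        img = np.full((200, 250), 0.5)     # mid-grey: clipping negligible
        noisy = add_gaussian_noise(img, 5.0, seed=0)
        assert np.std(noisy - img) == pytest.approx(0.05, rel=0.05)

    def test_seed_determinism(self, rng):
        img = rng.random((8, 8, 3))
        np.testing.assert_array_equal(add_gaussian_noise(img, 3.0, seed=9),
                                      add_gaussian_noise(img, 3.0, seed=9))

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            add_gaussian_noise(np.zeros((2, 2)), -1.0)


def small_bundle(rng, n=24, size=32):
    from pidsan.synth import synthetic_dataset
    images, labels, _ = synthetic_dataset(n // 2, n // 2, image_size=size, seed=5)
    order = rng.permutation(n)
    images, labels = images[order], labels[order]
    return DataBundle(images[:16], labels[:16], images[16:], labels[16:])


class TestTrainLoop:
    def test_loss_decreases_on_separable_data(self, rng):
        bundle = small_bundle(rng)
        model = Pidsan4(Pidsan4Config.reduced(input_size=32, seed=0))
        model, hist = train_loop(model, bundle,
                                 {"learning_rate": 0.005, "batch_size": 8,
                                  "epochs": 4}, seed=0)
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert len(hist.val_accuracy) == 4

    def test_unit_weight_loss_equals_unweighted(self, rng):
        probs = rng.dirichlet(np.ones(2), size=8)
        onehot = np.eye(2)[rng.integers(0, 2, 8)]
        assert weighted_cross_entropy(probs, onehot, np.ones(2)) == pytest.approx(
            weighted_cross_entropy(probs, onehot), abs=1e-14)

    def test_checkpoint_roundtrip_preserves_predictions(self, rng, tmp_path):
        bundle = small_bundle(rng)
        model = Pidsan4(Pidsan4Config.reduced(input_size=32, seed=0))
        model, _ = train_loop(model, bundle,
                              {"learning_rate": 0.005, "batch_size": 8,
                               "epochs": 1}, seed=0)
        before = model.predict_proba(bundle.val_images)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path, metadata={"note": "test"})
        restored, meta = load_checkpoint(path)
        assert meta == {"note": "test"}
        np.testing.assert_array_equal(restored.predict_proba(bundle.val_images),
                                      before)


class TestEvaluate:
    def test_report_per_noise_level(self, rng):
        bundle = small_bundle(rng)
        model = Pidsan4(Pidsan4Config.reduced(input_size=32, seed=0))
        reports = evaluate(model, bundle.val_images, bundle.val_labels,
                           noise_levels=[0.0, 3.0])
        assert set(reports) == {0.0, 3.0}
        rep = reports[0.0]
        assert rep.tp + rep.tn + rep.fp + rep.fn == len(bundle.val_labels)

    def test_empty_dataset_rejected(self, rng):
        model = Pidsan4(Pidsan4Config.reduced(input_size=32, seed=0))
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, np.zeros((0, 32, 32, 3)), np.zeros(0, dtype=int))
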