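"""Training loop, metrics and the subject-wise CV harness."""

import numpy as np
import pytest

from cohgram.errors import ConfigurationError, ContractError
from cohgram.evaluate import (
    TrainConfig,
    assert_no_leakage,
    evaluate,
    subject_wise_cv,
    train,
)
from cohgram.models import ModelSpec, build_model
from cohgram.nn import Layer, Sequential
from cohgram.split import SplitPlan, assign_folds


class _FixedLogits(Layer):
    """Stub model that returns pre-set logits row-aligned with its input
    (first input feature indexes the logit table)."""

    def __init__(self, table: np.ndarray):
        self.table = table

    def forward(self, x, training=False):
        idx = x.reshape(x.shape[0], -1)[:, 0].astype(int)
        return self.table[idx]


def _stub_model(logits: np.ndarray) -> Sequential:
    return Sequential([_FixedLogits(np.asarray(logits, dtype=float))])


def _index_images(n, shape=(4, 3)):
    """Images whose first pixel encodes their row index."""
    x = np.zeros((n, *shape))
    x[:, 0, 0] = np.arange(n)
    return x


SPEC3 = ModelSpec("shallow_resnet", (4, 3), 3)


class TestEvaluate:
    def test_perfect_predictions(self):
        logits = np.eye(3)[[0, 0, 1, 1, 2, 2]] * 10.0
        model = _stub_model(logits)
        rep = evaluate(model, _index_images(6),
                       ["a", "a", "b", "b", "c", "c"], SPEC3)
        assert rep.accuracy == 1.0
        np.testing.assert_array_equal(rep.confusion, 2 * np.eye(3))
        np.testing.assert_array_equal(rep.precision, 1.0)
        np.testing.assert_array_equal(rep.roc_auc, 1.0)

    def test_all_one_class_on_balanced_set(self):
        logits = np.tile([10.0, 0.0, 0.0], (6, 1))
        rep = evaluate(_stub_model(logits), _index_images(6),
                       ["a", "a", "b", "b", "c", "c"], SPEC3)
        assert rep.accuracy == pytest.approx(1 / 3)

    def test_metrics_match_textbook_formulas(self):
        """Cross-check precision/recall/F1 against direct computation
        from the confusion matrix."""
        y_true = ["a"] * 5 + ["b"] * 4 + ["c"] * 3
        pred_idx = [0, 0, 0, 1, 2, 1, 1, 1, 0, 2, 2, 0]
        logits = np.eye(3)[pred_idx] * 8.0
        rep = evaluate(_stub_model(logits), _index_images(12), y_true, SPEC3)
        cm = rep.confusion
        for k in range(3):
            tp = cm[k, k]
            prec = tp / cm[:, k].sum() if cm[:, k].sum() else 0.0
            rec = tp / cm[k, :].sum()
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert rep.precision[k] == pytest.approx(prec)
            assert rep.recall[k] == pytest.approx(rec)
            assert rep.f1[k] == pytest.approx(f1)
        np.testing.assert_array_equal(rep.support, [5, 4, 3])
        assert rep.accuracy == pytest.approx(np.trace(cm) / cm.sum())
        assert cm.sum(axis=1).tolist() == rep.support.tolist()

    def test_absent_class_auc_nan_not_error(self):
        logits = np.eye(3)[[0, 1, 0, 1]] * 5.0
        rep = evaluate(_stub_model(logits), _index_images(4),
                       ["a", "b", "a", "b"], SPEC3, classes=["a", "b", "c"])
        assert np.isnan(rep.roc_auc[2])
        assert not np.isnan(rep.roc_auc[0])


class TestTrain:
    def test_single_class_rejected(self):
        spec = ModelSpec("shallow_resnet", (8, 3), 2)
        model = build_model(spec)
        with pytest.raises(ConfigurationError, match="single class"):
            train(model, np.zeros((4, 8, 3)), ["a"] * 4,
                  TrainConfig(epochs=1), spec)

    def test_history_length_matches_epochs(self, rng):
        spec = ModelSpec("shallow_resnet", (8, 3), 2)
        model = build_model(spec, seed=0)
        x = rng.standard_normal((6, 8, 3))
        hist = train(model, x, ["a", "b", "a", "b", "a", "b"],
                     TrainConfig(epochs=1, batch_size=2, seed=0), spec)
        assert len(hist["loss"]) == 1
        assert len(hist["accuracy"]) == 1

    def test_seeded_training_is_deterministic(self, rng):
        spec = ModelSpec("shallow_resnet", (8, 3), 2)
        x = rng.standard_normal((8, 8, 3))
        y = ["a", "b"] * 4
        weights = []
        for _ in range(2):
            model = build_model(spec, seed=7)
            train(model, x, y, TrainConfig(epochs=2, batch_size=4, seed=7),
                  spec)
            weights.append(model.get_weights())
        for a, b in zip(*weights):
            np.testing.assert_array_equal(a, b)

    def test_cnn_learns_separable_images(self, rng):
        """Two classes whose means differ by 0.3 in a pixel block are fit
        to >= 0.95 training accuracy within 20 epochs."""
        n = 40
        x = np.clip(rng.normal(0.4, 0.1, (n, 24, 24)), 0, 1)
        x[n // 2:, 4:12, 4:12] = np.clip(x[n // 2:, 4:12, 4:12] + 0.3, 0, 1)
        y = ["a"] * (n // 2) + ["b"] * (n // 2)
        spec = ModelSpec("custom_cnn", (24, 24, 1), 2)
        model = build_model(spec, seed=5)
        hist = train(model, x, y,
                     TrainConfig(epochs=20, batch_size=8, seed=5), spec)
        assert hist["accuracy"][-1] >= 0.95

    def test_validation_history_recorded(self, rng):
        spec = ModelSpec("shallow_resnet", (8, 3), 2)
        model = build_model(spec, seed=0)
        x = rng.standard_normal((6, 8, 3))
        hist = train(model, x, ["a", "b"] * 3,
                     TrainConfig(epochs=2, batch_size=3, seed=0), spec,
                     val_images=x[:2], val_labels=["a", "b"])
        assert len(hist["val_accuracy"]) == 2
        assert len(hist["val_loss"]) == 2


class TestLeakage:
    def test_disjoint_passes(self):
        assert_no_leakage(["s1", "s2"], ["s3"])

    def test_overlap_hard_failure(self):
        with pytest.raises(ContractError, match="s2"):
            assert_no_leakage(["s1", "s2"], ["s2", "s3"])

    def test_cv_refuses_leaky_plan(self, rng):
        """A subject present in the images but absent from the plan is a
        configuration error, never a silent pass."""
        plan = SplitPlan(k=2, assignment={"s0": 0, "s1": 1})
        spec = ModelSpec("shallow_resnet", (8, 3), 2)
        with pytest.raises(ConfigurationError, match="s2"):
            subject_wise_cv(rng.standard_normal((4, 8, 3)),
                            ["a", "a", "b", "b"],
                            ["s0", "s1", "s2", "s2"], plan, spec,
                            TrainConfig(epochs=1))


class TestSubjectWiseCV:
    def test_fold_structure_and_aggregate(self, rng):
        """k=5 on 10 subjects: 5 reports, each test fold holds exactly 2
        subjects' segments, and the aggregate sd matches direct
        recomputation."""
        subjects = [f"s{i}" for i in range(10)]
        labels = ["a" if i < 5 else "b" for i in range(10)]
        plan = assign_folds(list(zip(subjects, labels)), k=5, seed=0)
        seg_subj, seg_lab, imgs = [], [], []
        for sid, lab in zip(subjects, labels):
            for _ in range(3):
                img = rng.random((8, 3)) * 0.2
                if lab == "b":
                    img[:4] += 0.5
                imgs.append(np.clip(img, 0, 1))
                seg_subj.append(sid)
                seg_lab.append(lab)
        spec = ModelSpec("shallow_resnet", (8, 3), 2)
        cfg = TrainConfig(epochs=8, batch_size=6, seed=0, val_fraction=0.0)
        reports, agg = subject_wise_cv(np.stack(imgs), seg_lab, seg_subj,
                                       plan, spec, cfg)
        assert len(reports) == 5
        for fold, rep in enumerate(reports):
            assert rep.support.sum() == 6  # 2 subjects x 3 segments
        accs = np.array([r.accuracy for r in reports])
        assert agg["mean_accuracy"] == pytest.approx(accs.mean())
        assert agg["sd_accuracy"] == pytest.approx(accs.std(ddof=1))
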