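"""CNN regressor: architecture conformance, determinism, recoverability."""

import numpy as np
import pytest

from bcgbp import (
    ArchitectureSpec,
    PhaseEpoch,
    TrainSettings,
    build_model,
    make_cv_folds,
    parameter_count,
    predict_bp,
    shape_report,
    split_train_test,
    train_model,
)
from bcgbp.cnnreg import _fit_one, _to_engine, epochs_to_arrays, predict_arrays

TINY = ArchitectureSpec(
    input_len=100, in_channels=2, conv_filters=(8, 12, 16), conv_kernels=(5, 3, 3)
)


def linear_phase_epochs(n, n_samples=100, fs=100.0, seed=0, session="rest"):
    """Epochs whose SBP is an exact linear function of the seat-channel
    phase shift — recoverable by construction."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    wrap = lambda p: np.angle(np.exp(1j * p))
    out = []
    for i in range(n):
        delta = rng.uniform(0.0, 0.5)
        base = 2 * np.pi * 2.0 * t + rng.uniform(0, 2 * np.pi)
        out.append(
            PhaseEpoch(
                phase_back=wrap(base),
                phase_seat=wrap(base + delta),
                sbp=110.0 + 40.0 * delta,
                dbp=70.0,
                session=session,
                subject_id=f"s{i:02d}",
            )
        )
    return out


class TestBuildModel:
    def test_shape_report_matches_published_topology(self):
        report = shape_report(ArchitectureSpec())
        got = [(r["layer"], r["channels"], r["length"]) for r in report]
        assert got == [
            ("input", 2, 1000),
            ("conv1", 100, 1000),
            ("pool1", 100, 500),
            ("conv2", 200, 500),
            ("pool2", 200, 250),
            ("conv3", 300, 250),
            ("gap", 300, 1),
            ("dense", 1, 1),
        ]

    def test_parameter_count_matches_hand_arithmetic(self):
        spec = ArchitectureSpec()
        convs = zip((spec.in_channels,) + spec.conv_filters[:-1], spec.conv_filters,
                    spec.conv_kernels)
        expected = sum(k * ci * co + co for ci, co, k in convs)
        expected += 2 * sum(spec.conv_filters)  # batch-norm gamma/beta
        expected += spec.conv_filters[-1] * 1 + 1  # dense head
        assert parameter_count(spec) == expected

    def test_single_scalar_output(self):
        model, _ = build_model(TINY, np.random.default_rng(0))
        x = np.random.default_rng(1).standard_normal((1, 100, 2)).astype(np.float32)
        assert model.forward(x).shape == (1, 1)

    def test_incompatible_input_length_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ArchitectureSpec(input_len=1001)


class TestTrainModel:
    @pytest.fixture(scope="class")
    def fitted(self):
        eps = linear_phase_epochs(40, seed=3)
        plan = make_cv_folds(split_train_test(eps, seed=1), k=10)
        settings = TrainSettings(
            target="sbp", batch_size=4, max_epochs=120, early_stop_patience=120, seed=5
        )
        model = train_model(eps, plan, TINY, settings)
        return eps, plan, settings, model

    def test_fold_history_contract(self, fitted):
        _, _, _, model = fitted
        assert len(model.fold_history) == 10
        assert model.selected_fold == int(np.argmin(model.fold_history))

    def test_training_set_overfit_to_construction(self, fitted):
        eps, plan, _, model = fitted
        train_eps = [eps[i] for i in plan.train]
        preds = predict_bp(model, train_eps)
        refs = np.array([e.sbp for e in train_eps])
        assert np.mean((preds - refs) ** 2) < 1.0

    def test_held_out_predictions_track_truth(self, fitted):
        eps, plan, _, model = fitted
        test_eps = [eps[i] for i in plan.test]
        preds = predict_bp(model, test_eps)
        refs = np.array([e.sbp for e in test_eps])
        assert np.corrcoef(preds, refs)[0, 1] > 0.9

    def test_seeded_determinism(self):
        eps = linear_phase_epochs(30, seed=2)
        plan = make_cv_folds(split_train_test(eps, seed=0), k=10)
        settings = TrainSettings(target="sbp", batch_size=4, max_epochs=5, seed=9)
        m1 = train_model(eps, plan, TINY, settings)
        m2 = train_model(eps, plan, TINY, settings)
        assert m1.fold_history == m2.fold_history
        assert all(np.array_equal(m1.weights[k], m2.weights[k]) for k in m1.weights)

    def test_mixed_sessions_rejected(self):
        mixed = linear_phase_epochs(20, seed=0) + linear_phase_epochs(
            20, seed=1, session="recovery"
        )
        plan = make_cv_folds(split_train_test_unchecked(mixed), k=10)
        with pytest.raises(ValueError, match="session"):
            train_model(mixed, plan, TINY, TrainSettings(target="sbp"))

    def test_refit_full_train_uses_all_training_epochs(self):
        eps = linear_phase_epochs(30, seed=8)
        plan = make_cv_folds(split_train_test(eps, seed=0), k=10)
        settings = TrainSettings(target="sbp", batch_size=4, max_epochs=120,
                                 early_stop_patience=120, seed=1)
        model = train_model(eps, plan, TINY, settings, refit_full_train=True)
        assert len(model.fold_history) == 10
        assert model.train_log[-1]["fold"] == "refit_full_train"
        train_eps = [eps[i] for i in plan.train]
        preds = predict_bp(model, train_eps)
        refs = np.array([e.sbp for e in train_eps])
        assert np.corrcoef(preds, refs)[0, 1] > 0.9

    def test_plan_without_folds_rejected(self):
        eps = linear_phase_epochs(20, seed=0)
        plan = split_train_test(eps, seed=0)
        with pytest.raises(ValueError, match="folds"):
            train_model(eps, plan, TINY, TrainSettings(target="sbp"))

    @pytest.mark.filterwarnings("ignore:overflow")
    def test_divergence_guard_raises(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((8, 100, 2)).astype(np.float32)
        y = np.full(8, 1e38, dtype=np.float32)  # squared error overflows
        model, _ = build_model(TINY, rng)
        with pytest.raises(RuntimeError, match="diverged"):
            _fit_one(model, x, y, x, y,
                     TrainSettings(target="sbp", batch_size=4, max_epochs=2), rng)


class TestPredictBp:
    def test_batch_invariance(self):
        eps = linear_phase_epochs(12, seed=4)
        x, _ = epochs_to_arrays(eps, "sbp")
        model, _ = build_model(TINY, np.random.default_rng(0))
        xe = _to_engine(x)
        single = np.concatenate(
            [predict_arrays(model, xe[i : i + 1]) for i in range(len(eps))]
        )
        batched = predict_arrays(model, xe)
        assert np.max(np.abs(single - batched)) < 1e-4

    def test_duplicated_epoch_identical_predictions(self):
        eps = linear_phase_epochs(1, seed=6)
        x, _ = epochs_to_arrays(eps * 4, "sbp")
        model, _ = build_model(TINY, np.random.default_rng(0))
        preds = predict_arrays(model, _to_engine(x))
        assert np.all(preds == preds[0])

    def test_wrong_epoch_length_rejected(self):
        eps = linear_phase_epochs(20, seed=0)
        plan = make_cv_folds(split_train_test(eps, seed=0), k=10)
        settings = TrainSettings(target="sbp", max_epochs=1)
        model = train_model(eps, plan, TINY, settings)
        bad = linear_phase_epochs(2, n_samples=50, seed=1)
        with pytest.raises(ValueError, match="samples"):
            predict_bp(model, bad)


def split_train_test_unchecked(epochs):
    """Hand-built plan that bypasses the splitter's own session guard, so the
    trainer's guard is exercised in isolation."""
    from bcgbp import SplitPlan

    n = len(epochs)
    idx = np.arange(n)
    return SplitPlan(train=idx[: int(0.8 * n)], test=idx[int(0.8 * n):], seed=0, mode="epoch")
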