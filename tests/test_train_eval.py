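"""Training loop, metrics vs oracles, protocols, classical baselines."""

from dataclasses import replace

import numpy as np
import pytest

from protacdeg.dataset import SplitSpec, split
from protacdeg.model import ModelConfig, init_model
from protacdeg.train_eval import (
    EvalReport,
    TrainConfig,
    aggregate_reports,
    evaluate,
    leave_one_target_out,
    mean_loss,
    paired_ttest,
    predict_proba,
    prepare_samples,
    run_ablation_suite,
    train,
    train_rf,
    train_svm,
)

FAST = TrainConfig(epochs=2, seed=5)
SMALL_CFG = ModelConfig()


def _auroc_bruteforce(y, p):
    """All-pairs concordance count (ties count half)."""
    pos = [pi for yi, pi in zip(y, p) if yi == 1]
    neg = [pi for yi, pi in zip(y, p) if yi == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class _FixedModel:
    """Evaluation stub with predetermined probabilities."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)


def _fake_samples(labels):
    from protacdeg.train_eval import FeaturizedSample

    return [
        FeaturizedSample(record_id=str(k), poi_name="P", inputs={}, label=int(y))
        for k, y in enumerate(labels)
    ]


@pytest.fixture()
def patched_eval(monkeypatch):
    """evaluate() with predict_proba replaced by a table lookup."""

    def make(y, p):
        import protacdeg.train_eval as te

        monkeypatch.setattr(
            te, "predict_proba", lambda params, samples: np.asarray(p, dtype=float)
        )
        return te.evaluate(None, _fake_samples(y))

    return make


class TestMetrics:
    def test_perfect_scores(self, patched_eval):
        rep = patched_eval([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert rep.accuracy == 100.0
        assert rep.auroc == 1.0
        assert rep.tpr == 100.0 and rep.precision == 100.0

    def test_perfect_ranking_despite_threshold_misses(self, patched_eval):
        rep = patched_eval([1, 1, 0, 0], [0.9, 0.8, 0.7, 0.1])
        assert rep.auroc == 1.0
        assert rep.accuracy == 75.0  # the 0.7 inactive crosses the threshold

    def test_auroc_matches_bruteforce_oracle(self, patched_eval, rng):
        y = rng.integers(0, 2, size=200)
        y[:3] = [0, 1, 0]  # both classes present
        p = np.round(rng.uniform(0, 1, size=200), 2)  # ties likely
        rep = patched_eval(y.tolist(), p.tolist())
        assert rep.auroc == pytest.approx(_auroc_bruteforce(y, p), abs=1e-9)

    def test_single_class_auroc_missing_with_warning(self, patched_eval, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            rep = patched_eval([1, 1, 1], [0.9, 0.8, 0.7])
        assert rep.auroc is None
        assert "single-class" in caplog.text

    def test_aggregate_mean_sd(self):
        reps = [
            EvalReport(80.0, 0.9, None, None, 10),
            EvalReport(70.0, 0.8, None, None, 10),
            EvalReport(90.0, 1.0, None, None, 10),
        ]
        agg = aggregate_reports(reps)
        assert agg["accuracy_mean"] == pytest.approx(80.0)
        assert agg["accuracy_sd"] == pytest.approx(10.0)  # sample SD, n-1
        assert agg["auroc_mean"] == pytest.approx(0.9)
        assert agg["n_runs"] == 3

    def test_paired_ttest_two_sided(self):
        t, p = paired_ttest([1.0, 2.0, 3.0, 4.0], [1.1, 2.1, 3.1, 4.1])
        assert p < 0.05  # consistent small difference
        t2, p2 = paired_ttest([1.0, 2.0, 3.0], [2.0, 1.5, 2.5])
        assert p2 > 0.05


class TestTraining:
    def test_loss_history_shape_and_finite(self, tiny_samples):
        tr = tiny_samples[:20]
        params, hist = train(SMALL_CFG, tr, None, FAST)
        assert len(hist) == 2
        assert all(np.isfinite(h) for h in hist)

    def test_deterministic_under_seed(self, tiny_samples):
        tr = tiny_samples[:16]
        p1, h1 = train(SMALL_CFG, tr, None, FAST)
        p2, h2 = train(SMALL_CFG, tr, None, FAST)
        assert h1 == h2
        assert p1.checksum() == p2.checksum()
        te = tiny_samples[16:28]
        assert evaluate(p1, te) == evaluate(p2, te)

    def test_weight_sharing_survives_updates(self, tiny_samples):
        params, _ = train(SMALL_CFG, tiny_samples[:12], None, FAST)
        pocket = params.branch_group("poi_pocket")
        assert pocket is params.branch_group("e3_pocket")
        lig = params.branch_group("warhead")
        assert lig is params.branch_group("e3_ligand")
        # the shared state actually moved during training
        fresh = init_model(SMALL_CFG, FAST.seed)
        assert not np.allclose(
            pocket["W1"].data, fresh.branch_group("poi_pocket")["W1"].data
        )

    def test_weighted_loss_doubles_active_sample_loss(self, tiny_samples):
        active = next(s for s in tiny_samples if s.label == 1)
        params = init_model(SMALL_CFG, 0)
        normal = mean_loss([active], params, SMALL_CFG, (1.0, 1.0))
        weighted = mean_loss([active], params, SMALL_CFG, (2.0, 1.0))
        assert weighted == pytest.approx(2 * normal, rel=1e-12)
        inactive = next(s for s in tiny_samples if s.label == 0)
        same = mean_loss([inactive], params, SMALL_CFG, (2.0, 1.0))
        assert same == pytest.approx(
            mean_loss([inactive], params, SMALL_CFG, (1.0, 1.0)), rel=1e-12
        )

    def test_balanced_assertion_trips_on_imbalance(self, tiny_samples):
        imbalanced = [s for s in tiny_samples if s.label == 0][:4] + [
            s for s in tiny_samples if s.label == 1
        ][:2]
        cfg = replace(FAST, assert_balanced=True)
        with pytest.raises(AssertionError, match="not 1:1"):
            train(SMALL_CFG, imbalanced, None, cfg)

    def test_early_stopping_with_batch_size_over_one(self, tiny_samples):
        tr, val = tiny_samples[:12], tiny_samples[12:18]
        cfg = replace(FAST, batch_size=4, patience=1, max_epochs=4)
        params, hist = train(SMALL_CFG, tr, val, cfg)
        assert 1 <= len(hist) <= 4

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train(SMALL_CFG, [], None, FAST)


class TestProtocols:
    def test_ablation_suite_shape(self, tiny_samples):
        tr, te = split(tiny_samples, SplitSpec((0.7, 0.3), seed=2))
        df = run_ablation_suite(
            tr, te, SMALL_CFG, replace(FAST, epochs=1), items=(1, 6), repeats=2
        )
        assert len(df) == 2
        assert list(df["item"]) == [1, 6]
        assert all(len(runs) == 2 for runs in df["per_run_accuracy"])
        assert "linker" not in df.loc[df.item == 6, "branches"].iloc[0]

    def test_loto_exclusion_and_counts(self, tiny_samples):
        target = tiny_samples[0].poi_name
        held_rep, rest_rep = leave_one_target_out(
            tiny_samples, target, SMALL_CFG, replace(FAST, epochs=1)
        )
        n_target = sum(s.poi_name == target for s in tiny_samples)
        assert held_rep.n == n_target
        n_rest = len(tiny_samples) - n_target
        assert rest_rep.n == int(np.floor(0.2 * n_rest)) or rest_rep.n == round(
            0.2 * n_rest
        )

    def test_loto_unknown_target_rejected(self, tiny_samples):
        with pytest.raises(ValueError, match="NOPE"):
            leave_one_target_out(tiny_samples, "NOPE", SMALL_CFG, FAST)


class TestExports:
    def test_roc_points_monotone_and_bounded(self, tiny_samples):
        from protacdeg.train_eval import roc_points

        params, _ = train(SMALL_CFG, tiny_samples[:12], None, replace(FAST, epochs=1))
        df = roc_points(params, tiny_samples[12:40])
        assert {"fpr", "tpr", "threshold"} <= set(df.columns)
        assert df["fpr"].is_monotonic_increasing
        assert df["fpr"].between(0, 1).all() and df["tpr"].between(0, 1).all()

    def test_feature_matrix_csv_has_provenance_header(self, tmp_path):
        import pandas as pd

        from protacdeg.baselines import feature_matrix_to_csv, maccs_fp

        vecs = [maccs_fp("CCO"), maccs_fp("c1ccccc1")]
        out = tmp_path / "feats.csv"
        feature_matrix_to_csv(out, vecs, ["a", "b"])
        df = pd.read_csv(out, index_col="record_id")
        assert df.shape == (2, 166)
        assert all(c.startswith("maccs_") for c in df.columns)
        with pytest.raises(ValueError, match="mixed"):
            from protacdeg.baselines import morgan_fp

            feature_matrix_to_csv(out, [maccs_fp("C"), morgan_fp("C")], ["a", "b"])


class TestClassicalBaselines:
    def test_svm_separable_data_perfect_train_accuracy(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (20, 5)), rng.normal(3, 0.3, (20, 5))])
        y = np.array([0] * 20 + [1] * 20)
        clf = train_svm(X, y)
        assert clf.kernel == "linear" and clf.C == 1.0
        assert (clf.predict(X) == y).mean() == 1.0

    def test_rf_depth_limit_hurts_deep_interactions(self, rng):
        """6-bit parity needs depth > 5; a depth-5 forest cannot fit it."""
        X = rng.integers(0, 2, size=(256, 6)).astype(float)
        y = (X.sum(axis=1) % 2).astype(int)
        clf = train_rf(X, y)
        assert clf.max_depth == 5 and clf.n_estimators == 100
        assert (clf.predict(X) == y).mean() < 1.0

    def test_probability_scores_in_unit_interval(self, rng):
        X = rng.normal(size=(40, 4))
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        for fit in (train_svm, train_rf):
            p = fit(X, y).predict_proba(X)[:, 1]
            assert np.all((p >= 0) & (p <= 1))
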