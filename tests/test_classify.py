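"""LOPO balanced splits, classifier selection, baselines and metrics."""

import numpy as np
import pytest

import cytoblast as cb
from cytoblast.classify import BLAST, HEALTHY


def make_labeled_set(n_patients=20, blasts_per_patient=1500, n_remission=20_000,
                     n_channels=5, seed=0, shift=0.0):
    """A synthetic LabeledSRESet; blast rows optionally shifted upward."""
    rng = np.random.default_rng(seed)
    n_blast = n_patients * blasts_per_patient
    values = np.abs(rng.normal(0.1, 0.05, size=(n_remission + n_blast, n_channels)))
    values[n_remission:] += shift
    labels = np.asarray([HEALTHY] * n_remission + [BLAST] * n_blast)
    pids = np.asarray(
        ["rem"] * n_remission
        + [f"P{i}" for i in range(n_patients) for _ in range(blasts_per_patient)]
    )
    origin = np.asarray(["remission_test"] * n_remission
                        + ["annotated_nonremission"] * n_blast)
    sre = cb.SREMatrix(values=values, channels=[f"m{i}" for i in range(n_channels)])
    return cb.LabeledSRESet(sre=sre, labels=labels, patient_ids=pids, origin=origin)


class TestLOPOSplits:
    def test_twenty_patients_twenty_balanced_splits(self):
        data = make_labeled_set(n_patients=20, blasts_per_patient=1500,
                                n_remission=20_000)
        plan = cb.build_lopo_splits(data, seed=1)
        assert plan.n_folds == 20
        # stated fractions: validation share 1/20 of the remission pool,
        # training share the remaining 19/20
        assert (plan.balance_report["val_healthy"] == 1000).all()
        assert (plan.balance_report["val_blast"] == 1000).all()
        assert (plan.balance_report["train_healthy"] == 19_000).all()
        assert (plan.balance_report["train_blast"] == 19_000).all()
        assert plan.balance_report["balanced"].all()

    def test_validation_blasts_single_patient_and_disjoint(self):
        data = make_labeled_set(n_patients=5, blasts_per_patient=300,
                                n_remission=2_000)
        plan = cb.build_lopo_splits(data, seed=0)
        for train, val in plan.folds:
            val_pat = set(data.patient_ids[val][data.labels[val] == BLAST])
            train_pat = set(data.patient_ids[train][data.labels[train] == BLAST])
            assert len(val_pat) == 1
            assert val_pat.isdisjoint(train_pat)
            assert len(set(train) & set(val)) == 0

    def test_fold_class_balance(self):
        data = make_labeled_set(n_patients=4, blasts_per_patient=1_000,
                                n_remission=4_000)
        plan = cb.build_lopo_splits(data, seed=3)
        for train, val in plan.folds:
            assert (data.labels[val] == BLAST).sum() == (data.labels[val] == HEALTHY).sum()
            assert (data.labels[train] == BLAST).sum() == (data.labels[train] == HEALTHY).sum()

    def test_scarce_blasts_flagged_imbalanced(self):
        data = make_labeled_set(n_patients=3, blasts_per_patient=10,
                                n_remission=3_000)
        plan = cb.build_lopo_splits(data, seed=0)
        assert not plan.balance_report["balanced"].any()
        assert (plan.balance_report["val_blast"] == 10).all()

    def test_too_few_patients_rejected(self):
        data = make_labeled_set(n_patients=1, blasts_per_patient=50, n_remission=500)
        with pytest.raises(ValueError):
            cb.build_lopo_splits(data, seed=0)


class TestClassifierSelection:
    def test_separable_sre_perfect_validation_accuracy(self):
        data = make_labeled_set(n_patients=4, blasts_per_patient=100,
                                n_remission=800, shift=5.0, seed=2)
        plan = cb.build_lopo_splits(data, seed=2)
        clf = cb.train_select_classifier(plan, data, n_trials=2, seed=2,
                                         model_space=[("linear", {"C": [1.0]})])
        assert clf.mean_val_accuracy == pytest.approx(1.0)

    def test_selection_reproducible(self):
        data = make_labeled_set(n_patients=3, blasts_per_patient=80,
                                n_remission=600, shift=1.0, seed=4)
        plan = cb.build_lopo_splits(data, seed=4)
        a = cb.train_select_classifier(plan, data, n_trials=3, seed=7)
        b = cb.train_select_classifier(plan, data, n_trials=3, seed=7)
        assert a.family == b.family and a.params == b.params
        assert a.trials.equals(b.trials)

    def test_prediction_consistency_and_zero_rows(self):
        data = make_labeled_set(n_patients=3, blasts_per_patient=100,
                                n_remission=900, shift=5.0, seed=5)
        plan = cb.build_lopo_splits(data, seed=5)
        clf = cb.train_select_classifier(plan, data, n_trials=2, seed=5)
        # duplicated rows get identical label and score
        dup = cb.SREMatrix(values=np.vstack([data.sre.values[:1]] * 2),
                           channels=data.sre.channels)
        pred = cb.predict_blasts(clf, dup)
        assert pred.labels[0] == pred.labels[1]
        assert pred.scores[0] == pred.scores[1]
        # all-zero SRE (perfect reconstruction) is healthy-like by construction
        zeros = cb.SREMatrix(values=np.zeros((5, 5)), channels=data.sre.channels)
        assert (cb.predict_blasts(clf, zeros).labels == HEALTHY).all()

    def test_channel_mismatch_rejected(self):
        data = make_labeled_set(n_patients=3, blasts_per_patient=50,
                                n_remission=300, shift=5.0)
        plan = cb.build_lopo_splits(data, seed=0)
        clf = cb.train_select_classifier(plan, data, n_trials=1, seed=0)
        bad = cb.SREMatrix(values=np.zeros((2, 3)), channels=["a", "b", "c"])
        with pytest.raises(ValueError):
            cb.predict_blasts(clf, bad)


class TestGateAndMetrics:
    def test_gate_extremes(self, panel):
        m = cb.CellMatrix(np.full((10, 23), 3.0), list(panel.channels), "arcsinh")
        assert (cb.cd45low_gate(m, 1.0) == HEALTHY).all()
        assert (cb.cd45low_gate(m, np.inf) == BLAST).all()

    def test_missing_cd45_rejected(self):
        m = cb.CellMatrix(np.ones((2, 2)), ["a", "b"], "arcsinh")
        with pytest.raises(KeyError):
            cb.cd45low_gate(m, 1.0)

    def test_perfect_prediction_metrics(self):
        y = np.asarray(["b", "h", "b", "h"])
        metrics = cb.evaluate_predictions(y, y)
        assert metrics["accuracy"] == 1.0
        assert metrics["balanced_accuracy"] == 1.0

    def test_hand_computed_recalls(self):
        truth = np.asarray(["b", "b", "h", "h"])
        pred = np.asarray(["b", "h", "h", "h"])
        metrics = cb.evaluate_predictions(pred, truth)
        assert metrics["accuracy"] == pytest.approx(0.75)
        assert metrics["balanced_accuracy"] == pytest.approx(0.75)  # (0.5 + 1.0)/2
        assert metrics["confusion"]["true_b|pred_h"] == 1

    def test_single_class_truth_warns(self):
        with pytest.warns(UserWarning):
            metrics = cb.evaluate_predictions(["b", "h"], ["b", "b"])
        assert metrics["balanced_accuracy"] == pytest.approx(0.5)

    def test_matches_bruteforce_confusion_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = rng.integers(10, 1000)
            truth = rng.choice(["b", "h"], size=n)
            pred = rng.choice(["b", "h"], size=n)
            m = cb.evaluate_predictions(pred, truth)
            # independent brute-force loop
            correct = sum(p == t for p, t in zip(pred, truth))
            assert m["accuracy"] == correct / n
            recalls = []
            for c in np.unique(truth):
                idx = [i for i in range(n) if truth[i] == c]
                recalls.append(sum(pred[i] == c for i in idx) / len(idx))
            assert m["balanced_accuracy"] == pytest.approx(np.mean(recalls), abs=1e-12)
            counts = {}
            for t, p in zip(truth, pred):
                counts[f"true_{t}|pred_{p}"] = counts.get(f"true_{t}|pred_{p}", 0) + 1
            for key, v in counts.items():
                assert m["confusion"][key] == v
            assert sum(m["confusion"].values()) == n

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cb.evaluate_predictions(["b"], ["b", "h"])


class TestExpressionBaseline:
    @staticmethod
    def _training_data(panel, trajectory, n=600):
        healthy, _ = cb.simulate_healthy(n, trajectory, seed=20)
        blasts, _ = cb.simulate_blasts(n, trajectory,
                                       cb.default_aberration_catalog()[0], seed=21)
        m = cb.concat([healthy, blasts])
        arc = cb.arcsinh_transform(m, panel)
        labels = np.asarray([HEALTHY] * n + [BLAST] * n)
        return arc, labels

    def test_small_latent_variant_exposes_four_units(self, panel, trajectory):
        arc, labels = self._training_data(panel, trajectory)
        base = cb.train_expression_baseline(arc, labels, variant="small_latent", seed=0)
        scaled = cb.apply_minmax(base.scaler, arc)
        acts = base.hidden_activations(scaled)
        assert acts.shape == (arc.n_cells, 4)

    def test_scaler_is_private_not_the_autoencoders(self, panel, trajectory, trained_ae):
        arc, labels = self._training_data(panel, trajectory)
        base = cb.train_expression_baseline(arc, labels, variant="small_latent", seed=0)
        assert base.scaler is not trained_ae.scaler
        assert not np.array_equal(base.scaler.mins, trained_ae.scaler.mins)

    def test_separable_data_high_accuracy(self, panel, trajectory):
        arc, labels = self._training_data(panel, trajectory)
        base = cb.train_expression_baseline(arc, labels, variant="small_latent", seed=0)
        scaled = cb.apply_minmax(base.scaler, arc)
        assert (base.predict(scaled) == labels).mean() > 0.97
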