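"""Marker positivity, diagnosis-to-relapse change accounting, individuality."""

import numpy as np
import pandas as pd
import pytest

import cytoblast as cb


def _arcsinh_matrix(values, channels):
    return cb.CellMatrix(np.asarray(values, dtype=float), list(channels), "arcsinh")


class TestPositiveFraction:
    def test_all_below_threshold(self, panel):
        m = _arcsinh_matrix(np.zeros((5, 23)), panel.channels)
        out = cb.positive_fraction(m, np.ones(5, bool), panel)
        assert (out == 0.0).all()

    def test_strict_threshold(self, panel):
        t = panel.threshold("CD56")
        vals = np.zeros((3, 23))
        j = panel.channels.index("CD56")
        vals[:, j] = [t - 1, t + 1, t + 2]
        m = _arcsinh_matrix(vals, panel.channels)
        out = cb.positive_fraction(m, np.ones(3, bool), panel)
        assert out["CD56"] == pytest.approx(2 / 3)
        # exactly at threshold is NOT positive (strict >)
        vals[:, j] = [t, t, t]
        m = _arcsinh_matrix(vals, panel.channels)
        assert cb.positive_fraction(m, np.ones(3, bool), panel)["CD56"] == 0.0

    def test_mask_restriction_and_order_invariance(self, panel):
        rng = np.random.default_rng(0)
        vals = rng.normal(2, 1, size=(100, 23))
        m = _arcsinh_matrix(vals, panel.channels)
        mask = rng.uniform(size=100) < 0.5
        base = cb.positive_fraction(m, mask, panel)
        perm = rng.permutation(100)
        m2 = _arcsinh_matrix(vals[perm], panel.channels)
        out = cb.positive_fraction(m2, mask[perm], panel)
        pd.testing.assert_series_equal(base, out)
        # adding masked-out cells changes nothing
        m3 = _arcsinh_matrix(np.vstack([vals, np.full((10, 23), 99.0)]), panel.channels)
        out3 = cb.positive_fraction(m3, np.concatenate([mask, np.zeros(10, bool)]), panel)
        pd.testing.assert_series_equal(base, out3)

    def test_empty_mask_rejected(self, panel):
        m = _arcsinh_matrix(np.zeros((3, 23)), panel.channels)
        with pytest.raises(ValueError):
            cb.positive_fraction(m, np.zeros(3, bool), panel)

    def test_planted_cd56_penetrance_recovered(self, panel, trajectory):
        from dataclasses import replace
        spec = replace(cb.default_aberration_catalog()[0], penetrance=0.6)
        n = 4000
        m, _ = cb.simulate_blasts(n, trajectory, spec, seed=9)
        arc = cb.arcsinh_transform(m, panel)
        frac = cb.positive_fraction(arc, np.ones(n, bool), panel)["CD56"]
        assert frac == pytest.approx(0.60, abs=2 / np.sqrt(n))


class TestChangeTable:
    @staticmethod
    def _tables():
        # constructed 3-patient fixture; hand-enumerated flags below
        dx = pd.DataFrame({"CD33": [0.10, 0.50, 0.30], "CD56": [0.10, 0.20, 0.90]},
                          index=["P1", "P2", "P3"])
        rel = pd.DataFrame({"CD33": [0.16, 0.40, 0.30], "CD56": [0.15, 0.80, 0.30]},
                           index=["P1", "P2", "P3"])
        return dx, rel

    def test_hand_enumerated_counts(self):
        dx, rel = self._tables()
        cm = cb.change_table(dx, rel, delta=0.05)
        # CD33: P1 +0.06 gained; P2 -0.10 lost; P3 0 neither
        # CD56: P1 +0.05 exactly -> neither (strict); P2 +0.60 gained; P3 -0.60 lost
        counts = cm.counts()
        assert counts.loc["CD33", "gained"] == 1 and counts.loc["CD33", "lost"] == 1
        assert counts.loc["CD56", "gained"] == 1 and counts.loc["CD56", "lost"] == 1
        assert not cm.gained.loc["P1", "CD56"] and not cm.lost.loc["P1", "CD56"]
        assert cm.delta.loc["P1", "CD33"] == pytest.approx(0.06)

    def test_antisymmetry(self):
        dx, rel = self._tables()
        fwd = cb.change_table(dx, rel)
        rev = cb.change_table(rel, dx)
        pd.testing.assert_frame_equal(fwd.delta, -rev.delta)
        pd.testing.assert_frame_equal(fwd.gained, rev.lost)
        pd.testing.assert_frame_equal(fwd.lost, rev.gained)

    def test_unmatched_patient_excluded_with_warning(self):
        dx, rel = self._tables()
        rel = rel.drop(index="P3")
        with pytest.warns(UserWarning, match="P3"):
            cm = cb.change_table(dx, rel)
        assert set(cm.delta.index) == {"P1", "P2"}


class TestIndividuality:
    def test_hand_computed_posterior(self):
        # one query cell whose 4 nearest neighbors split {A: 3, B: 1} with
        # class sizes 10 and 30: weighted (0.3, 0.0333...), normalized (0.9, 0.1)
        pts = [[0.0]]
        labels = ["A"]
        pts += [[1.0], [1.1], [1.2]]          # 3 close A neighbors
        labels += ["A"] * 3
        pts += [[1.3]]                         # 1 close B neighbor
        labels += ["B"]
        pts += [[50 + i] for i in range(6)]    # distant A cells (size 10 total)
        labels += ["A"] * 6
        pts += [[100 + i] for i in range(29)]  # distant B cells (size 30 total)
        labels += ["B"] * 29
        m = cb.CellMatrix(np.asarray(pts), ["x"], "scaled")
        res = cb.individuality(m, np.asarray(labels), k=4)
        assert res.posterior.loc[0, "A"] == pytest.approx(0.9, abs=1e-12)
        assert res.posterior.loc[0, "B"] == pytest.approx(0.1, abs=1e-12)
        assert res.class_sizes["A"] == 10 and res.class_sizes["B"] == 30

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        m = cb.CellMatrix(rng.normal(size=(200, 3)), ["a", "b", "c"], "scaled")
        labels = rng.choice(["x", "y", "z"], size=200, p=[0.5, 0.3, 0.2])
        res = cb.individuality(m, labels, k=10)
        np.testing.assert_allclose(res.posterior.sum(axis=1), 1.0, atol=1e-12)

    def test_pure_neighborhood_full_posterior(self):
        # equal class sizes, all k neighbors share the cell's class
        x = np.vstack([np.random.default_rng(0).normal(0, 0.01, (20, 2)),
                       np.random.default_rng(1).normal(100, 0.01, (20, 2))])
        labels = np.asarray(["A"] * 20 + ["B"] * 20)
        res = cb.individuality(cb.CellMatrix(x, ["a", "b"], "scaled"), labels, k=5)
        np.testing.assert_allclose(res.posterior.to_numpy()[:20, 0], 1.0)
        np.testing.assert_allclose(res.per_class_mean["mean_own_posterior"], 1.0)

    def test_uniform_neighbors_uniform_posterior(self):
        # AABB-repeating classes on a line: every cell's k=2 neighborhood
        # holds one cell of each class, so the posterior is uniform (1/C)
        x = np.arange(12, dtype=float).reshape(-1, 1)
        labels = np.asarray(["A", "A", "B", "B"] * 3)
        res = cb.individuality(cb.CellMatrix(x, ["x"], "scaled"), labels, k=2)
        np.testing.assert_allclose(res.posterior.to_numpy(), 0.5, atol=1e-12)

    def test_size_correction_duplication_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(60, 2))
        labels = rng.choice(["A", "B"], size=60)
        m1 = cb.CellMatrix(x, ["a", "b"], "scaled")
        res1 = cb.individuality(m1, labels, k=6)
        # duplicate every cell of every class with a tiny offset: class-size
        # weighting keeps per-class mean own-posterior approximately unchanged
        m2 = cb.CellMatrix(np.vstack([x, x + 1e-9]), ["a", "b"], "scaled")
        res2 = cb.individuality(m2, np.concatenate([labels, labels]), k=6)
        a1 = res1.per_class_mean["mean_own_posterior"]
        a2 = res2.per_class_mean["mean_own_posterior"]
        np.testing.assert_allclose(a1.to_numpy(), a2.to_numpy(), atol=0.12)

    def test_shuffled_labels_drop_own_posterior(self):
        rng = np.random.default_rng(5)
        x = np.vstack([rng.normal(0, 0.3, (100, 2)), rng.normal(5, 0.3, (100, 2))])
        labels = np.asarray(["A"] * 100 + ["B"] * 100)
        m = cb.CellMatrix(x, ["a", "b"], "scaled")
        separated = cb.individuality(m, labels, k=10)
        shuffled = cb.individuality(m, rng.permutation(labels), k=10)
        assert (separated.per_class_mean["mean_own_posterior"]
                > shuffled.per_class_mean["mean_own_posterior"]).all()
        # shuffled labels: own-posterior near the size-corrected prior 1/C
        np.testing.assert_allclose(
            shuffled.per_class_mean["mean_own_posterior"], 0.5, atol=0.1)

    def test_literal_variant_constant_denominator(self):
        rng = np.random.default_rng(6)
        m = cb.CellMatrix(rng.normal(size=(50, 2)), ["a", "b"], "scaled")
        labels = np.asarray(["A"] * 20 + ["B"] * 30)
        res = cb.individuality(m, labels, k=4, normalize=False)
        denom = 1 / 20 + 1 / 30
        # rows need not sum to 1; entries are weighted counts / constant
        row = res.posterior.iloc[0]
        assert not np.allclose(res.posterior.sum(axis=1), 1.0)
        assert row.max() <= (4 / 20) / denom + 1e-12

    def test_parameter_validation(self):
        m = cb.CellMatrix(np.zeros((5, 1)) + np.arange(5)[:, None], ["x"], "scaled")
        labels = np.asarray(["A", "A", "A", "B", "B"])
        with pytest.raises(ValueError):
            cb.individuality(m, labels, k=5)
        with pytest.raises(ValueError):
            cb.individuality(m, np.asarray(["A"] * 5), k=2)
        with pytest.warns(UserWarning):
            cb.individuality(m, labels, k=3)
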