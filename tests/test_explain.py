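import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ecgage.explain import (
    AggregatedBeat,
    FeatureAttribution,
    aggregate_group_and_mark,
    beat_align_saliency,
    crop_saliency,
    rank_features_per_group,
    segment_occupancy,
    tree_attributions,
)
from ecgage.features import FEATURE_COLUMNS
from ecgage.models import FeatureAgeClassifier, RawSignalAgeClassifier


def _frame(values, cols):
    X = pd.DataFrame(0.0, index=range(len(values)), columns=FEATURE_COLUMNS)
    for j, c in enumerate(cols):
        X[c] = np.asarray(values)[:, j]
    return X


# ----------------------- brute-force Shapley oracle over fitted xgb trees --

def _tree_conditional_expectation(rows, x, subset):
    """Expected leaf value of one tree given only the features in ``subset``,
    weighting unobserved splits by the training cover of each branch."""
    by_id = {r["ID"]: r for r in rows}

    def rec(node_id):
        r = by_id[node_id]
        if r["Feature"] == "Leaf":
            return r["Gain"]
        if r["Feature"] in subset:
            child = r["Yes"] if x[r["Feature"]] < r["Split"] else r["No"]
            return rec(child)
        cy, cn = by_id[r["Yes"]]["Cover"], by_id[r["No"]]["Cover"]
        return (cy * rec(r["Yes"]) + cn * rec(r["No"])) / (cy + cn)

    root = min(rows, key=lambda r: r["Node"])
    return rec(root["ID"])


def _oracle_shapley(model, x: pd.Series, target_class: int, features):
    booster = model.booster_model_.get_booster()
    df = booster.trees_to_dataframe()
    n_classes = len(model.classes_)
    tree_rows = {
        t: g.to_dict("records")
        for t, g in df.groupby("Tree")
        if t % n_classes == target_class
    }

    def value(subset):
        return sum(
            _tree_conditional_expectation(rows, x, subset)
            for rows in tree_rows.values()
        )

    m = len(features)
    phi = {}
    for f in features:
        others = [g for g in features if g != f]
        total = 0.0
        for k in range(m):
            for subset in itertools.combinations(others, k):
                w = math.factorial(k) * math.factorial(m - k - 1) / math.factorial(m)
                total += w * (value(set(subset) | {f}) - value(set(subset)))
        phi[f] = total
    return phi


class TestTreeAttributions:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(0)
        n = 120
        f1 = rng.integers(0, 2, n).astype(float)
        f2 = rng.integers(0, 2, n).astype(float)
        f3 = rng.standard_normal(n)
        y = (f1 + 2 * f2).astype(int) % 3
        X = _frame(np.column_stack([f1, f2, f3]), ["HRV_SDNN", "SR_p_mV", "breathing_rate"])
        model = FeatureAgeClassifier(
            n_estimators=6, max_depth=2, learning_rate=0.3, balanced=False, seed=0
        ).fit(X, y)
        return model, X

    def test_local_accuracy(self, fitted):
        model, X = fitted
        attr = tree_attributions(model, X)
        margins = model.margins(X)
        recon = attr.base_values + attr.values.sum(axis=2)
        np.testing.assert_allclose(recon, margins, atol=1e-3)

    def test_matches_bruteforce_shapley(self, fitted):
        """TreeSHAP attributions equal exhaustive Shapley values computed by
        enumerating feature subsets over the fitted trees."""
        model, X = fitted
        attr = tree_attributions(model, X)
        used = ["HRV_SDNN", "SR_p_mV", "breathing_rate"]
        idx = [attr.feature_names.index(f) for f in used]
        for i in [0, 5, 17]:
            for cls in range(3):
                phi = _oracle_shapley(model, X.iloc[i], cls, used)
                for f, j in zip(used, idx):
                    assert attr.values[i, cls, j] == pytest.approx(phi[f], abs=1e-4)

    def test_unused_features_have_zero_attribution(self, fitted):
        model, X = fitted
        attr = tree_attributions(model, X)
        j = attr.feature_names.index("HRV_LF")  # constant zero column
        assert np.abs(attr.values[:, :, j]).max() < 1e-12


class TestRanking:
    def test_single_signal_feature_ranked_first(self):
        rng = np.random.default_rng(1)
        n = 300
        y = rng.integers(0, 5, n)
        X = _frame(
            np.column_stack([y + 0.1 * rng.standard_normal(n), rng.standard_normal(n)]),
            ["SR_p_mV", "HRV_SDNN"],
        )
        model = FeatureAgeClassifier(n_estimators=80, balanced=False, seed=0).fit(X, y)
        attr = tree_attributions(model, X)
        ranking = rank_features_per_group(attr, X, k=3)
        firsts = ranking[ranking["rank"] == 0]
        assert (firsts["feature"] == "SR_p_mV").mean() >= 0.8

    def test_direction_tracks_feature_value(self):
        rng = np.random.default_rng(2)
        n = 400
        y = rng.integers(0, 2, n)
        X = _frame(
            np.column_stack([y * 2.0 + 0.1 * rng.standard_normal(n)]), ["breathing_rate"]
        )
        model = FeatureAgeClassifier(n_estimators=50, balanced=False, seed=0).fit(X, y)
        ranking = rank_features_per_group(tree_attributions(model, X), X, k=1)
        by_group = ranking.set_index("age_group")
        # high feature value pushes toward class 1, away from class 0
        assert by_group.loc[1, "direction"] == 1.0
        assert by_group.loc[0, "direction"] == -1.0

    def test_zero_attributions_flagged(self):
        attr = FeatureAttribution(
            values=np.zeros((4, 2, 3)),
            base_values=np.zeros((4, 2)),
            feature_names=["a", "b", "c"],
            classes=np.array([0, 1]),
        )
        X = pd.DataFrame(np.zeros((4, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            rank_features_per_group(attr, X)


class TestSaliency:
    def test_saliency_is_absolute_input_gradient(self):
        """|gradient| from the network's backward pass matches central finite
        differences of the target-class pre-softmax score."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((8, 60))
        y = np.array([0, 1] * 4)
        m = RawSignalAgeClassifier(epochs=1, width=4, n_blocks=1, seed=0).fit(X, y)
        crop = X[0]
        sal = crop_saliency(m, crop, 1)
        eps = 1e-5
        for t in [5, 20, 41]:
            cp, cm = crop.copy(), crop.copy()
            cp[t] += eps
            cm[t] -= eps

            def score(c):
                return m.net_.forward(c[None, None, :])[0, list(m.classes_).index(1)]

            num = abs((score(cp) - score(cm)) / (2 * eps))
            assert sal[t] == pytest.approx(num, rel=1e-4, abs=1e-7)

    def test_shape_contract(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((4, 80))
        m = RawSignalAgeClassifier(epochs=1, width=4, n_blocks=1, seed=0).fit(
            X, np.array([0, 1, 0, 1])
        )
        assert crop_saliency(m, X[0], 0).shape == (80,)
        assert crop_saliency(m, X, 0).shape == (4, 80)


class TestBeatAlignment:
    def test_identical_beats_average_to_single_beat(self):
        fs = 100.0
        beat = np.sin(np.linspace(0, 3, 80))
        crop = np.zeros(300)
        sal = np.zeros(300)
        rpeaks = [100, 200]
        for r in rpeaks:
            crop[r - 30 : r + 50] = beat
            sal[r - 30 : r + 50] = beat**2
        mean_beat, mean_sal, n = beat_align_saliency(
            [crop], [sal], [np.array(rpeaks)], fs, 300.0, 500.0
        )
        assert n == 2
        np.testing.assert_allclose(mean_beat, beat)
        np.testing.assert_allclose(mean_sal, beat**2)

    def test_window_and_boundary_rule(self):
        fs = 100.0
        crop = np.arange(300, dtype=float)
        sal = np.ones(300)
        mean_beat, mean_sal, n = beat_align_saliency(
            [crop], [sal], [np.array([1, 150])], fs, 300.0, 500.0
        )
        # R at sample 1 is skipped (window exceeds bounds); R at 150 fits
        assert n == 1
        np.testing.assert_array_equal(mean_beat, crop[120:200])

    def test_aligned_spikes_do_not_smear(self):
        fs = 100.0
        crops, sals, rps = [], [], []
        for r in (100, 180):
            crop = np.zeros(300)
            sal = np.zeros(300)
            sal[r + 1] = 1.0  # spike at R + 10 ms
            crops.append(crop)
            sals.append(sal)
            rps.append(np.array([r]))
        _, mean_sal, n = beat_align_saliency(crops, sals, rps, fs, 300.0, 500.0)
        assert n == 2
        assert mean_sal[31] == pytest.approx(1.0)
        assert mean_sal.sum() == pytest.approx(1.0)


class TestAggregation:
    def _subject(self, sal, beat=None, n_beats=3):
        L = len(sal)
        return (np.zeros(L) if beat is None else beat, np.asarray(sal, float), n_beats)

    def test_single_subject_identity(self):
        sal = np.arange(10.0)
        out = aggregate_group_and_mark({"s1": self._subject(sal)}, {"s1": 2}, k=3)
        np.testing.assert_array_equal(out[2].saliency, sal)
        assert out[2].n_subjects == 1 and out[2].n_heartbeats == 3

    def test_marked_count_is_k(self):
        rng = np.random.default_rng(5)
        subjects = {f"s{i}": self._subject(rng.random(40)) for i in range(4)}
        labels = {f"s{i}": i % 2 for i in range(4)}
        out = aggregate_group_and_mark(subjects, labels, k=8)
        assert all(len(agg.marked) == 8 for agg in out.values())

    def test_ramp_marks_last_indices(self):
        out = aggregate_group_and_mark(
            {"s1": self._subject(np.arange(20.0))}, {"s1": 0}, k=8
        )
        np.testing.assert_array_equal(out[0].marked, np.arange(12, 20))

    def test_ties_break_toward_earlier_index(self):
        out = aggregate_group_and_mark(
            {"s1": self._subject(np.ones(20))}, {"s1": 0}, k=8
        )
        np.testing.assert_array_equal(out[0].marked, np.arange(8))

    def test_permutation_invariance_over_subjects(self):
        rng = np.random.default_rng(6)
        sals = {f"s{i}": self._subject(rng.random(30)) for i in range(5)}
        labels = {k: 0 for k in sals}
        a = aggregate_group_and_mark(dict(sals), labels, k=5)
        b = aggregate_group_and_mark(dict(reversed(list(sals.items()))), labels, k=5)
        np.testing.assert_allclose(a[0].saliency, b[0].saliency)
        np.testing.assert_array_equal(a[0].marked, b[0].marked)

    def test_subject_with_no_beats_skipped_with_warning(self):
        subjects = {"s1": (None, None, 0), "s2": self._subject(np.ones(10))}
        with pytest.warns(UserWarning):
            out = aggregate_group_and_mark(subjects, {"s1": 0, "s2": 0}, k=2)
        assert out[0].n_subjects == 1


class TestOccupancy:
    FID = {
        "P_onset": 10.0, "P_peak": 14.0, "P_offset": 18.0,
        "Q": 27.0, "R": 30.0, "S": 33.0,
        "T_onset": 45.0, "T_peak": 52.0, "T_offset": 58.0,
    }

    def _agg(self, group, marked):
        return AggregatedBeat(
            age_group=group, waveform=np.zeros(80), saliency=np.zeros(80),
            n_subjects=1, n_heartbeats=1, marked=np.asarray(marked),
        )

    def test_all_marks_in_p_offset_interval(self):
        agg = {0: self._agg(0, [15, 16, 17, 18])}
        occ = segment_occupancy(agg, {0: self.FID}, fs=100.0)
        assert occ.percentages["P_offset"] == 100.0
        assert sum(occ.percentages.values()) + occ.unassigned_pct == pytest.approx(100.0)

    def test_pooled_denominator_across_groups(self):
        # 15 groups x 8 marks; 15 of the 120 marks land in TP (sample 70)
        agg = {}
        for g in range(15):
            marks = [15] * 7 + [70] if g < 15 else []
            agg[g] = self._agg(g, marks)
        occ = segment_occupancy(agg, {g: self.FID for g in range(15)}, fs=100.0)
        assert occ.n_marks == 120
        assert occ.percentages["TP"] == pytest.approx(100.0 * 15 / 120)

    def test_partition_sums_to_100(self):
        rng = np.random.default_rng(7)
        agg = {g: self._agg(g, rng.integers(0, 80, 8)) for g in range(4)}
        occ = segment_occupancy(agg, {g: self.FID for g in range(4)}, fs=100.0)
        assert sum(occ.percentages.values()) + occ.unassigned_pct == pytest.approx(100.0)

    def test_missing_fiducials_count_unassigned(self):
        fid = {k: np.nan for k in self.FID}
        occ = segment_occupancy({0: self._agg(0, [5, 50])}, {0: fid}, fs=100.0)
        assert occ.unassigned_pct == 100.0
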