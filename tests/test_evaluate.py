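"""Clinimetric statistics: oracles, fold integrity, correlations, baselines."""

import numpy as np
import pandas as pd
import pytest

from wristmotor.evaluate import (ConfusionMatrix3, activity_stratified,
                                 clinimetrics, committee_vote, grouped_folds,
                                 icc_2_1, loso_folds, run_baselines,
                                 temporal_correlations)
from wristmotor.postprocess import ExpCNNSeries
from wristmotor.preprocess import WindowedDataset
from wristmotor.simulate import AnnotationTrack, ConfigError
from conftest import make_band_dataset


# ---------------------------------------------------------------------------
# oracle: metrics recomputed by direct enumeration over label pairs
# ---------------------------------------------------------------------------

def pairwise_metrics_oracle(ref, pred):
    """Brute-force 1-vs-all metrics and kappa from raw label pairs."""
    ref, pred = np.asarray(ref), np.asarray(pred)
    n = ref.size
    out = {"accuracy": np.mean(ref == pred), "per_class": {}}
    recalls = []
    for c in range(3):
        tp = np.sum((ref == c) & (pred == c))
        fn = np.sum((ref == c) & (pred != c))
        fp = np.sum((ref != c) & (pred == c))
        tn = np.sum((ref != c) & (pred != c))
        div = lambda a, b: a / b if b > 0 else float("nan")
        out["per_class"][c] = {
            "sensitivity": div(tp, tp + fn), "specificity": div(tn, tn + fp),
            "ppv": div(tp, tp + fp), "npv": div(tn, tn + fn),
        }
        if (ref == c).any():
            recalls.append(tp / (tp + fn))
    out["balanced_accuracy"] = float(np.mean(recalls))
    po = np.mean(ref == pred)
    pe = sum(np.mean(ref == c) * np.mean(pred == c) for c in range(3))
    out["kappa"] = (po - pe) / (1 - pe) if pe < 1 else float("nan")
    return out


def anova_icc_oracle(data):
    """ICC(2,1) via explicit two-way ANOVA variance components."""
    data = np.asarray(data, float)
    n, k = data.shape
    ms_r = k * np.sum((data.mean(1) - data.mean()) ** 2) / (n - 1)
    ms_c = n * np.sum((data.mean(0) - data.mean()) ** 2) / (k - 1)
    ms_e = (np.sum((data - data.mean(1)[:, None] - data.mean(0)[None, :]
                    + data.mean()) ** 2) / ((n - 1) * (k - 1)))
    var_r = (ms_r - ms_e) / k
    var_c = (ms_c - ms_e) / n
    return var_r / (var_r + var_c + ms_e)


class TestFolds:
    def test_loso_three_subjects(self):
        folds = loso_folds(["a", "b", "c"])
        assert len(folds) == 3
        assert all(len(tr) == 2 for tr, _ in folds)

    def test_loso_partitions_exactly(self):
        ids = [f"S{i}" for i in range(7)]
        folds = loso_folds(ids)
        tests = [te for _, te in folds]
        assert sorted(tests) == sorted(ids)
        for tr, te in folds:
            assert te not in tr and sorted(tr + [te]) == sorted(ids)

    def test_grouped_sizes_differ_by_at_most_one(self):
        for n, expected in [(8, {2}), (30, {7, 8})]:
            folds = grouped_folds([f"S{i}" for i in range(n)], k=4,
                                  rng=np.random.default_rng(0))
            sizes = {len(te) for _, te in folds}
            assert sizes == expected
            all_test = sorted(s for _, te in folds for s in te)
            assert all_test == sorted(f"S{i}" for i in range(n))

    def test_grouped_seeded_reproducible(self):
        ids = [f"S{i}" for i in range(9)]
        a = grouped_folds(ids, 4, np.random.default_rng(5))
        b = grouped_folds(ids, 4, np.random.default_rng(5))
        assert a == b


class TestClinimetrics:
    def test_diagonal_matrix_perfect(self):
        m = clinimetrics(ConfusionMatrix3(np.diag([10, 20, 30])))
        assert m["kappa"] == pytest.approx(1.0)
        for cls in ("OFF", "ON", "DYS"):
            assert m["per_class"][cls]["sensitivity"] == 1.0
            assert m["per_class"][cls]["specificity"] == 1.0

    def test_single_column_on_balanced_reference(self):
        cm = ConfusionMatrix3(np.array([[10, 0, 0], [10, 0, 0], [10, 0, 0]]).T * 0
                              + np.array([[10, 0, 0], [10, 0, 0], [10, 0, 0]]))
        m = clinimetrics(cm)
        assert m["balanced_accuracy"] == pytest.approx(1 / 3)
        assert m["kappa"] == pytest.approx(0.0)

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            clinimetrics(ConfusionMatrix3())

    def test_zero_denominator_reported_missing(self):
        cm = ConfusionMatrix3(np.array([[5, 0, 0], [5, 0, 0], [0, 0, 0]]))
        m = clinimetrics(cm)
        assert np.isnan(m["per_class"]["DYS"]["sensitivity"])
        assert np.isnan(m["per_class"]["ON"]["ppv"])

    def test_fifty_random_matrices_match_pairwise_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            ref = rng.integers(0, 3, 200)
            pred = rng.integers(0, 3, 200)
            m = clinimetrics(ConfusionMatrix3.from_labels(ref, pred))
            o = pairwise_metrics_oracle(ref, pred)
            assert m["kappa"] == pytest.approx(o["kappa"], abs=1e-12)
            assert m["balanced_accuracy"] == pytest.approx(o["balanced_accuracy"], abs=1e-12)
            for c, cls in enumerate(("OFF", "ON", "DYS")):
                for key in ("sensitivity", "specificity", "ppv", "npv"):
                    a, b = m["per_class"][cls][key], o["per_class"][c][key]
                    assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b, abs=1e-12)

    def test_kappa_agrees_with_sklearn(self):
        from sklearn.metrics import cohen_kappa_score, balanced_accuracy_score
        rng = np.random.default_rng(3)
        ref = rng.integers(0, 3, 500)
        pred = np.where(rng.random(500) < 0.6, ref, rng.integers(0, 3, 500))
        m = clinimetrics(ConfusionMatrix3.from_labels(ref, pred))
        assert m["kappa"] == pytest.approx(cohen_kappa_score(ref, pred), abs=1e-12)
        assert m["balanced_accuracy"] == pytest.approx(
            balanced_accuracy_score(ref, pred), abs=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        ref = rng.integers(0, 3, 300)
        pred = rng.integers(0, 3, 300)
        perm = np.array([2, 0, 1])
        m1 = clinimetrics(ConfusionMatrix3.from_labels(ref, pred))
        m2 = clinimetrics(ConfusionMatrix3.from_labels(perm[ref], perm[pred]))
        assert m1["kappa"] == pytest.approx(m2["kappa"], abs=1e-12)
        assert m1["balanced_accuracy"] == pytest.approx(m2["balanced_accuracy"], abs=1e-12)
        names = ("OFF", "ON", "DYS")
        for c in range(3):
            assert m1["per_class"][names[c]]["sensitivity"] == pytest.approx(
                m2["per_class"][names[perm[c]]]["sensitivity"], abs=1e-12)

    def test_diagonal_dominance_beats_row_permutations(self):
        from itertools import permutations
        cm = np.array([[30, 5, 5], [4, 40, 6], [3, 7, 35]])
        base = clinimetrics(ConfusionMatrix3(cm))["balanced_accuracy"]
        for perm in permutations(range(3)):
            if perm == (0, 1, 2):
                continue
            permuted = clinimetrics(ConfusionMatrix3(cm[list(perm)]))["balanced_accuracy"]
            assert base > permuted


class TestCommitteeAndICC:
    @pytest.mark.parametrize("ratings,expected", [
        ((0, 0, 1), 0), ((2, 2, 2), 2), ((0, 1, 2), 1), ((1, 2, 2), 2),
    ])
    def test_committee_vote(self, ratings, expected):
        assert committee_vote(ratings) == expected

    def test_identical_columns_icc_1(self):
        x = np.arange(10.0)
        res = icc_2_1(np.column_stack([x, x]))
        assert res["icc"] == pytest.approx(1.0)

    def test_constant_shift_penalized(self):
        x = np.arange(10.0)
        res = icc_2_1(np.column_stack([x, x + 2.0]))
        assert res["icc"] < 1.0

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            icc_2_1([(1.0, 1.0)])

    def test_thirty_seeded_pairs_match_anova_oracle(self):
        rng = np.random.default_rng(30)
        truth = rng.integers(0, 3, 30).astype(float)
        data = np.column_stack([
            np.clip(truth + rng.normal(0, 0.4, 30), 0, 2),
            np.clip(truth + rng.normal(0, 0.4, 30), 0, 2)])
        res = icc_2_1(data)
        assert res["icc"] == pytest.approx(anova_icc_oracle(data), abs=1e-12)

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(14)
        truth = rng.integers(0, 3, 30).astype(float)
        data = np.column_stack([
            np.clip(truth + rng.normal(0, 0.3, 30), 0, 2),
            np.clip(truth + rng.normal(0, 0.3, 30), 0, 2)])
        res = icc_2_1(data)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(30), 2),
            "raters": np.tile(["A", "B"], 30),
            "score": data.ravel()})
        table = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                         ratings="score").set_index("Type")
        ref = table.loc["ICC(A,1)"] if "ICC(A,1)" in table.index else table.loc["ICC2"]
        ci_col = "CI95" if "CI95" in ref.index else "CI95%"
        assert res["icc"] == pytest.approx(ref["ICC"], abs=1e-9)
        assert res["F"] == pytest.approx(ref["F"], abs=1e-9)
        assert res["ci_low"] == pytest.approx(ref[ci_col][0], abs=0.01)
        assert res["ci_high"] == pytest.approx(ref[ci_col][1], abs=0.01)


def _series_from_states(sid, states, rng, noise_sd=0.5):
    e = np.clip(states.astype(float) + rng.normal(0, noise_sd, states.size), 0, 2)
    return ExpCNNSeries(sid, np.arange(states.size) * 60.0, e)


def _track_from_states(sid, states):
    brady = np.where(states == 0, 3, np.where(states == 1, 1, 0))
    dys = np.where(states == 2, 2, 0)
    return AnnotationTrack(sid, np.arange(states.size), states, brady, dys,
                           ["sitting"] * states.size)


class TestTemporalCorrelations:
    def test_exactly_linear_items_give_r_1(self):
        """Items built as exact linear maps of the clipped score -> Pearson r = 1."""
        rng = np.random.default_rng(0)
        series, tracks = {}, []
        for i in range(6):
            states = rng.integers(0, 3, 120)
            series[f"S{i}"] = _series_from_states(f"S{i}", states, rng, noise_sd=0.0)
            brady = 2 * (states == 0).astype(int)      # = 2*(1 - clip(e,0,1))
            dys = 2 * (states == 2).astype(int)        # = 2*(clip(e,1,2) - 1)
            tracks.append(AnnotationTrack(f"S{i}", np.arange(120), states,
                                          brady, dys, ["sitting"] * 120))
        rep = temporal_correlations(series, tracks)
        for w in ("1", "5", "daily"):
            assert abs(rep[w]["brady"]["r"]) == pytest.approx(1.0, abs=1e-9)
            assert abs(rep[w]["dys"]["r"]) == pytest.approx(1.0, abs=1e-9)
            assert rep[w]["brady"]["r"] > 0 and rep[w]["dys"]["r"] > 0

    def test_constant_predictions_give_missing_r(self):
        states = np.zeros(50, dtype=int)
        series = {"S0": _series_from_states("S0", states,
                                            np.random.default_rng(0), 0.0)}
        rep = temporal_correlations(series, [_track_from_states("S0", states)])
        assert np.isnan(rep["1"]["brady"]["r"])

    def test_aggregation_improves_correlation_under_iid_noise(self):
        """Averaging minute-level iid noise raises r monotonically to daily.

        Subjects get heterogeneous state mixes (Dirichlet propensities) so
        between-subject differences persist under aggregation while the iid
        prediction noise averages away.
        """
        rng = np.random.default_rng(123)
        series, tracks = {}, []
        for i in range(20):
            probs = rng.dirichlet([1.0, 1.0, 1.0])
            states = rng.choice(3, size=300, p=probs)
            series[f"S{i}"] = _series_from_states(f"S{i}", states, rng, noise_sd=1.0)
            tracks.append(_track_from_states(f"S{i}", states))
        rep = temporal_correlations(series, tracks)
        for item in ("brady", "dys"):
            rs = [rep[w][item]["r"] for w in ("1", "5", "30", "60", "daily")]
            assert all(np.isfinite(rs))
            assert all(a < b for a, b in zip(rs[:-1], rs[1:]))


class TestActivityTable:
    def test_single_activity_prevalence_100(self):
        cm = ConfusionMatrix3(np.diag([5, 5, 5]))
        table = activity_stratified({"sitting": cm})
        assert table.loc[0, "prevalence_pct"] == 100.0

    def test_prevalences_sum_to_100_and_match_clinimetrics(self):
        rng = np.random.default_rng(4)
        cms = {}
        for act in ("sitting", "walking", "lying"):
            ref, pred = rng.integers(0, 3, 60), rng.integers(0, 3, 60)
            cms[act] = ConfusionMatrix3.from_labels(ref, pred)
        table = activity_stratified(cms).set_index("activity")
        assert table["prevalence_pct"].sum() == pytest.approx(100.0)
        for act, cm in cms.items():
            assert table.loc[act, "balanced_accuracy"] == pytest.approx(
                clinimetrics(cm)["balanced_accuracy"])


def make_offset_dataset(n_subjects, minutes, seed):
    """Classes coded by a mean offset on their own axis (orthogonal
    prototypes): separable for every raw-input method."""
    from wristmotor.preprocess import MinuteWindow
    rng = np.random.default_rng(seed)
    wins = []
    for s in range(n_subjects):
        for i in range(minutes):
            cls = i % 3
            v = rng.normal(0, 0.05, (3600, 3)).astype(np.float32)
            v[:, cls] += 0.5
            wins.append(MinuteWindow(f"S{s}", 60.0 * i, v, float(cls), "sitting"))
    return wins


class TestBaselines:
    def test_separable_fixture_all_methods_high(self):
        ds = WindowedDataset(make_offset_dataset(8, 12, seed=2))
        folds = grouped_folds(ds.subjects(), 4, np.random.default_rng(0))
        table = run_baselines(ds, folds, seed=0).set_index("method")
        for method in ("SVM (linear)", "kNN (n=10)", "Random Forest", "MLP"):
            assert table.loc[method, "balanced_accuracy"] >= 0.9

    def test_table_has_exactly_five_rows(self):
        wins = make_band_dataset(4, 6, seed=3)
        ds = WindowedDataset(wins)
        folds = grouped_folds(ds.subjects(), 2, np.random.default_rng(0))
        table = run_baselines(ds, folds, seed=0, cnn_balanced_accuracy=0.9)
        assert list(table["method"]) == ["SVM (linear)", "kNN (n=10)",
                                         "Random Forest", "MLP", "CNN"]
        assert table.set_index("method").loc["CNN", "balanced_accuracy"] == 0.9
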