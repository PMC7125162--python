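"""LOSO orchestration and clinimetric statistics.

Evaluation mirrors a clinical validation protocol: leave-one-subject-out
(LOSO) cross-validation — each subject is the entire test set of one fold,
so performance reflects generalization to unseen patients — with a
one-vs-all metric battery per class (sensitivity, specificity, PPV, NPV,
balanced accuracy), three-class balanced accuracy (macro recall), Cohen's
kappa, Pearson correlations of window-aggregated expCNN with the rater's
bradykinesia/dyskinesia items at several temporal resolutions, a per-activity
stratification, classical-ML baselines on raw windows with grouped 4-fold
CV, and rater-reliability statistics (committee mode vote, ICC(2,1)).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .augment import augment_training_set
from .model import CNNConfig, EnsembleModel, predict, train_ensemble
from .postprocess import ExpCNNSeries, build_series, subject_summary
from .preprocess import FilterSpec, WindowedDataset, preprocess_recording, VARIANCE_THRESHOLD_G2
from .simulate import AnnotationTrack, RawRecording, ConfigError

__all__ = [
    "ConfusionMatrix3", "MetricsReport",
    "loso_folds", "grouped_folds", "clinimetrics",
    "temporal_correlations", "activity_stratified",
    "committee_vote", "icc_2_1",
    "run_baselines", "ExperimentConfig", "run_loso_experiment",
]

CLASS_NAMES = ("OFF", "ON", "DYS")
WINDOW_SIZES_MIN = (1, 5, 30, 60, "daily")


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def loso_folds(subject_ids: Sequence[str]) -> list[tuple[list[str], str]]:
    """One fold per subject; the subject is the entire test set."""
    ids = sorted(set(subject_ids))
    return [([s for s in ids if s != test], test) for test in ids]


def grouped_folds(subject_ids: Sequence[str], k: int = 4,
                  rng: Optional[np.random.Generator] = None
                  ) -> list[tuple[list[str], list[str]]]:
    """k folds over similar-sized patient groups (sizes differ by <= 1)."""
    ids = sorted(set(subject_ids))
    if k < 2 or k > len(ids):
        raise ConfigError(f"k must be in [2, {len(ids)}]")
    rng = rng if rng is not None else np.random.default_rng(0)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    groups = [sorted(g.tolist()) for g in np.array_split(np.array(perm, dtype=object), k)]
    return [(sorted(set(ids) - set(g)), g) for g in groups]


# ---------------------------------------------------------------------------
# confusion matrix and the metric battery
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix3:
    """3x3 counts; rows = reference (rater), columns = prediction."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros((3, 3), dtype=np.int64))

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3) or np.any(self.counts < 0):
            raise ValueError("confusion matrix must be 3x3 non-negative counts")

    @classmethod
    def from_labels(cls, reference: Sequence[int], prediction: Sequence[int]) -> "ConfusionMatrix3":
        cm = np.zeros((3, 3), dtype=np.int64)
        for r, p in zip(reference, prediction, strict=True):
            cm[int(r), int(p)] += 1
        return cls(cm)

    def __add__(self, other: "ConfusionMatrix3") -> "ConfusionMatrix3":
        return ConfusionMatrix3(self.counts + other.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _safe_div(a: float, b: float) -> float:
    return float(a) / float(b) if b > 0 else float("nan")


def clinimetrics(cm: ConfusionMatrix3) -> dict:
    """One-vs-all metric battery from a 3x3 confusion matrix.

    Zero-denominator rates are reported as NaN (missing), never as 0.
    Balanced (3-class) accuracy is the macro average of per-class recall over
    classes present in the reference.
    """
    c = cm.counts.astype(float)
    n = c.sum()
    if n == 0:
        raise ValueError("empty confusion matrix: metrics undefined")
    rows, cols = c.sum(axis=1), c.sum(axis=0)
    per_class = {}
    recalls = []
    for i, name in enumerate(CLASS_NAMES):
        tp = c[i, i]
        fn = rows[i] - tp
        fp = cols[i] - tp
        tn = n - rows[i] - cols[i] + tp
        sens = _safe_div(tp, tp + fn)
        spec = _safe_div(tn, tn + fp)
        per_class[name] = {
            "sensitivity": sens,
            "specificity": spec,
            "ppv": _safe_div(tp, tp + fp),
            "npv": _safe_div(tn, tn + fn),
            "balanced_accuracy": (sens + spec) / 2.0,
            "detection_prevalence": _safe_div(cols[i], n),
            "true_prevalence": _safe_div(rows[i], n),
        }
        if rows[i] > 0:
            recalls.append(sens)
    po = np.trace(c) / n
    pe = float((rows / n) @ (cols / n))
    kappa = _safe_div(po - pe, 1.0 - pe) if pe < 1.0 else float("nan")
    return {
        "n": int(n),
        "accuracy": float(po),
        "balanced_accuracy": float(np.mean(recalls)) if recalls else float("nan"),
        "kappa": kappa,
        "per_class": per_class,
    }


# ---------------------------------------------------------------------------
# temporal correlations (criterion validity)
# ---------------------------------------------------------------------------

def _pearson_with_ci(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> dict:
    n = x.size
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return {"r": float("nan"), "p": float("nan"),
                "ci_low": float("nan"), "ci_high": float("nan"), "n": int(n)}
    r, p = stats.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3) if n > 3 else np.inf
    zc = stats.norm.ppf(1 - alpha / 2)
    return {"r": float(r), "p": float(p),
            "ci_low": float(np.tanh(z - zc * se)),
            "ci_high": float(np.tanh(z + zc * se)), "n": int(n)}


def temporal_correlations(series_by_subject: dict[str, ExpCNNSeries],
                          tracks: Sequence[AnnotationTrack],
                          window_sizes=WINDOW_SIZES_MIN) -> dict:
    """Correlate window-aggregated expCNN with rater items at several scales.

    The ordinal score is mapped to the two item directions before
    aggregation: brady_pred = 1 - clip(expCNN, 0, 1) (OFF end of the scale)
    and dys_pred = clip(expCNN, 1, 2) - 1 (DYS end).  Per window size, means
    are taken within windows (per subject; "daily" = the whole recording)
    and pooled across subjects for the Pearson correlation.  Minutes without
    an annotation are excluded.
    """
    tr_by_id = {t.subject_id: t for t in tracks}
    out = {}
    for w in window_sizes:
        bx, by, dx, dy = [], [], [], []
        for sid, series in series_by_subject.items():
            track = tr_by_id.get(sid)
            if track is None:
                continue
            minutes = np.rint(series.start_s / 60.0).astype(int)
            annotated = {int(m): j for j, m in enumerate(track.minute_index)
                         if track.motor_state[j] >= 0}
            keep = np.array([m in annotated for m in minutes])
            if not keep.any():
                continue
            mins = minutes[keep]
            e = series.expcnn[keep]
            brady_pred = 1.0 - np.clip(e, 0.0, 1.0)
            dys_pred = np.clip(e, 1.0, 2.0) - 1.0
            bi = np.array([track.brady_item[annotated[m]] for m in mins], dtype=float)
            di = np.array([track.dys_item[annotated[m]] for m in mins], dtype=float)
            group = np.zeros_like(mins) if w == "daily" else mins // int(w)
            for g in np.unique(group):
                sel = group == g
                bx.append(brady_pred[sel].mean())
                by.append(bi[sel].mean())
                dx.append(dys_pred[sel].mean())
                dy.append(di[sel].mean())
        out[str(w)] = {
            "brady": _pearson_with_ci(np.array(bx), np.array(by)),
            "dys": _pearson_with_ci(np.array(dx), np.array(dy)),
        }
    return out


# ---------------------------------------------------------------------------
# activity stratification
# ---------------------------------------------------------------------------

def activity_stratified(cm_by_activity: dict[str, ConfusionMatrix3]) -> pd.DataFrame:
    """Prevalence (% of scored minutes) and balanced accuracy per activity."""
    total = sum(cm.total for cm in cm_by_activity.values())
    rows = []
    for act, cm in sorted(cm_by_activity.items()):
        if cm.total == 0:
            rows.append({"activity": act, "prevalence_pct": 0.0,
                         "balanced_accuracy": float("nan"), "n": 0})
            continue
        m = clinimetrics(cm)
        rows.append({"activity": act,
                     "prevalence_pct": 100.0 * cm.total / total if total else float("nan"),
                     "balanced_accuracy": m["balanced_accuracy"], "n": cm.total})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rater reliability
# ---------------------------------------------------------------------------

def committee_vote(ratings: Sequence[int]) -> int:
    """Modal rating of the specialist committee; a three-way tie -> median."""
    vals = [int(r) for r in ratings]
    counts = {v: vals.count(v) for v in set(vals)}
    best = max(counts.values())
    modes = [v for v, c in counts.items() if c == best]
    if len(modes) == 1:
        return modes[0]
    return int(statistics.median(vals))


def icc_2_1(pairs: Sequence[tuple[float, float]], alpha: float = 0.05) -> dict:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``pairs`` are (rating_A, rating_B) per item, e.g. committee vote vs the
    expert.  Returns the ICC, the F statistic with its p-value, and the
    standard F-based 95% confidence interval.
    """
    data = np.asarray(pairs, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2 or data.shape[0] < 2:
        raise ValueError("need at least 2 items rated by at least 2 raters")
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    F = msr / mse if mse > 0 else float("inf")
    p = float(stats.f.sf(F, n - 1, (n - 1) * (k - 1))) if np.isfinite(F) else 0.0
    # Satterthwaite df for the CI (standard two-way absolute-agreement formula)
    fj = msc / mse if mse > 0 else float("inf")
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else float("inf")
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else float("inf")
    if np.isfinite(a) and np.isfinite(fj):
        v = ((a * fj + b) ** 2) / ((a ** 2 * fj ** 2) / (k - 1)
                                   + b ** 2 / ((n - 1) * (k - 1)))
        f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = (n * (msr - f_low * mse)
                 / (f_low * (k * msc + (k * n - k - n) * mse) + n * msr))
        upper = (n * (f_up * msr - mse)
                 / (k * msc + (k * n - k - n) * mse + n * f_up * msr))
    else:
        lower = upper = float("nan")
    return {"icc": float(icc), "F": float(F), "p": p,
            "ci_low": float(lower), "ci_high": float(upper), "n": n, "k": k}


# ---------------------------------------------------------------------------
# classical-ML baselines on raw windows
# ---------------------------------------------------------------------------

def run_baselines(dataset: WindowedDataset, folds: Sequence[tuple[list[str], list[str]]],
                  seed: int = 0, cnn_balanced_accuracy: Optional[float] = None,
                  max_windows_per_subject: Optional[int] = None) -> pd.DataFrame:
    """Balanced accuracy of SVM / kNN(10) / random forest / MLP on raw windows.

    Each classifier consumes the flattened 10,800-value window with no
    feature extraction; scoring uses non-augmented, integer-labeled windows
    pooled over the given grouped folds.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    wins = [w for w in dataset.windows
            if w.origin == "original" and w.label is not None
            and float(w.label).is_integer()]
    if max_windows_per_subject is not None:
        rng = np.random.default_rng(seed)
        by_subj: dict[str, list] = {}
        for w in wins:
            by_subj.setdefault(w.subject_id, []).append(w)
        wins = [w for ws in by_subj.values()
                for w in (ws if len(ws) <= max_windows_per_subject else
                          [ws[i] for i in sorted(rng.choice(len(ws), max_windows_per_subject,
                                                            replace=False))])]
    X = np.stack([w.values.reshape(-1) for w in wins])
    y = np.array([int(w.label) for w in wins])
    sids = np.array([w.subject_id for w in wins])

    def make_models():
        # scale-sensitive models get a standardizer; still raw samples, no features
        return {
            "SVM (linear)": make_pipeline(StandardScaler(),
                                          SVC(kernel="linear", random_state=seed)),
            "kNN (n=10)": KNeighborsClassifier(n_neighbors=10),
            "Random Forest": RandomForestClassifier(n_estimators=100, random_state=seed),
            "MLP": make_pipeline(StandardScaler(),
                                 MLPClassifier(hidden_layer_sizes=(100,), max_iter=300,
                                               random_state=seed)),
        }

    cms = {name: ConfusionMatrix3() for name in make_models()}
    for train_ids, test_ids in folds:
        tr = np.isin(sids, list(train_ids))
        te = np.isin(sids, list(test_ids))
        if not tr.any() or not te.any():
            continue
        for name, clf in make_models().items():
            clf.fit(X[tr], y[tr])
            cms[name] += ConfusionMatrix3.from_labels(y[te], clf.predict(X[te]))
    rows = [{"method": name,
             "balanced_accuracy": clinimetrics(cm)["balanced_accuracy"] if cm.total else float("nan")}
            for name, cm in cms.items()]
    rows.append({"method": "CNN",
                 "balanced_accuracy": float("nan") if cnn_balanced_accuracy is None
                 else float(cnn_balanced_accuracy)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end LOSO experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Everything a LOSO run needs; echoed verbatim into the run manifest."""

    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    stride_s: int = 5
    rotate: bool = True
    score_augmented: bool = False       # score the augmented test set instead
    variance_threshold: float = VARIANCE_THRESHOLD_G2
    loess_span: float = 0.25
    loess_degree: int = 2
    seed: int = 0


def run_loso_experiment(recordings: Sequence[RawRecording],
                        tracks: Sequence[AnnotationTrack],
                        config: ExperimentConfig) -> dict:
    """Preprocess -> augment(train) -> train ensemble -> predict held-out subject.

    Scoring uses each fold's original, integer-labeled test windows (the
    rater's annotation is the reference class); windows with interpolated
    float labels exist only in training.  Returns a JSON-serializable report
    with the pooled confusion matrix, the metric battery, correlations at
    all temporal resolutions, the activity table, per-subject day-curve
    summaries and the fold/seed manifest.
    """
    track_by_id = {t.subject_id: t for t in tracks}
    per_subject: dict[str, WindowedDataset] = {}
    discard: list[dict] = []
    for rec in recordings:
        ds = preprocess_recording(rec, track_by_id[rec.subject_id],
                                  config.filter_spec, config.variance_threshold)
        discard += ds.discard_log
        if ds.windows:
            per_subject[rec.subject_id] = ds
    subjects = sorted(per_subject)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects with usable windows for LOSO")

    folds = loso_folds(subjects)
    fold_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in np.random.SeedSequence(config.seed).spawn(len(folds))]
    pooled = ConfusionMatrix3()
    cm_by_activity: dict[str, ConfusionMatrix3] = {}
    series_by_subject: dict[str, ExpCNNSeries] = {}
    fold_log = []
    for (train_ids, test_id), fseed in zip(folds, fold_seeds):
        rng = np.random.default_rng(fseed)
        train_ds = WindowedDataset(
            [w for s in train_ids for w in per_subject[s].windows])
        augmented = augment_training_set(train_ds, rng, config.stride_s,
                                         config.rotate, test_subjects=(test_id,))
        ensemble = train_ensemble(augmented, train_ids, config.cnn, rng,
                                  test_subjects=(test_id,))
        test_windows = [w for w in per_subject[test_id].windows
                        if w.label is not None and float(w.label).is_integer()]
        if config.score_augmented:
            test_aug = augment_training_set(per_subject[test_id], rng,
                                            config.stride_s, config.rotate)
            test_windows = [w for w in test_aug.windows
                            if w.label is not None and float(w.label).is_integer()]
        preds = predict(ensemble, test_windows)
        refs = [int(w.label) for w in test_windows]
        hyps = [p.argmax for p in preds]
        pooled += ConfusionMatrix3.from_labels(refs, hyps)
        for w, r, h in zip(test_windows, refs, hyps):
            cm = cm_by_activity.setdefault(w.activity, ConfusionMatrix3())
            cm.counts[r, h] += 1
        orig_preds = [p for p, w in zip(preds, test_windows) if w.origin == "original"]
        if orig_preds:
            series_by_subject[test_id] = build_series(
                orig_preds, config.loess_span, config.loess_degree)
        fold_log.append({"test_subject": test_id, "seed": fseed,
                         "n_train_windows": len(augmented.windows),
                         "n_test_windows": len(test_windows),
                         "train_subjects": list(train_ids),
                         "member_subsets": [list(m.subject_subset)
                                            for m in ensemble.members]})

    metrics = clinimetrics(pooled)
    correlations = temporal_correlations(series_by_subject, tracks)
    activity = activity_stratified(cm_by_activity)
    summaries = {sid: dict(zip(("mean", "sd"), subject_summary(s)))
                 for sid, s in series_by_subject.items()}
    return {
        "confusion": pooled.counts.tolist(),
        "metrics": metrics,
        "correlations": correlations,
        "activity_table": activity.to_dict("records"),
        "subject_summaries": summaries,
        "discard_counts": pd.DataFrame(discard)["reason"].value_counts().to_dict()
        if discard else {},
        "folds": fold_log,
        "config": {
            "filter": {"low_cut_hz": config.filter_spec.low_cut_hz,
                       "high_cut_hz": config.filter_spec.high_cut_hz,
                       "order": config.filter_spec.order},
            "cnn": config.cnn.to_dict(),
            "stride_s": config.stride_s,
            "rotate": config.rotate,
            "score_augmented": config.score_augmented,
            "variance_threshold": config.variance_threshold,
            "seed": config.seed,
        },
        "_series": series_by_subject,   # stripped before JSON export
    }
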