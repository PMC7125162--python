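"""From softmax triples to an ordinal motor-state score and smoothed day curves.

The expected-value aggregation

    expCNN = 0 * p(OFF) + 1 * p(ON) + 2 * p(DYS)

turns the three class probabilities into a single ordinal score in [0, 2]
(0 = OFF, 1 = ON, 2 = DYS).  It is a relative marker of the motor state, not
a calibrated severity measure.  Per-subject "day curves" are the expCNN
points over time, smoothed with LOESS (locally weighted polynomial
regression with tricube weights; defaults span 0.25, degree 2).  Smoothing
never bridges recording gaps longer than 10 minutes, so sensor outages stay
visible as breaks in the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import SoftmaxPrediction
from .simulate import ConfigError

__all__ = ["ExpCNNSeries", "expcnn", "loess_smooth", "subject_summary",
           "build_series", "write_day_curve"]

_WEIGHTS = np.array([0.0, 1.0, 2.0])


def expcnn(p: SoftmaxPrediction | Sequence[float]) -> float:
    """Expected class index under the softmax distribution; in [0, 2]."""
    probs = np.asarray(p.p if isinstance(p, SoftmaxPrediction) else p, dtype=float)
    if probs.shape != (3,) or np.any(probs < -1e-9) or abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("expcnn needs a normalized probability triple")
    return float(probs @ _WEIGHTS)


def loess_smooth(t: np.ndarray, y: np.ndarray, span: float = 0.25, degree: int = 2,
                 max_gap_s: float = 600.0, clip: tuple | None = (0.0, 2.0)) -> np.ndarray:
    """LOESS: tricube-weighted local polynomial fit evaluated at the input times.

    The series is split at gaps exceeding ``max_gap_s`` and each contiguous
    segment smoothed independently; segments with fewer than degree + 2
    points pass through unchanged.  ``span`` is the fraction of segment
    points in each local neighborhood.
    """
    if not 0.0 < span <= 1.0:
        raise ConfigError("span must be in (0, 1]")
    if degree < 0:
        raise ConfigError("degree must be non-negative")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be matching 1-D arrays")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    out = np.empty_like(y)
    breaks = np.flatnonzero(np.diff(t) > max_gap_s) + 1
    edges = np.concatenate([[0], breaks, [t.size]])
    for a, b in zip(edges[:-1], edges[1:]):
        ts, ys = t[a:b], y[a:b]
        n = ts.size
        q = max(int(np.ceil(span * n)), degree + 1)
        if n < degree + 2 or q > n:
            out[a:b] = ys
            continue
        for i in range(n):
            d = np.abs(ts - ts[i])
            idx = np.argpartition(d, q - 1)[:q]
            dmax = d[idx].max()
            w = (1.0 - (d[idx] / dmax) ** 3) ** 3 if dmax > 0 else np.ones(q)
            # weighted polynomial fit centred at ts[i] for conditioning
            X = np.vander(ts[idx] - ts[i], degree + 1, increasing=True)
            WX = X * w[:, None]
            beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ ys[idx], rcond=None)
            out[a + i] = beta[0]
    if clip is not None:
        out = np.clip(out, *clip)
    return out


@dataclass
class ExpCNNSeries:
    """Per-subject expCNN points plus their LOESS-smoothed day curve."""

    subject_id: str
    start_s: np.ndarray
    expcnn: np.ndarray
    smoothed: np.ndarray = field(default=None)
    smoothing_span: float = 0.25

    def __post_init__(self):
        self.start_s = np.asarray(self.start_s, dtype=float)
        self.expcnn = np.asarray(self.expcnn, dtype=float)
        if self.start_s.size > 1 and np.any(np.diff(self.start_s) <= 0):
            raise ValueError("points must be sorted by time")
        if np.any((self.expcnn < -1e-9) | (self.expcnn > 2 + 1e-9)):
            raise ValueError("expCNN values must lie in [0, 2]")
        if self.smoothed is None:
            self.smoothed = np.full_like(self.expcnn, np.nan)


def build_series(predictions: Sequence[SoftmaxPrediction], span: float = 0.25,
                 degree: int = 2, max_gap_s: float = 600.0) -> ExpCNNSeries:
    """Assemble and smooth one subject's prediction series."""
    if not predictions:
        raise ValueError("no predictions")
    sids = {p.subject_id for p in predictions}
    if len(sids) != 1:
        raise ValueError("predictions must come from a single subject")
    preds = sorted(predictions, key=lambda p: p.start_s)
    t = np.array([p.start_s for p in preds])
    v = np.array([expcnn(p) for p in preds])
    sm = loess_smooth(t, v, span=span, degree=degree, max_gap_s=max_gap_s)
    return ExpCNNSeries(sids.pop(), t, v, sm, span)


def subject_summary(series: ExpCNNSeries) -> tuple[float, float]:
    """Mean and population SD of the unsmoothed expCNN points."""
    v = series.expcnn
    if v.size == 0:
        raise ValueError("empty series")
    return float(v.mean()), float(v.std(ddof=0))


def write_day_curve(series: ExpCNNSeries, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"daycurve_{series.subject_id}.csv"
    pd.DataFrame({"start_s": series.start_s, "expcnn": series.expcnn,
                  "smoothed": series.smoothed}).to_csv(path, index=False)
    return path
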