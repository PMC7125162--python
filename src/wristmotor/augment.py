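"""Training-set augmentation: sliding windows with float labels, SO(3) rotations.

Two families, matching the data expansion the pipeline reproduces:

* *Sliding-window*: from each pair of truly consecutive kept minutes a window
  is slid across the 120 s span with a 5 s stride; a window starting t
  seconds into the span gets the linearly interpolated float label
  (1 - t/60) * L1 + (t/60) * L2.  Offsets 0 and 60 duplicate originals and
  are deduplicated, so M gap-free minutes yield M + (M-1)*11 windows
  (a factor approaching 12x on long gap-free sessions).

* *Rotational*: a random rotation drawn uniformly from SO(3) is applied to
  every window in place, emulating arbitrary arm poses.  Labels are
  unchanged; per-sample vector norms are preserved exactly.

Augmentation is strictly training-only; feeding a designated test subject in
raises :class:`LeakageError`.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .preprocess import MinuteWindow, WindowedDataset, SAMPLES_PER_MINUTE
from .simulate import ConfigError

__all__ = [
    "LeakageError",
    "rotate_window",
    "random_rotation",
    "sliding_windows",
    "augment_training_set",
]


class LeakageError(RuntimeError):
    """A test subject's data reached a training-only operation."""


def _check_rotation(R: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise ValueError("rotation matrix is not orthonormal")
    if abs(np.linalg.det(R) - 1.0) > 1e-6:
        raise ValueError("rotation matrix must have determinant +1")
    return R


def rotate_window(window: MinuteWindow, rotation: np.ndarray) -> MinuteWindow:
    """Rotate every 3-vector sample; label/activity/subject are untouched."""
    R = _check_rotation(rotation)
    origin = {"original": "rotated", "slid": "slid+rotated"}.get(window.origin, window.origin)
    return MinuteWindow(window.subject_id, window.start_s,
                        (window.values @ R.T).astype(np.float32),
                        window.label, window.activity, origin)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A rotation matrix drawn uniformly from SO(3) (random unit quaternion)."""
    return Rotation.random(rng=rng).as_matrix()


def sliding_windows(dataset: WindowedDataset, stride_s: int = 5) -> WindowedDataset:
    """Expand consecutive minute pairs by sliding; originals are kept once.

    Only pairs with start times exactly 60 s apart (gap-free on the grid) are
    slid; an isolated minute contributes only itself.
    """
    if stride_s <= 0 or 60 % stride_s != 0:
        raise ConfigError("stride_s must be a positive divisor of 60")
    rate = SAMPLES_PER_MINUTE / 60.0
    out = WindowedDataset(list(dataset.windows), list(dataset.discard_log))
    by_subject: dict[str, list[MinuteWindow]] = {}
    for w in dataset.windows:
        by_subject.setdefault(w.subject_id, []).append(w)
    for sid, ws in by_subject.items():
        ws = sorted(ws, key=lambda w: w.start_s)
        for w1, w2 in zip(ws[:-1], ws[1:]):
            if abs((w2.start_s - w1.start_s) - 60.0) > 1e-6:
                continue
            joined = np.concatenate([w1.values, w2.values])
            for t in range(stride_s, 60, stride_s):
                o = int(round(t * rate))
                frac = t / 60.0
                lab = None
                if w1.label is not None and w2.label is not None:
                    lab = (1.0 - frac) * w1.label + frac * w2.label
                out.windows.append(MinuteWindow(
                    sid, w1.start_s + t, joined[o:o + SAMPLES_PER_MINUTE],
                    lab, w1.activity if frac < 0.5 else w2.activity, "slid"))
    out.check_unique()
    return out


def augment_training_set(dataset: WindowedDataset, rng: np.random.Generator,
                         stride_s: int = 5, rotate: bool = True,
                         test_subjects: Iterable[str] = ()) -> WindowedDataset:
    """Sliding augmentation, then one independent uniform rotation per window.

    Rotations are applied in place (the unrotated window is replaced), so the
    total count is M + (M-1)*11 per gap-free run of M minutes.  Deterministic
    for a fixed rng state.
    """
    test = set(test_subjects)
    leaked = test & {w.subject_id for w in dataset.windows}
    if leaked:
        raise LeakageError(f"test subjects {sorted(leaked)} present in training data")
    slid = sliding_windows(dataset, stride_s)
    if not rotate:
        return slid
    slid.windows = [rotate_window(w, random_rotation(rng)) for w in slid.windows]
    return slid
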