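"""Raw stream -> cleaned, labeled 1-minute windows.

Pipeline order follows the preprocessing it reproduces: a zero-phase
(forward-backward) Butterworth band-pass of 0.1-20 Hz removes gravity/drift
and high-frequency sensor noise at the native sampling rate, the stream is
then resampled to a uniform 60 Hz grid, and each annotated minute becomes a
3600 x 3 window.  Minutes with a summed per-axis variance below 0.01 G^2
("little to no signal") and minutes without a motor-state annotation are
discarded; the discard log keeps the bookkeeping exact (kept + discarded =
recorded minutes).

Minute k covers the half-open interval [60k, 60(k+1)) seconds, 0-based.
Filtering and resampling are applied per contiguous segment and never bridge
recording gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import h5py
import numpy as np
import pandas as pd
from scipy import signal

from .simulate import RawRecording, AnnotationTrack, ConfigError

__all__ = [
    "FilterSpec",
    "MinuteWindow",
    "WindowedDataset",
    "bandpass",
    "resample_to_grid",
    "window_and_label",
    "preprocess_recording",
    "write_windows",
    "read_windows",
]

log = logging.getLogger("wristmotor.preprocess")

RESAMPLE_RATE_HZ = 60.0
SAMPLES_PER_MINUTE = 3600
VARIANCE_THRESHOLD_G2 = 0.01

#: discard_log reason codes
UNANNOTATED, LOW_VARIANCE, DROPOUT = "unannotated", "low_variance", "dropout"


@dataclass
class FilterSpec:
    low_cut_hz: float = 0.1
    high_cut_hz: float = 20.0
    order: int = 4          # per direction; forward-backward squares the response
    # mode is always zero-phase forward-backward (sosfiltfilt)

    def __post_init__(self):
        if not 0 < self.low_cut_hz < self.high_cut_hz:
            raise ConfigError("need 0 < low_cut_hz < high_cut_hz")
        if self.high_cut_hz >= RESAMPLE_RATE_HZ / 2:
            raise ConfigError("high_cut_hz must lie below the 30 Hz output Nyquist")
        if self.order < 1:
            raise ConfigError("order must be >= 1")

    def sos(self, fs: float) -> np.ndarray:
        if self.high_cut_hz >= fs / 2:
            raise ConfigError(
                f"high cutoff {self.high_cut_hz} Hz >= Nyquist {fs / 2} Hz of the stream")
        return signal.butter(self.order, [self.low_cut_hz, self.high_cut_hz],
                             btype="bandpass", fs=fs, output="sos")


@dataclass
class MinuteWindow:
    """One labeled 3600x3 minute of filtered 60 Hz acceleration."""

    subject_id: str
    start_s: float
    values: np.ndarray            # (3600, 3) float32, G
    label: Optional[float]        # float in [0, 2], None if scoring-only use
    activity: str
    origin: str = "original"      # original | slid | rotated | slid+rotated

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != (SAMPLES_PER_MINUTE, 3):
            raise ValueError(f"window must be {SAMPLES_PER_MINUTE}x3, got {self.values.shape}")
        if self.label is not None and not 0.0 <= self.label <= 2.0:
            raise ValueError("label must be in [0, 2]")

    @property
    def key(self) -> tuple:
        return (self.subject_id, round(float(self.start_s), 6), self.origin)


@dataclass
class WindowedDataset:
    windows: list[MinuteWindow] = field(default_factory=list)
    discard_log: list[dict] = field(default_factory=list)  # subject_id, minute_index, reason

    def __len__(self):
        return len(self.windows)

    def subjects(self) -> list[str]:
        return sorted({w.subject_id for w in self.windows})

    def check_unique(self) -> None:
        keys = [w.key for w in self.windows]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (subject, start_s, origin) window keys")

    def discard_counts(self) -> dict:
        out: dict[str, int] = {}
        for e in self.discard_log:
            out[e["reason"]] = out.get(e["reason"], 0) + 1
        return out

    def restrict(self, subject_ids: Iterable[str]) -> "WindowedDataset":
        ids = set(subject_ids)
        return WindowedDataset([w for w in self.windows if w.subject_id in ids],
                               [e for e in self.discard_log if e["subject_id"] in ids])


def _segments(t: np.ndarray, gap_threshold_s: float = 0.5) -> list[slice]:
    """Slices of contiguous samples; a time step above the threshold starts a new segment."""
    if t.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(t) > gap_threshold_s) + 1
    edges = np.concatenate([[0], breaks, [t.size]])
    return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def bandpass(recording: RawRecording, spec: FilterSpec = FilterSpec(),
             gap_threshold_s: float = 0.5) -> RawRecording:
    """Zero-phase band-pass per contiguous segment at the segment's native rate.

    Segments too short for stable forward-backward filtering (fewer than
    ~3 x order x 2 + 1 samples) are dropped and logged; their minutes later
    surface in the discard log as dropout.
    """
    t_parts, x_parts = [], []
    for seg in _segments(recording.t, gap_threshold_s):
        ts, xs = recording.t[seg], recording.xyz[seg]
        fs = 1.0 / float(np.median(np.diff(ts))) if ts.size > 1 else 0.0
        sos = spec.sos(fs) if ts.size > 1 else None
        padlen = 3 * (2 * (sos.shape[0] if sos is not None else 0))
        if ts.size <= padlen:
            log.info("dropping segment of %d samples (< %d) for %s",
                     ts.size, padlen + 1, recording.subject_id)
            continue
        t_parts.append(ts)
        x_parts.append(signal.sosfiltfilt(sos, xs, axis=0))
    if not t_parts:
        return RawRecording(recording.subject_id, np.empty(0), np.empty((0, 3)),
                            recording.device_meta)
    return RawRecording(recording.subject_id, np.concatenate(t_parts),
                        np.concatenate(x_parts), recording.device_meta)


def resample_to_grid(recording: RawRecording, rate_hz: float = RESAMPLE_RATE_HZ,
                     gap_threshold_s: float = 0.5) -> RawRecording:
    """Linear interpolation onto the global k/rate grid, per contiguous segment.

    Output timestamps are exact multiples of 1/rate spanning each segment, so
    minute windows from different segments stay aligned to the same grid.
    """
    t_parts, x_parts = [], []
    for seg in _segments(recording.t, gap_threshold_s):
        ts, xs = recording.t[seg], recording.xyz[seg]
        if ts.size < 2:
            log.info("skipping degenerate segment (%d samples) for %s",
                     ts.size, recording.subject_id)
            continue
        k0 = int(np.ceil(ts[0] * rate_hz - 1e-9))
        k1 = int(np.floor(ts[-1] * rate_hz + 1e-9))
        if k1 < k0:
            continue
        grid = np.arange(k0, k1 + 1, dtype=float) / rate_hz
        out = np.column_stack([np.interp(grid, ts, xs[:, j]) for j in range(3)])
        t_parts.append(grid)
        x_parts.append(out)
    if not t_parts:
        return RawRecording(recording.subject_id, np.empty(0), np.empty((0, 3)),
                            recording.device_meta)
    meta = dict(recording.device_meta)
    meta["resampled_rate_hz"] = rate_hz
    return RawRecording(recording.subject_id, np.concatenate(t_parts),
                        np.concatenate(x_parts), meta)


def window_and_label(recording: RawRecording, track: AnnotationTrack,
                     variance_threshold: float = VARIANCE_THRESHOLD_G2) -> WindowedDataset:
    """Cut the filtered, resampled stream into annotated minute windows.

    Precedence of discard reasons: a partial minute (< 3600 samples on the
    grid) is ``dropout``; an intact minute without a motor-state annotation is
    ``unannotated``; an intact annotated minute whose per-axis variances sum
    below the threshold is ``low_variance``.
    """
    ds = WindowedDataset()
    if recording.t.size == 0:
        return ds
    rate = recording.device_meta.get("resampled_rate_hz", RESAMPLE_RATE_HZ)
    idx = np.rint(recording.t * rate).astype(np.int64)  # global grid index
    minute_of = idx // SAMPLES_PER_MINUTE
    order = np.argsort(idx)
    for minute in np.unique(minute_of):
        sel = order[minute_of[order] == minute]
        if sel.size < SAMPLES_PER_MINUTE:
            ds.discard_log.append({"subject_id": recording.subject_id,
                                   "minute_index": int(minute), "reason": DROPOUT})
            continue
        state = track.state_of_minute(int(minute))
        if state < 0:
            ds.discard_log.append({"subject_id": recording.subject_id,
                                   "minute_index": int(minute), "reason": UNANNOTATED})
            continue
        vals = recording.xyz[sel]
        if float(np.var(vals, axis=0).sum()) < variance_threshold:
            ds.discard_log.append({"subject_id": recording.subject_id,
                                   "minute_index": int(minute), "reason": LOW_VARIANCE})
            continue
        pos = int(np.searchsorted(track.minute_index, int(minute)))
        ds.windows.append(MinuteWindow(
            recording.subject_id, 60.0 * float(minute), vals.astype(np.float32),
            float(state), str(track.activity[pos]), "original"))
    return ds


def preprocess_recording(recording: RawRecording, track: AnnotationTrack,
                         spec: FilterSpec = FilterSpec(),
                         variance_threshold: float = VARIANCE_THRESHOLD_G2) -> WindowedDataset:
    """filter -> resample -> window, the full preprocessing chain for one subject."""
    filtered = bandpass(recording, spec)
    regular = resample_to_grid(filtered)
    return window_and_label(regular, track, variance_threshold)


# ---------------------------------------------------------------------------
# HDF5 container + discard log CSV
# ---------------------------------------------------------------------------

def write_windows(dataset: WindowedDataset, path: str | Path,
                  discard_log_path: str | Path | None = None) -> None:
    path = Path(path)
    n = len(dataset.windows)
    values = np.stack([w.values for w in dataset.windows]) if n else \
        np.empty((0, SAMPLES_PER_MINUTE, 3), np.float32)
    labels = np.array([np.nan if w.label is None else w.label
                       for w in dataset.windows], np.float32)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=values, compression="gzip", compression_opts=1)
        f.create_dataset("label", data=labels)
        f.create_dataset("start_s", data=np.array([w.start_s for w in dataset.windows]))
        s = h5py.string_dtype("utf-8")
        f.create_dataset("subject", data=np.array([w.subject_id for w in dataset.windows], s))
        f.create_dataset("activity", data=np.array([w.activity for w in dataset.windows], s))
        f.create_dataset("origin", data=np.array([w.origin for w in dataset.windows], s))
    if discard_log_path is not None:
        pd.DataFrame(dataset.discard_log,
                     columns=["subject_id", "minute_index", "reason"]).to_csv(
            discard_log_path, index=False)


def read_windows(path: str | Path,
                 discard_log_path: str | Path | None = None) -> WindowedDataset:
    with h5py.File(path, "r") as f:
        values = f["values"][...]
        labels = f["label"][...]
        starts = f["start_s"][...]
        subj = [s.decode() if isinstance(s, bytes) else s for s in f["subject"][...]]
        acts = [s.decode() if isinstance(s, bytes) else s for s in f["activity"][...]]
        origins = [s.decode() if isinstance(s, bytes) else s for s in f["origin"][...]]
    ds = WindowedDataset()
    for i in range(values.shape[0]):
        lab = None if np.isnan(labels[i]) else float(labels[i])
        ds.windows.append(MinuteWindow(subj[i], float(starts[i]), values[i],
                                       lab, acts[i], origins[i]))
    if discard_log_path is not None and Path(discard_log_path).exists():
        ds.discard_log = pd.read_csv(discard_log_path).to_dict("records")
    return ds
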