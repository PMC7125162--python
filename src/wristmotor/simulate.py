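"""Synthetic wrist-accelerometer cohorts with minute-level motor-state annotations.

Real recordings of patients with Parkinson's disease (PwP) alternate between
three motor states — OFF (bradykinetic), ON (good mobility) and DYS
(choreatic dyskinesia), coded 0/1/2 — on a time scale of minutes, driven by
medication pharmacokinetics.  This module generates cohorts that mimic the
*shape* of such data (multi-hour tri-axial wrist acceleration at a jittered
~62.5 Hz, one-minute expert annotations with gaps, recording dropouts) and
give each state a distinct, recoverable motion signature:

* OFF  — little voluntary movement plus intermittent 4–6 Hz rest-tremor bursts;
* ON   — moderate voluntary movement in the 0.5–3 Hz band;
* DYS  — high-amplitude irregular oscillation in the 1–4 Hz band.

Walking adds a gait harmonic; a slowly drifting gravity vector and white
sensor noise are superimposed.  The per-minute state sequence follows a
row-stochastic Markov chain whose default stationary distribution matches a
realistic OFF/ON/DYS minute mix (~27/41/32 %).  No claim of clinical realism
is made: the signatures are parameterised stand-ins that give the downstream
pipeline a ground truth to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "RawRecording",
    "AnnotationTrack",
    "ConfigError",
    "CohortParseError",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "stationary_distribution",
    "default_class_transition",
]

#: Motor-state codes.
OFF, ON, DYS = 0, 1, 2

#: Activity categories the rater may note (plus "unknown" for undocumented).
ACTIVITIES = ("sitting", "lying", "walking", "standing", "sleeping", "testing", "other")

G_CLIP = 8.0  # sensor clipping range, G


class ConfigError(ValueError):
    """Invalid simulation or pipeline configuration."""


class CohortParseError(ValueError):
    """A cohort CSV could not be parsed; the message names the offending row."""


def default_class_transition(stationary=(0.268, 0.414, 0.318), mix: float = 0.10) -> np.ndarray:
    """Per-minute Markov matrix with the given stationary distribution.

    Uses the reversible construction P[i,j] = mix*pi[j] (i != j), which
    satisfies detailed balance, so ``stationary`` is exact.  ``mix`` sets the
    switching rate; 0.10 gives mean dwell times of roughly 15 minutes.
    """
    pi = np.asarray(stationary, dtype=float)
    pi = pi / pi.sum()
    P = mix * np.tile(pi, (3, 1))
    np.fill_diagonal(P, 0.0)
    np.fill_diagonal(P, 1.0 - P.sum(axis=1))
    return P


def _default_activity_transition() -> np.ndarray:
    n = len(ACTIVITIES)
    # diagonal-heavy chain; off-diagonal mass weighted toward sitting/walking
    w = np.array([0.50, 0.10, 0.20, 0.08, 0.04, 0.03, 0.05])
    P = 0.15 * np.tile(w / w.sum(), (n, 1))
    np.fill_diagonal(P, 0.0)
    np.fill_diagonal(P, 1.0 - P.sum(axis=1))
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix via eigen-decomposition."""
    vals, vecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    return pi / pi.sum()


@dataclass
class SimulationConfig:
    """Everything that determines a synthetic cohort, including the seed."""

    n_subjects: int = 8
    session_minutes_range: tuple[int, int] = (30, 60)
    sampling_rate_hz: float = 62.5
    sampling_jitter: float = 0.02        # uniform +/- fraction per sample interval
    class_transition: np.ndarray = field(default_factory=default_class_transition)
    initial_state: Optional[int] = None  # None -> draw from the chain's stationary dist.
    # class signatures: band edges (Hz) and amplitude scales (G)
    tremor_band_hz: tuple[float, float] = (4.0, 6.0)
    voluntary_band_hz: tuple[float, float] = (0.5, 3.0)
    dyskinesia_band_hz: tuple[float, float] = (1.0, 4.0)
    amp_off_g: float = 0.10
    amp_on_g: float = 0.30
    amp_dys_g: float = 0.60
    tremor_amp_g: float = 0.25
    tremor_burst_prob: float = 0.7       # fraction of OFF seconds with active tremor
    gait_hz: float = 1.9
    gait_amp_g: float = 0.25
    activity_transition: np.ndarray = field(default_factory=_default_activity_transition)
    gravity_drift_scale: float = 0.02    # rad / sqrt(s) orientation random walk
    noise_sd_g: float = 0.02
    dropout_prob: float = 0.05
    unannotated_prob: float = 0.05
    seed: int = 0

    def __post_init__(self):
        self.class_transition = np.asarray(self.class_transition, dtype=float)
        self.activity_transition = np.asarray(self.activity_transition, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name, P, n in (
            ("class_transition", self.class_transition, 3),
            ("activity_transition", self.activity_transition, len(ACTIVITIES)),
        ):
            if P.shape != (n, n):
                raise ConfigError(f"{name} must be {n}x{n}, got {P.shape}")
            if np.any(P < -1e-12) or np.any(P > 1 + 1e-12):
                raise ConfigError(f"{name} entries must be probabilities in [0, 1]")
            if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
                raise ConfigError(f"{name} rows must sum to 1 within 1e-9")
        if self.sampling_rate_hz <= 2 * 20.0:
            raise ConfigError("sampling_rate_hz must exceed twice the 20 Hz filter cutoff")
        for name in ("dropout_prob", "unannotated_prob", "tremor_burst_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be non-negative")
        lo, hi = self.session_minutes_range
        if not (0 < lo <= hi):
            raise ConfigError("session_minutes_range must satisfy 0 < min <= max")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_transition"] = self.class_transition.tolist()
        d["activity_transition"] = self.activity_transition.tolist()
        return d


@dataclass
class RawRecording:
    """One subject's timestamped tri-axial acceleration stream (G units)."""

    subject_id: str
    t: np.ndarray          # seconds from session start, strictly increasing
    xyz: np.ndarray        # (n, 3) acceleration in G
    device_meta: dict = field(default_factory=lambda: {"nominal_rate_hz": 62.5, "clip_g": G_CLIP})

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.t.ndim != 1 or self.xyz.shape != (self.t.size, 3):
            raise ValueError("t must be 1-D and xyz (n, 3)")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __eq__(self, other):
        return (
            isinstance(other, RawRecording)
            and self.subject_id == other.subject_id
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.xyz, other.xyz)
        )


@dataclass
class AnnotationTrack:
    """Per-minute expert labels for one subject.

    ``motor_state`` uses -1 for a missing (unannotated) minute; items are on
    the clinical 0-4 scales (global bradykinesia and upper-limb dyskinesia).
    """

    subject_id: str
    minute_index: np.ndarray   # unique, sorted
    motor_state: np.ndarray    # {0,1,2} or -1 missing
    brady_item: np.ndarray     # 0-4
    dys_item: np.ndarray       # 0-4
    activity: np.ndarray       # object array of category names / "unknown"

    def __post_init__(self):
        self.minute_index = np.asarray(self.minute_index, dtype=int)
        self.motor_state = np.asarray(self.motor_state, dtype=int)
        self.brady_item = np.asarray(self.brady_item, dtype=int)
        self.dys_item = np.asarray(self.dys_item, dtype=int)
        self.activity = np.asarray(self.activity, dtype=object)
        if len(set(self.minute_index.tolist())) != self.minute_index.size:
            raise ValueError("minute_index must be unique per subject")
        bad = (self.motor_state == DYS) & (self.dys_item <= 0)
        if np.any(bad):
            raise ValueError("DYS minutes must have dys_item > 0")

    def state_of_minute(self, k: int) -> int:
        """Motor state of minute k, or -1 if absent/unannotated."""
        idx = np.searchsorted(self.minute_index, k)
        if idx < self.minute_index.size and self.minute_index[idx] == k:
            return int(self.motor_state[idx])
        return -1

    def __eq__(self, other):
        return (
            isinstance(other, AnnotationTrack)
            and self.subject_id == other.subject_id
            and np.array_equal(self.minute_index, other.minute_index)
            and np.array_equal(self.motor_state, other.motor_state)
            and np.array_equal(self.brady_item, other.brady_item)
            and np.array_equal(self.dys_item, other.dys_item)
            and list(self.activity) == list(other.activity)
        )


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _markov_path(P: np.ndarray, n: int, rng: np.random.Generator, init: Optional[int]) -> np.ndarray:
    pi = stationary_distribution(P) if init is None else None
    states = np.empty(n, dtype=int)
    s = int(rng.choice(P.shape[0], p=pi)) if init is None else int(init)
    for k in range(n):
        states[k] = s
        s = int(rng.choice(P.shape[0], p=P[s]))
    return states


def _band_mixture(t: np.ndarray, band: tuple[float, float], amp: float,
                  n_components: int, rng: np.random.Generator) -> np.ndarray:
    """Sum of randomly oriented sinusoids with frequencies jittered in a band."""
    out = np.zeros((t.size, 3))
    if amp == 0.0 or t.size == 0:
        return out
    for _ in range(n_components):
        f = rng.uniform(*band)
        phase = rng.uniform(0, 2 * np.pi)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        a = amp * rng.uniform(0.5, 1.0) / np.sqrt(n_components)
        out += a * np.sin(2 * np.pi * f * t + phase)[:, None] * direction[None, :]
    return out


def _minute_signature(t: np.ndarray, state: int, activity: str,
                      cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Class-conditional acceleration (G) for one minute, gravity/noise excluded."""
    if state == OFF:
        sig = _band_mixture(t, cfg.voluntary_band_hz, cfg.amp_off_g, 2, rng)
        if cfg.tremor_amp_g > 0:
            # intermittent rest tremor: per-second on/off envelope
            env_sec = (rng.random(int(np.ceil(t.max() - t.min() + 1e-9)) + 1 if t.size else 1)
                       < cfg.tremor_burst_prob).astype(float)
            env = env_sec[np.minimum((t - t.min()).astype(int), env_sec.size - 1)]
            tremor = _band_mixture(t, cfg.tremor_band_hz, cfg.tremor_amp_g, 1, rng)
            sig = sig + tremor * env[:, None]
    elif state == ON:
        sig = _band_mixture(t, cfg.voluntary_band_hz, cfg.amp_on_g, 3, rng)
    else:  # DYS: irregular high-amplitude oscillation, amplitude-modulated
        sig = _band_mixture(t, cfg.dyskinesia_band_hz, cfg.amp_dys_g, 3, rng)
        am = 1.0 + 0.5 * np.sin(2 * np.pi * rng.uniform(0.05, 0.2) * t + rng.uniform(0, 2 * np.pi))
        sig = sig * am[:, None]
    if activity == "walking" and cfg.gait_amp_g > 0:
        f, ph = cfg.gait_hz * rng.uniform(0.9, 1.1), rng.uniform(0, 2 * np.pi)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        gait = cfg.gait_amp_g * (np.sin(2 * np.pi * f * t + ph)
                                 + 0.4 * np.sin(4 * np.pi * f * t + ph))
        sig = sig + gait[:, None] * axis[None, :]
    return sig


def _gravity_path(t: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator,
                  theta0: float, phi0: float) -> np.ndarray:
    """Slow orientation random walk of the 1 G gravity vector, sampled at t."""
    if t.size == 0:
        return np.zeros((0, 3))
    duration = float(t[-1] - t[0])
    n_knots = max(int(np.ceil(duration)) + 2, 2)
    knots = t[0] + np.arange(n_knots, dtype=float)
    steps = rng.normal(0.0, cfg.gravity_drift_scale, size=(n_knots, 2))
    steps[0] = 0.0
    theta = theta0 + np.cumsum(steps[:, 0])
    phi = phi0 + np.cumsum(steps[:, 1])
    th = np.interp(t, knots, theta)
    ph = np.interp(t, knots, phi)
    return np.column_stack([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])


def simulate_cohort(config: SimulationConfig) -> tuple[list[RawRecording], list[AnnotationTrack]]:
    """Generate one recording and one annotation track per subject.

    Deterministic: the same config (including seed) yields bit-identical
    output.  Dropout minutes produce no samples but keep their annotation;
    unannotated minutes are recorded but have a missing motor state.
    """
    config.validate()
    recordings: list[RawRecording] = []
    tracks: list[AnnotationTrack] = []
    root = np.random.SeedSequence(config.seed)
    for i, child in enumerate(root.spawn(config.n_subjects)):
        rng = np.random.default_rng(child)
        sid = f"S{i:03d}"
        n_min = int(rng.integers(config.session_minutes_range[0],
                                 config.session_minutes_range[1] + 1))
        states = _markov_path(config.class_transition, n_min, rng, config.initial_state)
        act_idx = _markov_path(config.activity_transition, n_min, rng, None)
        acts = np.array([ACTIVITIES[j] for j in act_idx], dtype=object)
        dropout = rng.random(n_min) < config.dropout_prob
        unannot = rng.random(n_min) < config.unannotated_prob

        # severity items coupled to state by a fixed monotone map + bounded noise
        brady_base = np.select([states == OFF, states == ON], [3, 1], default=0)
        brady = np.clip(brady_base + rng.integers(-1, 2, size=n_min), 0, 4)
        brady[states == DYS] = 0
        dys = np.zeros(n_min, dtype=int)
        dys[states == DYS] = np.clip(2 + rng.integers(-1, 2, size=int((states == DYS).sum())), 1, 4)

        theta0, phi0 = rng.uniform(0, np.pi), rng.uniform(0, 2 * np.pi)
        period = 1.0 / config.sampling_rate_hz
        t_parts, a_parts = [], []
        for k in range(n_min):
            if dropout[k]:
                continue
            # jittered sample times covering [60k, 60(k+1))
            n_nom = int(np.ceil(60.0 / period)) + 8
            dt = period * (1.0 + config.sampling_jitter * rng.uniform(-1, 1, size=n_nom))
            tt = 60.0 * k + np.concatenate([[0.0], np.cumsum(dt)])
            tt = tt[tt < 60.0 * (k + 1)]
            sig = _minute_signature(tt, int(states[k]), str(acts[k]), config, rng)
            t_parts.append(tt)
            a_parts.append(sig)
        if t_parts:
            t = np.concatenate(t_parts)
            a = np.concatenate(a_parts)
            a = a + _gravity_path(t, config, rng, theta0, phi0)
            if config.noise_sd_g > 0:
                a = a + rng.normal(0.0, config.noise_sd_g, size=a.shape)
            a = np.clip(a, -G_CLIP, G_CLIP)
        else:
            t, a = np.empty(0), np.empty((0, 3))
        recordings.append(RawRecording(
            sid, t, a,
            device_meta={"nominal_rate_hz": config.sampling_rate_hz, "clip_g": G_CLIP}))
        ms = np.where(unannot, -1, states)
        tracks.append(AnnotationTrack(
            sid, np.arange(n_min), ms, brady, dys, acts))
    return recordings, tracks


# ---------------------------------------------------------------------------
# cohort I/O (plain CSV + JSON manifest)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def write_cohort(recordings: Sequence[RawRecording], tracks: Sequence[AnnotationTrack],
                 directory: str | Path, config: Optional[SimulationConfig] = None) -> dict:
    """Write ``sensor_<id>.csv`` / ``annotations_<id>.csv`` per subject plus a manifest.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_id = {tr.subject_id: tr for tr in tracks}
    if set(by_id) != {r.subject_id for r in recordings}:
        raise ValueError("recordings and tracks must cover the same subjects")
    files = []
    for rec in recordings:
        sp = directory / f"sensor_{rec.subject_id}.csv"
        with open(sp, "w", encoding="utf-8") as fh:
            fh.write("timestamp_s,ax_g,ay_g,az_g\n")
            for j in range(rec.t.size):
                fh.write(_FLOAT_FMT % rec.t[j] + "," +
                         ",".join(_FLOAT_FMT % v for v in rec.xyz[j]) + "\n")
        tr = by_id[rec.subject_id]
        ap = directory / f"annotations_{rec.subject_id}.csv"
        with open(ap, "w", encoding="utf-8") as fh:
            fh.write("minute_index,motor_state,brady_item,dys_item,activity\n")
            for j in range(tr.minute_index.size):
                ms = "" if tr.motor_state[j] < 0 else str(int(tr.motor_state[j]))
                fh.write(f"{int(tr.minute_index[j])},{ms},{int(tr.brady_item[j])},"
                         f"{int(tr.dys_item[j])},{tr.activity[j]}\n")
        files.append({"subject": rec.subject_id, "sensor": sp.name, "annotations": ap.name})
    manifest = {
        "subjects": [r.subject_id for r in recordings],
        "files": files,
        "config": config.to_dict() if config is not None else None,
        "seed": config.seed if config is not None else None,
    }
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_cohort(directory: str | Path) -> tuple[list[RawRecording], list[AnnotationTrack]]:
    """Inverse of :func:`write_cohort`; round-trips to full float precision."""
    directory = Path(directory)
    mpath = directory / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    with open(mpath, encoding="utf-8") as fh:
        manifest = json.load(fh)
    recordings, tracks = [], []
    for entry in manifest["files"]:
        sid = entry["subject"]
        try:
            sdf = pd.read_csv(directory / entry["sensor"], dtype=float,
                              float_precision="round_trip")
        except (ValueError, pd.errors.ParserError) as exc:
            raise CohortParseError(f"{entry['sensor']}: {exc}") from exc
        need = ["timestamp_s", "ax_g", "ay_g", "az_g"]
        if list(sdf.columns) != need:
            raise CohortParseError(f"{entry['sensor']}: header row must be {','.join(need)}")
        recordings.append(RawRecording(sid, sdf["timestamp_s"].to_numpy(),
                                       sdf[["ax_g", "ay_g", "az_g"]].to_numpy()))
        adf = pd.read_csv(directory / entry["annotations"],
                          dtype={"activity": str}, keep_default_na=False, na_values=[""])
        for col in ("minute_index", "brady_item", "dys_item"):
            bad = adf[col].isna()
            if bad.any():
                raise CohortParseError(
                    f"{entry['annotations']}: row {int(np.flatnonzero(bad)[0]) + 2} "
                    f"has missing {col}")
        ms = adf["motor_state"].fillna(-1).astype(int).to_numpy()
        tracks.append(AnnotationTrack(
            sid, adf["minute_index"].astype(int).to_numpy(), ms,
            adf["brady_item"].astype(int).to_numpy(),
            adf["dys_item"].astype(int).to_numpy(),
            adf["activity"].to_numpy(dtype=object)))
    return recordings, tracks
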