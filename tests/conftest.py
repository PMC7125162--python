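"""Shared fixtures: small synthetic cohorts and separable band-signal windows."""

import numpy as np
import pytest

from wristmotor.preprocess import MinuteWindow
from wristmotor.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """8 subjects, 30-60 min sessions, default signatures (seed 7)."""
    cfg = SimulationConfig(n_subjects=8, session_minutes_range=(30, 60), seed=7)
    recordings, tracks = simulate_cohort(cfg)
    return cfg, recordings, tracks


def make_band_window(cls: int, rng: np.random.Generator, subject="S0", start=0.0,
                     axis=(1.0, 0.0, 0.0), noise_sd=0.02) -> MinuteWindow:
    """One minute whose class is encoded by frequency band and amplitude.

    The signal lies along a fixed axis so that rotation augmentation has
    something to do; classes are separable by band power.
    """
    t = np.arange(3600) / 60.0
    f = {0: rng.uniform(4, 6), 1: rng.uniform(0.5, 3), 2: rng.uniform(1, 4)}[cls]
    a = {0: 0.1, 1: 0.3, 2: 0.6}[cls]
    sig = a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))[:, None] \
        * np.asarray(axis, dtype=float)[None, :]
    sig = sig + rng.normal(0, noise_sd, (3600, 3))
    return MinuteWindow(subject, start, sig.astype(np.float32), float(cls), "sitting")


def make_band_dataset(n_subjects: int, minutes_per_subject: int, seed: int):
    """Separable multi-subject window list: classes cycle minute by minute."""
    rng = np.random.default_rng(seed)
    wins = []
    for s in range(n_subjects):
        for i in range(minutes_per_subject):
            wins.append(make_band_window(i % 3, rng, subject=f"S{s}", start=60.0 * i))
    return wins


@pytest.fixture(scope="session")
def band_windows():
    """6 subjects x 30 separable minutes; shared read-only across tests."""
    return make_band_dataset(6, 30, seed=0)
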