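"""Convolutional motor-state classifier and its patient-subset ensemble.

The network maps a 3600 x 3 one-minute acceleration window to three logits
(OFF/ON/DYS) through seven convolutional blocks — each convolution + batch
normalization + ReLU — followed by two fully connected layers (hidden size
512 by default).  The default temporal schedule, with valid padding,
contracts 3600 -> 899 -> 223 -> 73 -> 35 -> 16 -> 14 -> 13; with the default
channel schedule ending at 64, the 13 x 64 feature map flattens to an
832-vector.

Two published descriptions of the channel schedule conflict; both ship as
named configs.  ``caption`` (default) uses [8, 16, 16, 32, 32, 64, 64],
whose shape arithmetic (13 * 64 = 832) is internally consistent;
``paper-text`` uses [64, 128, 256, 512, 1024, 1024, 1024] and flattens to
13 * 1024.  A ``reduced`` schedule exists for desk-scale experiments.

The three acceleration axes enter as input channels of a 1-D convolution.
The alternative reading — a single-channel 2-D "image" of height 3600 and
width 3 with a width-3 kernel in the first block — collapses the width
dimension immediately and is arithmetically identical, so one computation
path serves both layouts.

An ensemble member is trained on windows from a random subset of (at most)
15 training subjects; the ensemble prediction is the mean of member softmax
vectors.  Training uses Adam on soft-label cross-entropy: a float label l
becomes a two-point distribution with mass 1-frac(l) on floor(l) and
frac(l) on ceil(l), so interpolated sliding-window labels train directly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._nn import (Adam, BatchNorm1d, Conv1d, Dense, Flatten, Network, ReLU,
                  refresh_batchnorm, soft_cross_entropy, softmax)
from .augment import LeakageError
from .preprocess import MinuteWindow, WindowedDataset, SAMPLES_PER_MINUTE
from .simulate import ConfigError

__all__ = [
    "CNNConfig", "ShapeError", "SoftmaxPrediction", "EnsembleModel",
    "CHANNEL_SCHEDULES", "DEFAULT_TEMPORAL_SCHEDULE",
    "build_cnn", "block_lengths", "parameter_count",
    "soft_target", "soft_targets",
    "train_member", "train_ensemble", "predict",
    "save_ensemble", "load_ensemble",
]

N_CLASSES = 3

#: (kernel, stride) per block; valid padding lands exactly on length 13.
DEFAULT_TEMPORAL_SCHEDULE = ((8, 4), (8, 4), (5, 3), (4, 2), (4, 2), (3, 1), (2, 1))

CHANNEL_SCHEDULES = {
    "caption": (8, 16, 16, 32, 32, 64, 64),
    "paper-text": (64, 128, 256, 512, 1024, 1024, 1024),
    "reduced": (4, 8, 8, 16, 16, 32, 32),
}


class ShapeError(ConfigError):
    """The block schedule's valid-padding arithmetic does not close."""


@dataclass
class CNNConfig:
    channels: tuple = CHANNEL_SCHEDULES["caption"]
    temporal: tuple = DEFAULT_TEMPORAL_SCHEDULE
    fc_hidden: int = 512
    input_layout: str = "channels"   # "channels" (3 x 1-D) or "image" (1 x 3600 x 3); identical math
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 64
    early_stopping: bool = True      # hold out one training subject when >= 4 available
    patience: int = 2
    subset_size: int = 15            # subjects per ensemble member
    n_members: int = 5

    def __post_init__(self):
        self.channels = tuple(int(c) for c in self.channels)
        self.temporal = tuple((int(k), int(s)) for k, s in self.temporal)
        if len(self.channels) != 7 or len(self.temporal) != 7:
            raise ConfigError("exactly 7 convolutional blocks are required")
        if self.input_layout not in ("channels", "image"):
            raise ConfigError("input_layout must be 'channels' or 'image'")

    @classmethod
    def named(cls, schedule: str, **kw) -> "CNNConfig":
        if schedule not in CHANNEL_SCHEDULES:
            raise ConfigError(f"unknown schedule {schedule!r}; "
                              f"choose from {sorted(CHANNEL_SCHEDULES)}")
        return cls(channels=CHANNEL_SCHEDULES[schedule], **kw)

    def to_dict(self) -> dict:
        return asdict(self)


def block_lengths(config: CNNConfig) -> list[int]:
    """Temporal length after each block: L_out = floor((L_in - k)/s) + 1."""
    lengths, l = [], SAMPLES_PER_MINUTE
    for k, s in config.temporal:
        l = Conv1d.out_len(l, k, s)
        if l <= 0:
            break
        lengths.append(l)
    return lengths


def flatten_length(config: CNNConfig) -> int:
    return block_lengths(config)[-1] * config.channels[-1]


def parameter_count(config: CNNConfig) -> int:
    """Closed-form learnable-parameter count (conv weights, BN affine, FC)."""
    n, c_in = 0, 3
    for c_out, (k, _) in zip(config.channels, config.temporal):
        n += c_in * k * c_out + 2 * c_out    # conv (no bias) + BN gamma/beta
        c_in = c_out
    flat = flatten_length(config)
    n += flat * config.fc_hidden + config.fc_hidden
    n += config.fc_hidden * N_CLASSES + N_CLASSES
    return n


def build_cnn(config: CNNConfig, rng: Optional[np.random.Generator] = None) -> Network:
    """Instantiate the network; raises :class:`ShapeError` if lengths don't close."""
    lengths = block_lengths(config)
    if len(lengths) != 7 or lengths[-1] != 13:
        raise ShapeError(
            f"temporal schedule yields per-block lengths {lengths}; "
            "the final block must land on 13 (adjust kernels/strides)")
    rng = rng if rng is not None else np.random.default_rng(0)
    layers: list = []
    c_in = 3
    for c_out, (k, s) in zip(config.channels, config.temporal):
        layers += [Conv1d(c_in, c_out, k, s, rng), BatchNorm1d(c_out), ReLU()]
        c_in = c_out
    layers += [Flatten(),
               Dense(lengths[-1] * c_in, config.fc_hidden, rng), ReLU(),
               Dense(config.fc_hidden, N_CLASSES, rng)]
    return Network(layers)


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------

def soft_target(label: float) -> np.ndarray:
    """Float label in [0,2] -> probability triple splitting mass to the neighbors."""
    if not 0.0 <= label <= 2.0:
        raise ValueError("label must be in [0, 2]")
    t = np.zeros(N_CLASSES)
    lo = int(math.floor(label))
    frac = label - lo
    t[lo] = 1.0 - frac
    if frac > 0:
        t[lo + 1] = frac
    return t


def soft_targets(labels: Sequence[float]) -> np.ndarray:
    return np.stack([soft_target(float(l)) for l in labels])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class SoftmaxPrediction:
    p: tuple          # (p_OFF, p_ON, p_DYS)
    subject_id: str
    start_s: float

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.shape != (3,) or np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("p must be 3 non-negative probabilities summing to 1")
        self.p = tuple(float(v) for v in p)

    @property
    def argmax(self) -> int:
        # ties break toward the lower class index (conservative toward OFF)
        p = np.asarray(self.p)
        return int(np.flatnonzero(p == p.max())[0])


@dataclass
class Member:
    network: Network
    subject_subset: tuple
    seed: int
    history: list = field(default_factory=list)   # training loss per epoch
    config: Optional[CNNConfig] = None


@dataclass
class EnsembleModel:
    members: list        # of Member
    config: CNNConfig

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")


def _dataset_arrays(windows: Sequence[MinuteWindow]):
    x = np.stack([w.values.T for w in windows]).astype(np.float32)  # (N, 3, 3600)
    t = soft_targets([w.label for w in windows]).astype(np.float32)
    return x, t


def _epoch(net, opt, x, t, batch, order):
    losses = []
    for i in range(0, order.size, batch):
        sel = order[i: i + batch]
        logits = net.forward(x[sel], training=True)
        loss, dlogits = soft_cross_entropy(logits, t[sel])
        net.backward(dlogits)
        opt.step()
        losses.append(loss * sel.size)
    return float(np.sum(losses) / order.size)


def _eval_loss(net, x, t, batch=256):
    total = 0.0
    for i in range(0, x.shape[0], batch):
        logits = net.forward(x[i: i + batch], training=False)
        loss, _ = soft_cross_entropy(logits, t[i: i + batch])
        total += loss * min(batch, x.shape[0] - i)
    return total / x.shape[0]


def train_member(train_windows: Sequence[MinuteWindow], subject_subset: Sequence[str],
                 config: CNNConfig, rng: np.random.Generator,
                 test_subjects: Sequence[str] = ()) -> Member:
    """Train one ensemble member on its subject subset's windows.

    With early stopping enabled and >= 4 subjects in the subset, one subject
    is held out as a validation split and the best-validation weights are
    restored.  Deterministic for a fixed rng state.
    """
    subset = tuple(subject_subset)
    leaked = set(subset) & set(test_subjects)
    if leaked:
        raise LeakageError(f"test subjects {sorted(leaked)} in member subset")
    windows = [w for w in train_windows
               if w.subject_id in set(subset) and w.label is not None]
    leaked = {w.subject_id for w in windows} & set(test_subjects)
    if leaked:
        raise LeakageError(f"windows from test subjects {sorted(leaked)} in training data")
    if not windows:
        raise ValueError("no training windows for this subject subset")

    seed = int(rng.integers(0, 2**31 - 1))
    net_rng = np.random.default_rng(seed)
    net = build_cnn(config, net_rng)
    member = Member(net, subset, seed, config=config)
    if config.epochs <= 0:
        return member

    val_windows: list[MinuteWindow] = []
    if config.early_stopping and len(subset) >= 4:
        val_subject = subset[int(net_rng.integers(len(subset)))]
        val_windows = [w for w in windows if w.subject_id == val_subject]
        rest = [w for w in windows if w.subject_id != val_subject]
        if rest:
            windows = rest
    x, t = _dataset_arrays(windows)
    xv, tv = _dataset_arrays(val_windows) if val_windows else (None, None)

    opt = Adam(net.parameters(), lr=config.learning_rate)
    best, best_state, since_best = np.inf, None, 0
    for _ in range(config.epochs):
        order = net_rng.permutation(x.shape[0])
        member.history.append(_epoch(net, opt, x, t, config.batch_size, order))
        if xv is not None:
            vloss = _eval_loss(net, xv, tv)
            if vloss < best - 1e-5:
                best, best_state, since_best = vloss, net.get_state(), 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    if best_state is not None:
        net.set_state(best_state)
    refresh_batchnorm(net, x, batch=config.batch_size)
    return member


def train_ensemble(dataset: WindowedDataset, train_subjects: Sequence[str],
                   config: CNNConfig, rng: np.random.Generator,
                   test_subjects: Sequence[str] = ()) -> EnsembleModel:
    """Train ``config.n_members`` networks on random subject subsets of size
    min(subset_size, n_train)."""
    train_subjects = sorted(set(train_subjects))
    leaked = set(train_subjects) & set(test_subjects)
    if leaked:
        raise LeakageError(f"subjects {sorted(leaked)} are both train and test")
    members = []
    size = min(config.subset_size, len(train_subjects))
    for _ in range(config.n_members):
        subset = tuple(sorted(rng.choice(train_subjects, size=size, replace=False)))
        members.append(train_member(dataset.windows, subset, config, rng, test_subjects))
    return EnsembleModel(members, config)


def predict(ensemble: EnsembleModel, windows: Sequence[MinuteWindow],
            batch: int = 256) -> list[SoftmaxPrediction]:
    """Mean of member softmax vectors for each window."""
    if not windows:
        return []
    x = np.stack([w.values.T for w in windows]).astype(np.float32)
    acc = np.zeros((x.shape[0], N_CLASSES))
    for member in ensemble.members:
        for i in range(0, x.shape[0], batch):
            logits = member.network.forward(x[i: i + batch], training=False)
            acc[i: i + batch] += softmax(logits)
    acc /= len(ensemble.members)
    acc /= acc.sum(axis=1, keepdims=True)
    return [SoftmaxPrediction(tuple(acc[i]), w.subject_id, w.start_s)
            for i, w in enumerate(windows)]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: EnsembleModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "ensemble.json", "w") as fh:
        json.dump({"n_members": len(ensemble.members),
                   "config": ensemble.config.to_dict()}, fh, indent=1)
    for i, member in enumerate(ensemble.members):
        mdir = directory / f"member_{i:02d}"
        mdir.mkdir(exist_ok=True)
        state = member.network.get_state()
        np.savez(mdir / "weights.npz", **{f"a{j}": s for j, s in enumerate(state)})
        with open(mdir / "member.json", "w") as fh:
            json.dump({"subject_subset": list(member.subject_subset),
                       "seed": member.seed, "history": member.history}, fh, indent=1)


def load_ensemble(directory: str | Path) -> EnsembleModel:
    directory = Path(directory)
    with open(directory / "ensemble.json") as fh:
        meta = json.load(fh)
    cfg_d = meta["config"]
    cfg_d["channels"] = tuple(cfg_d["channels"])
    cfg_d["temporal"] = tuple(tuple(p) for p in cfg_d["temporal"])
    config = CNNConfig(**cfg_d)
    members = []
    for i in range(meta["n_members"]):
        mdir = directory / f"member_{i:02d}"
        with open(mdir / "member.json") as fh:
            md = json.load(fh)
        net = build_cnn(config, np.random.default_rng(md["seed"]))
        with np.load(mdir / "weights.npz") as z:
            net.set_state([z[f"a{j}"] for j in range(len(z.files))])
        members.append(Member(net, tuple(md["subject_subset"]), md["seed"],
                              md["history"], config))
    return EnsembleModel(members, config)
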