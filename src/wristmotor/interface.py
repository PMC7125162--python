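"""Command-line interface, configuration loading, and run manifests.

Subcommands cover each pipeline stage (``simulate``, ``preprocess``,
``augment``, ``train``, ``predict``, ``evaluate``) plus ``demo``, which runs
the full desk-scale LOSO experiment from a single seed, and ``report``,
which renders a saved report.json as text.  Every run writes a manifest
with the fully materialized configuration, all derived seeds, and SHA-256
content hashes of its inputs, so any two runs with identical manifests
produce byte-identical outputs.

One master ``--seed`` is threaded to every random consumer through
:func:`derive_seed`, which hashes ``"<stage>:<seed>"`` (CRC-32, kept below
2**31) so stages draw from disjoint, reproducible streams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import zlib
from dataclasses import fields as dc_fields
from pathlib import Path

import click
import numpy as np
import yaml

from . import evaluate as ev
from . import model as mo
from . import postprocess as po
from . import preprocess as pp
from . import simulate as sim
from .augment import augment_training_set, LeakageError

__all__ = ["main", "cli", "derive_seed", "load_config", "run_demo"]

log = logging.getLogger("wristmotor")

EXIT_OK, EXIT_ERROR, EXIT_VALIDATION = 0, 1, 2


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return zlib.crc32(f"{stage}:{int(master)}".encode()) % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _setup_logging(verbose: bool) -> None:
    logging.basicConfig(
        stream=sys.stderr, level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_CONFIG_SECTIONS = {
    "simulation": sim.SimulationConfig,
    "filter": pp.FilterSpec,
    "cnn": mo.CNNConfig,
    "experiment": None,  # flat keys: stride_s, rotate, score_augmented, ...
}
_EXPERIMENT_KEYS = {"stride_s", "rotate", "score_augmented", "variance_threshold",
                    "loess_span", "loess_degree", "seed"}


def load_config(path: str | Path) -> dict:
    """Load a YAML config, reject unknown keys, materialize every default.

    The returned tree echoes all defaults, so a run's manifest is fully
    self-describing.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise sim.ConfigError("config root must be a mapping")
    unknown = set(raw) - set(_CONFIG_SECTIONS)
    if unknown:
        raise sim.ConfigError(f"unknown config sections: {sorted(unknown)}")
    out: dict = {}
    for section, cls in _CONFIG_SECTIONS.items():
        given = raw.get(section, {}) or {}
        if section == "experiment":
            bad = set(given) - _EXPERIMENT_KEYS
            if bad:
                raise sim.ConfigError(f"unknown keys in [experiment]: {sorted(bad)}")
            defaults = {"stride_s": 5, "rotate": True, "score_augmented": False,
                        "variance_threshold": pp.VARIANCE_THRESHOLD_G2,
                        "loess_span": 0.25, "loess_degree": 2, "seed": 0}
            defaults.update(given)
            out[section] = defaults
            continue
        allowed = {f.name for f in dc_fields(cls)}
        bad = set(given) - allowed
        if bad:
            raise sim.ConfigError(f"unknown keys in [{section}]: {sorted(bad)}")
        obj = cls(**given)
        out[section] = obj.to_dict() if hasattr(obj, "to_dict") else {
            f.name: getattr(obj, f.name) for f in dc_fields(cls)}
    return out


def _experiment_config(cfg: dict, seed: int) -> ev.ExperimentConfig:
    fc = cfg.get("filter", {})
    cnn_d = dict(cfg.get("cnn", {})) or {}
    if cnn_d:
        cnn_d["channels"] = tuple(cnn_d["channels"])
        cnn_d["temporal"] = tuple(tuple(p) for p in cnn_d["temporal"])
    exp = cfg.get("experiment", {})
    return ev.ExperimentConfig(
        filter_spec=pp.FilterSpec(**fc) if fc else pp.FilterSpec(),
        cnn=mo.CNNConfig(**cnn_d) if cnn_d else mo.CNNConfig(),
        stride_s=exp.get("stride_s", 5),
        rotate=exp.get("rotate", True),
        score_augmented=exp.get("score_augmented", False),
        variance_threshold=exp.get("variance_threshold", pp.VARIANCE_THRESHOLD_G2),
        loess_span=exp.get("loess_span", 0.25),
        loess_degree=exp.get("loess_degree", 2),
        seed=seed,
    )


def _write_manifest(run_dir: Path, command: str, seed: int, config_echo: dict,
                    inputs: list[Path]) -> None:
    manifest = {
        "command": command,
        "seed": seed,
        "derived_seeds": {s: derive_seed(seed, s)
                          for s in ("simulate", "experiment", "augment", "train")},
        "config": config_echo,
        "input_hashes": {str(p): _sha256(p) for p in inputs if p.is_file()},
    }
    with open(run_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _json_report(report: dict) -> dict:
    return {k: v for k, v in report.items() if not k.startswith("_")}


# ---------------------------------------------------------------------------
# demo composition (also used by the acceptance script)
# ---------------------------------------------------------------------------

DEMO_SIMULATION = dict(n_subjects=8, session_minutes_range=(45, 45))
DEMO_CNN = dict(channels=mo.CHANNEL_SCHEDULES["reduced"], fc_hidden=64,
                epochs=4, batch_size=64, n_members=1, early_stopping=False)


def run_demo(seed: int, out_dir: Path, n_subjects: int = 8,
             session_minutes: int = 45, epochs: int = 4,
             n_members: int = 1) -> dict:
    """Desk-scale end-to-end LOSO experiment: simulate, run, export.

    Uses the reduced channel schedule and a small cohort so the whole
    experiment runs in minutes on one CPU.
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = sim.SimulationConfig(n_subjects=n_subjects,
                               session_minutes_range=(session_minutes, session_minutes),
                               seed=derive_seed(seed, "simulate"))
    recordings, tracks = sim.simulate_cohort(cfg)
    cnn = mo.CNNConfig(**{**DEMO_CNN, "epochs": epochs, "n_members": n_members})
    exp = ev.ExperimentConfig(cnn=cnn, seed=derive_seed(seed, "experiment"))
    report = ev.run_loso_experiment(recordings, tracks, exp)
    for series in report["_series"].values():
        po.write_day_curve(series, out_dir / "daycurves")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(_json_report(report), fh, indent=1, sort_keys=True)
    np.savetxt(out_dir / "confusion.csv", np.array(report["confusion"]),
               fmt="%d", delimiter=",", header="OFF,ON,DYS", comments="")
    _write_manifest(out_dir, "demo", seed,
                    {"simulation": cfg.to_dict(), "cnn": cnn.to_dict()}, [])
    return report


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group(help="Motor-state detection pipeline for wrist accelerometry.")
@click.option("--verbose", is_flag=True, help="Debug logging to stderr.")
def cli(verbose):
    _setup_logging(verbose)


@cli.command(help="Generate a synthetic cohort into a directory.")
@click.option("--out", "out_dir", type=click.Path(path_type=Path), required=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--subjects", type=int, default=8, show_default=True)
@click.option("--minutes", type=int, default=45, show_default=True,
              help="Session length per subject.")
@click.option("--config", "config_path", type=click.Path(exists=True, path_type=Path),
              default=None, help="YAML config; [simulation] section is used.")
def simulate(out_dir, seed, subjects, minutes, config_path):
    kw = {}
    if config_path:
        kw = {k: v for k, v in load_config(config_path)["simulation"].items()}
        kw["class_transition"] = np.array(kw["class_transition"])
        kw["activity_transition"] = np.array(kw["activity_transition"])
    kw.update(n_subjects=subjects, session_minutes_range=(minutes, minutes),
              seed=derive_seed(seed, "simulate"))
    cfg = sim.SimulationConfig(**kw)
    recordings, tracks = sim.simulate_cohort(cfg)
    sim.write_cohort(recordings, tracks, out_dir, cfg)
    click.echo(f"wrote {len(recordings)} subjects to {out_dir}")


@cli.command(help="Filter, resample and window a cohort directory into windows.h5.")
@click.option("--cohort", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--out", "out_dir", type=click.Path(path_type=Path), required=True)
def preprocess(cohort, out_dir):
    recordings, tracks = sim.read_cohort(cohort)
    track_by_id = {t.subject_id: t for t in tracks}
    merged = pp.WindowedDataset()
    for rec in recordings:
        ds = pp.preprocess_recording(rec, track_by_id[rec.subject_id])
        merged.windows += ds.windows
        merged.discard_log += ds.discard_log
    out_dir.mkdir(parents=True, exist_ok=True)
    pp.write_windows(merged, out_dir / "windows.h5", out_dir / "discard_log.csv")
    _write_manifest(out_dir, "preprocess", 0, {}, sorted(cohort.glob("*.csv")))
    click.echo(f"kept {len(merged.windows)} windows, "
               f"discarded {len(merged.discard_log)} minutes")


@cli.command(help="Slide + rotate a windows.h5 training set.")
@click.option("--windows", "windows_path", type=click.Path(exists=True, path_type=Path),
              required=True)
@click.option("--out", "out_path", type=click.Path(path_type=Path), required=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--stride-seconds", type=int, default=5, show_default=True)
@click.option("--no-rotation", is_flag=True)
@click.option("--test-subject", multiple=True,
              help="Subjects that must NOT appear (leakage check).")
def augment(windows_path, out_path, seed, stride_seconds, no_rotation, test_subject):
    ds = pp.read_windows(windows_path)
    rng = np.random.default_rng(derive_seed(seed, "augment"))
    out = augment_training_set(ds, rng, stride_seconds, not no_rotation,
                               test_subjects=test_subject)
    pp.write_windows(out, out_path)
    click.echo(f"{len(ds.windows)} -> {len(out.windows)} windows")


@cli.command(help="Train a CNN ensemble on a windows.h5 file.")
@click.option("--windows", "windows_path", type=click.Path(exists=True, path_type=Path),
              required=True)
@click.option("--out", "out_dir", type=click.Path(path_type=Path), required=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--schedule", type=click.Choice(sorted(mo.CHANNEL_SCHEDULES)),
              default="caption", show_default=True)
@click.option("--members", type=int, default=5, show_default=True)
@click.option("--epochs", type=int, default=10, show_default=True)
def train(windows_path, out_dir, seed, schedule, members, epochs):
    ds = pp.read_windows(windows_path)
    config = mo.CNNConfig.named(schedule, n_members=members, epochs=epochs)
    rng = np.random.default_rng(derive_seed(seed, "train"))
    ensemble = mo.train_ensemble(ds, ds.subjects(), config, rng)
    mo.save_ensemble(ensemble, out_dir)
    _write_manifest(Path(out_dir), "train", seed, {"cnn": config.to_dict()},
                    [Path(windows_path)])
    click.echo(f"trained {members} member(s); saved to {out_dir}")


@cli.command(help="Predict softmax/expCNN for a windows.h5 file.")
@click.option("--model", "model_dir", type=click.Path(exists=True, path_type=Path),
              required=True)
@click.option("--windows", "windows_path", type=click.Path(exists=True, path_type=Path),
              required=True)
@click.option("--out", "out_dir", type=click.Path(path_type=Path), required=True)
def predict(model_dir, windows_path, out_dir):
    ensemble = mo.load_ensemble(model_dir)
    ds = pp.read_windows(windows_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    preds = mo.predict(ensemble, ds.windows)
    by_subject: dict[str, list] = {}
    for p in preds:
        by_subject.setdefault(p.subject_id, []).append(p)
    for sid, ps in sorted(by_subject.items()):
        series = po.build_series(ps)
        po.write_day_curve(series, out_dir)
    click.echo(f"predicted {len(preds)} windows for {len(by_subject)} subjects")


@cli.command(help="Full desk-scale LOSO experiment from one seed.")
@click.option("--out", "out_dir", type=click.Path(path_type=Path), required=True)
@click.option("--seed", type=int, default=11, show_default=True)
@click.option("--subjects", type=int, default=8, show_default=True)
@click.option("--minutes", type=int, default=45, show_default=True)
@click.option("--epochs", type=int, default=4, show_default=True)
@click.option("--members", type=int, default=1, show_default=True)
def demo(out_dir, seed, subjects, minutes, epochs, members):
    report = run_demo(seed, out_dir, subjects, minutes, epochs, members)
    m = report["metrics"]
    click.echo(f"balanced accuracy {m['balanced_accuracy']:.3f}, "
               f"kappa {m['kappa']:.3f} over {m['n']} scored minutes")


@cli.command(name="evaluate", help="Recompute metrics from a saved report.json.")
@click.option("--report", "report_path", type=click.Path(exists=True, path_type=Path),
              required=True)
def evaluate_cmd(report_path):
    with open(report_path) as fh:
        report = json.load(fh)
    cm = ev.ConfusionMatrix3(np.array(report["confusion"]))
    m = ev.clinimetrics(cm)
    click.echo(json.dumps(m, indent=1, sort_keys=True))


@cli.command(name="report", help="Render a report.json as a text summary.")
@click.option("--report", "report_path", type=click.Path(exists=True, path_type=Path),
              required=True)
def report_cmd(report_path):
    with open(report_path) as fh:
        r = json.load(fh)
    m = r["metrics"]
    click.echo(f"scored minutes: {m['n']}")
    click.echo(f"balanced accuracy: {m['balanced_accuracy']:.3f}  kappa: {m['kappa']:.3f}")
    for cls, d in m["per_class"].items():
        click.echo(f"  {cls}: sens {d['sensitivity']:.3f} spec {d['specificity']:.3f} "
                   f"ppv {d['ppv']:.3f} npv {d['npv']:.3f}")
    for w, d in r["correlations"].items():
        click.echo(f"  window {w}: r_brady {d['brady']['r']:.3f} r_dys {d['dys']['r']:.3f}")


@cli.command(name="model-summary", help="Per-block shapes and parameter count.")
@click.option("--schedule", type=click.Choice(sorted(mo.CHANNEL_SCHEDULES)),
              default="caption", show_default=True)
def model_summary(schedule):
    config = mo.CNNConfig.named(schedule)
    lengths = mo.block_lengths(config)
    click.echo("block  out_channels  kernel  stride  out_length")
    for i, (c, (k, s), l) in enumerate(zip(config.channels, config.temporal, lengths), 1):
        click.echo(f"{i:5d}  {c:12d}  {k:6d}  {s:6d}  {l:10d}")
    click.echo(f"flatten: {mo.flatten_length(config)}  "
               f"fc: {config.fc_hidden} -> 3  "
               f"parameters: {mo.parameter_count(config)}")


def main(argv=None) -> int:
    """Entry point with the documented exit-code contract (0 / 1 / 2)."""
    try:
        cli.main(args=argv, standalone_mode=False)
        return EXIT_OK
    except click.exceptions.Exit as exc:          # --help and friends
        return int(exc.exit_code)
    except click.UsageError as exc:
        click.echo(f"usage error: {exc}", err=True)
        return EXIT_VALIDATION
    except (sim.ConfigError, LeakageError, FileNotFoundError, ValueError) as exc:
        click.echo(f"validation error: {exc}", err=True)
        return EXIT_VALIDATION
    except Exception as exc:                      # pragma: no cover
        click.echo(f"error: {exc}", err=True)
        return EXIT_ERROR


if __name__ == "__main__":
    sys.exit(main())
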