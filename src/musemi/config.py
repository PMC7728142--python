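"""Flat-YAML run configuration, seed derivation, pipeline driver, fixtures.

One master seed in the config drives everything; each stage receives a seed
spawned from it by a fixed key (generation=10, model=30), so adding a stage
never perturbs an earlier stage's randomness and any stage can be re-run
standalone to bit-identical tensors.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .experiments import (
    VALIDATION_WINDOW_GRID,
    explore_grid,
    report,
    validate_continuous,
)
from .io_mindmonitor import align_and_interpolate, write_recording
from .model import ModelConfig, repeated_evaluation
from .preprocessing import (
    NoiseRules,
    SessionConfig,
    build_sample,
    reject_noisy,
)
from .synthetic import (
    SyntheticConfig,
    generate_continuous_dataset,
    generate_continuous_session,
    generate_dataset,
    generate_trial,
    inject_artifacts,
)

log = logging.getLogger("musemi")

SCHEMA_VERSION = 1

#: Allowed flat-YAML keys with defaults (None = required).
CONFIG_SCHEMA: dict[str, object] = {
    "schema_version": SCHEMA_VERSION,
    "mode": None,                      # explore | validate | train
    "seed": None,
    "out_dir": "runs/run",
    # generator
    "n_trials_per_class": 20,
    "n_participants": 3,
    "n_sessions_per_participant": 20,
    "class_effect": 0.3,
    "noise_sd": 0.5,
    "ar_coefficient": 0.97,
    "p_missing": 0.0,
    "p_flatline": 0.0,
    "p_outlier": 0.0,
    # windowing
    "session_sizes": [2.0],
    "window_sizes": [2.0],
    "overlap": 0.5,
    "head_discard": 2.0,
    "max_gap": 0.5,
    "min_recordings_per_subject": 14,
    # training
    "iterations": 5,
    "max_epochs": 200,
    "batch_size": 16,
    "learning_rate": 1e-3,
    "early_stop_patience": 10,
}

MODES = ("explore", "validate", "train")


class ConfigError(ValueError):
    """A run configuration violates the schema."""


@dataclass
class RunManifest:
    """Everything needed to re-run a stage to identical tensors."""

    config: dict
    master_seed: int
    stage_seeds: dict[str, int]
    outputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    version: str = __version__

    def to_dict(self) -> dict:
        return asdict(self)


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed spawned from the master seed."""
    key = {"generate": 10, "preprocess": 20, "model": 30}[stage]
    return int(
        np.random.SeedSequence(master, spawn_key=(key,)).generate_state(1)[0]
        % 2**31
    )


def load_config(path) -> dict:
    """Load and validate a flat YAML config; unknown keys are errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    unknown = sorted(set(raw) - set(CONFIG_SCHEMA))
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    cfg = {**CONFIG_SCHEMA, **raw}
    missing = sorted(k for k, v in cfg.items() if v is None)
    if missing:
        raise ConfigError(f"missing required key(s): {', '.join(missing)}")
    if cfg["mode"] not in MODES:
        raise ConfigError(f"mode must be one of {MODES}")
    if int(cfg["schema_version"]) != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {cfg['schema_version']}")
    if not cfg["session_sizes"] or not cfg["window_sizes"]:
        raise ConfigError("session_sizes and window_sizes must be non-empty")
    if min(cfg["window_sizes"]) > max(cfg["session_sizes"]) + 1e-12:
        raise ConfigError(
            "infeasible grid: every window size exceeds every session size"
        )
    return cfg


def _synth_config(cfg: dict) -> SyntheticConfig:
    return SyntheticConfig(
        class_effect=cfg["class_effect"], noise_sd=cfg["noise_sd"],
        ar_coefficient=cfg["ar_coefficient"], p_missing=cfg["p_missing"],
        p_flatline=cfg["p_flatline"], p_outlier=cfg["p_outlier"],
    )


def _model_config(cfg: dict, seed: int) -> ModelConfig:
    return ModelConfig(
        max_epochs=cfg["max_epochs"], batch_size=cfg["batch_size"],
        learning_rate=cfg["learning_rate"],
        early_stop_patience=cfg["early_stop_patience"], seed=seed,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config_path) -> Path:
    """Execute generate -> preprocess -> experiment per the config.

    Returns the run directory; a :class:`RunManifest` plus all result
    tables/plots are written there.
    """
    cfg = load_config(config_path)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    seeds = {s: stage_seed(master, s) for s in ("generate", "preprocess", "model")}
    synth = _synth_config(cfg)
    model_cfg = _model_config(cfg, seeds["model"])
    rules = NoiseRules(
        min_recordings_per_subject=cfg["min_recordings_per_subject"]
    )
    with_artifacts = any(
        cfg[k] > 0 for k in ("p_missing", "p_flatline", "p_outlier")
    )

    if cfg["mode"] in ("explore", "train"):
        recs = generate_dataset(
            synth, cfg["n_trials_per_class"], seeds["generate"],
            participant_id="P1", with_artifacts=with_artifacts,
        )
        recs = [align_and_interpolate(r, cfg["max_gap"]) for r in recs]
        kept, rejected = reject_noisy(recs, rules)
        for rec, reason in rejected:
            log.info("rejected %s: %s", rec.recording_id, reason)
        if cfg["mode"] == "explore":
            results = explore_grid(
                kept, cfg["session_sizes"], cfg["window_sizes"], model_cfg,
                SessionConfig(
                    session_size=cfg["session_sizes"][0],
                    window_size=min(cfg["window_sizes"]),
                    overlap_fraction=cfg["overlap"],
                    head_discard=cfg["head_discard"],
                ),
                n_iterations=cfg["iterations"],
            )
        else:   # train: single cell
            scfg = SessionConfig(
                session_size=cfg["session_sizes"][0],
                window_size=cfg["window_sizes"][0],
                overlap_fraction=cfg["overlap"],
                head_discard=cfg["head_discard"],
            )
            samples = [build_sample(r, scfg) for r in kept]
            rows, summary = repeated_evaluation(
                samples, model_cfg, cfg["iterations"]
            )
            results = None
            with open(out_dir / "train_results.json", "w") as fh:
                json.dump(
                    {"summary": summary, "iterations": [asdict(r) for r in rows]},
                    fh, indent=2,
                )
    else:   # validate
        by_pid = {}
        for p in range(cfg["n_participants"]):
            pid = f"P{p + 1}"
            pseed = int(
                np.random.SeedSequence(seeds["generate"], spawn_key=(p,))
                .generate_state(1)[0] % 2**31
            )
            recs = generate_continuous_dataset(
                synth, cfg["n_sessions_per_participant"], pseed, pid,
                with_artifacts=with_artifacts,
            )
            recs = [align_and_interpolate(r, cfg["max_gap"]) for r in recs]
            kept, rejected = reject_noisy(
                recs, NoiseRules(min_recordings_per_subject=5)
            )
            for rec, reason in rejected:
                log.info("rejected %s: %s", rec.recording_id, reason)
            by_pid[pid] = kept
        results = validate_continuous(
            by_pid,
            window_grid=[w for w in cfg["window_sizes"]],
            session_size=cfg["session_sizes"][0],
            model_cfg=model_cfg,
            n_iterations=cfg["iterations"],
        )

    manifest = RunManifest(config=cfg, master_seed=master, stage_seeds=seeds)
    written = report(results, out_dir, manifest.to_dict())
    manifest.outputs = {str(p): _sha256(p) for p in written if p.suffix != ".png"}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True, default=str)
    return out_dir


def make_fixtures(out_dir, seed: int = 0) -> list[Path]:
    """Write the canonical small CSV fixtures used by the test suite.

    Five files: a clean labelled trial, a flat-line trial, an outlier-spiked
    trial, a trial with a missing-value gap, and one continuous session.
    Trials are shortened to 6 s to keep the files light; the continuous
    session keeps the full 60 s protocol so it segments into 10 blocks.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(trial_duration=6.0)
    files = []

    def _write(name, rec):
        p = out / name
        write_recording(rec, p)
        files.append(p)

    _write("clean_trial.csv", generate_trial(cfg, "left", seed))

    flat = inject_artifacts(
        generate_trial(cfg, "right", seed + 1),
        SyntheticConfig(trial_duration=6.0, p_flatline=1.0), seed + 1,
    )
    _write("flatline_trial.csv", flat)

    spiky = inject_artifacts(
        generate_trial(cfg, "left", seed + 2),
        SyntheticConfig(trial_duration=6.0, p_outlier=0.05), seed + 2,
    )
    _write("outlier_trial.csv", spiky)

    gap = generate_trial(cfg, "right", seed + 3)
    gap.values[200:240, :] = np.nan    # ~0.16 s gap, repairable
    _write("missing_gap_trial.csv", gap)

    _write("continuous_session.csv",
           generate_continuous_session(SyntheticConfig(), seed + 4, "P1"))
    return files
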