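"""The two evaluation studies: grid exploration and continuous validation.

Study 1 (:func:`explore_grid`) sweeps session size S (the response time) and
window size W over a grid, retraining and evaluating the classifier for
every feasible (S, W) cell, to locate the smallest response time whose
accuracy stays acceptable.

Study 2 (:func:`validate_continuous`) checks the selected 2 s response time
operationally: per-participant models are trained on samples cut from
continuous sessions — 2 s of signal after every hand-change mark — for a
set of window sizes, five random splits each, and the per-participant and
averaged accuracies are tabulated (window sizes as rows, participants as
columns, plus averaged columns).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_mindmonitor import BandPowerRecording
from .model import ModelConfig, repeated_evaluation
from .preprocessing import (
    SessionConfig,
    WindowedSample,
    build_sample,
    segment_continuous,
)

#: Window sizes used by the continuous validation study (seconds).
VALIDATION_WINDOW_GRID: tuple[float, ...] = (2.0, 1.5, 1.0, 0.5, 0.25, 0.1, 0.05)

#: Accuracy an (S, W) cell must hold to count as acceptable.
STABILITY_THRESHOLD = 0.8


@dataclass
class GridResult:
    """Mean/sd test accuracy per feasible (session_size, window_size) cell."""

    frame: pd.DataFrame                    # columns: session_size, window_size,
    #                                        mean_test_acc, sd, n_iterations
    provenance: dict = field(default_factory=dict)
    skipped: list[tuple[float, float, str]] = field(default_factory=list)

    def stable_onset(self, window_size: float,
                     threshold: float = STABILITY_THRESHOLD) -> float | None:
        """Smallest S from which accuracy stays >= threshold for this W."""
        rows = self.frame[self.frame.window_size == window_size].sort_values(
            "session_size"
        )
        onset = None
        for _, row in rows.iterrows():
            if row.mean_test_acc >= threshold:
                if onset is None:
                    onset = row.session_size
            else:
                onset = None
        return onset


@dataclass
class ValidationTable:
    """Table-2-style layout: one row per window size, columns per participant."""

    frame: pd.DataFrame                    # index: window_size; columns:
    #                                        TrAcc{p}/VaAcc{p}/TeAcc{p} per
    #                                        participant + TrAvg/VaAvg/TeAvg
    best: tuple[float, float] | None = None   # (window_size, TeAvg)
    provenance: dict = field(default_factory=dict)
    excluded: list[tuple[str, str]] = field(default_factory=list)


def explore_grid(
    recordings: list[BandPowerRecording],
    session_grid: list[float],
    window_grid: list[float],
    model_cfg: ModelConfig,
    base_cfg: SessionConfig | None = None,
    n_iterations: int = 5,
) -> GridResult:
    """Train and evaluate over every feasible (session, window) cell.

    A cell is infeasible when W > S or when the recordings are too short for
    head-discard + S; infeasible cells are skipped and logged, not errors.
    """
    base = base_cfg or SessionConfig()
    min_duration = min(r.duration for r in recordings)
    rows = []
    skipped: list[tuple[float, float, str]] = []
    for S in session_grid:
        for W in window_grid:
            if W > S + 1e-12:
                skipped.append((S, W, "window exceeds session"))
                continue
            if base.head_discard + S > min_duration + 1e-9:
                skipped.append((S, W, "recordings too short"))
                continue
            cfg = SessionConfig(
                session_size=S, window_size=W,
                overlap_fraction=base.overlap_fraction,
                head_discard=base.head_discard,
                sampling_rate=base.sampling_rate,
            )
            samples = [build_sample(r, cfg) for r in recordings]
            _, summary = repeated_evaluation(samples, model_cfg, n_iterations)
            rows.append({
                "session_size": S, "window_size": W,
                "mean_test_acc": summary["test_acc"],
                "sd": summary["test_sd"], "n_iterations": n_iterations,
            })
    if not rows:
        raise ValueError("no feasible grid cells")
    frame = pd.DataFrame(rows)
    return GridResult(
        frame=frame,
        provenance={"model_cfg": asdict(model_cfg), "n_iterations": n_iterations,
                    "session_grid": list(session_grid),
                    "window_grid": list(window_grid)},
        skipped=skipped,
    )


def validate_continuous(
    recordings_by_participant: dict[str, list[BandPowerRecording]],
    window_grid: list[float] = VALIDATION_WINDOW_GRID,
    session_size: float = 2.0,
    model_cfg: ModelConfig | None = None,
    n_iterations: int = 5,
    offset: float = 0.0,
) -> ValidationTable:
    """Per-participant validation of the 2 s response time.

    Participants with fewer than 5 continuous recordings are excluded (and
    logged); each remaining participant gets, per window size, a 5-iteration
    repeated evaluation of a personal model on block samples built from the
    first ``session_size`` seconds after every mark.
    """
    cfg = model_cfg or ModelConfig()
    usable = {}
    excluded: list[tuple[str, str]] = []
    for pid, recs in sorted(recordings_by_participant.items()):
        if len(recs) < 5:
            excluded.append((pid, f"only {len(recs)} recordings (< 5)"))
        else:
            usable[pid] = recs
    if not usable:
        raise ValueError("no participant has enough recordings")

    participants = sorted(usable)
    rows = {}
    for W in window_grid:
        if W > session_size + 1e-12:
            continue
        row: dict[str, float] = {}
        for pid in participants:
            scfg = SessionConfig(
                session_size=session_size, window_size=W, head_discard=0.0,
                sampling_rate=usable[pid][0].sampling_rate,
            )
            samples: list[WindowedSample] = []
            for rec in usable[pid]:
                samples.extend(segment_continuous(rec, scfg, offset=offset))
            _, summary = repeated_evaluation(
                samples, cfg, n_iterations, participant_id=pid
            )
            row[f"TrAcc_{pid}"] = summary["train_acc"]
            row[f"VaAcc_{pid}"] = summary["val_acc"]
            row[f"TeAcc_{pid}"] = summary["test_acc"]
        row["TrAvg"] = float(np.mean([row[f"TrAcc_{p}"] for p in participants]))
        row["VaAvg"] = float(np.mean([row[f"VaAcc_{p}"] for p in participants]))
        row["TeAvg"] = float(np.mean([row[f"TeAcc_{p}"] for p in participants]))
        rows[W] = row

    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "window_size"
    best_ws = frame["TeAvg"].idxmax()
    return ValidationTable(
        frame=frame,
        best=(float(best_ws), float(frame.loc[best_ws, "TeAvg"])),
        provenance={"model_cfg": asdict(cfg), "session_size": session_size,
                    "n_iterations": n_iterations, "offset": offset,
                    "participants": participants},
        excluded=excluded,
    )


def report(
    results: GridResult | ValidationTable | None,
    out_dir,
    manifest: dict | None = None,
) -> list[Path]:
    """Write CSV + JSON tables, accuracy curves and a run manifest.

    Grid results additionally get one accuracy-vs-session-size plot per
    window size. Re-running on the same results overwrites deterministically.
    Returns the list of files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _dump_json(obj, name):
        p = out / name
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        written.append(p)

    _dump_json(manifest or {}, "manifest.json")

    if isinstance(results, GridResult):
        if len(results.frame):
            p = out / "grid_results.csv"
            results.frame.to_csv(p, index=False)
            written.append(p)
            _dump_json(
                {"provenance": results.provenance,
                 "skipped": [list(s) for s in results.skipped]},
                "grid_summary.json",
            )
            written.extend(_plot_grid(results, out))
    elif isinstance(results, ValidationTable):
        p = out / "validation_table.csv"
        results.frame.to_csv(p)
        written.append(p)
        _dump_json(
            {"best": list(results.best) if results.best else None,
             "provenance": results.provenance,
             "excluded": [list(e) for e in results.excluded]},
            "validation_summary.json",
        )
    return written


def _plot_grid(results: GridResult, out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for W, grp in results.frame.groupby("window_size"):
        fig, ax = plt.subplots(figsize=(5, 3.2))
        grp = grp.sort_values("session_size")
        ax.errorbar(grp.session_size, grp.mean_test_acc, yerr=grp.sd,
                    marker="o", capsize=3)
        ax.axhline(STABILITY_THRESHOLD, ls="--", color="gray", lw=0.8)
        ax.set_xlabel("session size (s)")
        ax.set_ylabel("test accuracy")
        ax.set_ylim(0, 1.02)
        ax.set_title(f"window size {W} s")
        fig.tight_layout()
        p = out / f"accuracy_vs_session_w{W}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    return written
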