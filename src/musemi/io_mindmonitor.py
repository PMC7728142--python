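"""Reading, writing and timing repair of Mind-Monitor-style band-power CSVs.

A recording holds the 20 log-PSD band-power signals (5 frequency bands x 4
headband channels) that the recording app exports, one row per sample at a
nominal 256 Hz. The canonical in-memory column order is the band-major vector

    [alpha^1..alpha^4, beta^1..beta^4, delta^1..delta^4,
     gamma^1..gamma^4, theta^1..theta^4]

over channels TP9, TP10, AF7, AF8 — regardless of the column order found in a
file. Missing cells are represented as NaN.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Headband electrode names, 10-20 system positions (ear / forehead sites).
CHANNELS: tuple[str, ...] = ("TP9", "TP10", "AF7", "AF8")

#: Frequency bands in the canonical (band-major, Greek-alphabetical) vector order.
BANDS: tuple[str, ...] = ("Alpha", "Beta", "Delta", "Gamma", "Theta")

#: The 20 canonical signal column names, band-major over channels.
BAND_COLUMNS: tuple[str, ...] = tuple(
    f"{band}_{channel}" for band in BANDS for channel in CHANNELS
)

N_SIGNALS = len(BAND_COLUMNS)

LEFT = "left"
RIGHT = "right"
UNLABELED = "unlabeled"
LABELS = (LEFT, RIGHT)

TIMESTAMP_FMT = "%.6f"
VALUE_FMT = "%.8g"


class ParseError(ValueError):
    """A recording file violates the expected schema."""


@dataclass
class BandPowerRecording:
    """A timestamped 20-signal band-power series with label and markers.

    Parameters
    ----------
    timestamps
        Sample times in seconds, strictly increasing, nominally 1/256 s apart.
    values
        ``(n_rows, 20)`` float array in canonical column order; NaN = missing.
    label
        ``"left"``, ``"right"`` or ``"unlabeled"``.
    markers
        ``(timestamp, mark_id)`` pairs, e.g. block boundaries in a continuous
        session; timestamps must lie within the recorded span.
    sampling_rate
        Nominal sampling rate in Hz.
    unrepairable
        Set by :func:`align_and_interpolate` when a missing run is too long to
        fill; downstream quality control rejects flagged recordings.
    artifacts
        Ground-truth bookkeeping written by the synthetic artifact injector
        (``flatline_channel``, ``missing``, ``outliers``); ``None`` for real
        or clean data.
    """

    timestamps: np.ndarray
    values: np.ndarray
    label: str = UNLABELED
    markers: list[tuple[float, int]] = field(default_factory=list)
    participant_id: str = ""
    sampling_rate: float = 256.0
    unrepairable: bool = False
    artifacts: dict | None = None
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_SIGNALS:
            raise ValueError(
                f"values must have exactly {N_SIGNALS} columns, "
                f"got shape {self.values.shape}"
            )
        if self.timestamps.shape[0] != self.values.shape[0]:
            raise ValueError("timestamps and values disagree on row count")
        if self.n_rows > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.label not in LABELS + (UNLABELED,):
            raise ValueError(f"label must be one of {LABELS + (UNLABELED,)!r}")
        if self.markers and self.n_rows:
            t0, t1 = self.timestamps[0], self.timestamps[-1]
            for t, _ in self.markers:
                if not (t0 <= t <= t1):
                    raise ValueError(f"marker at {t} outside [{t0}, {t1}]")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds, sample-count based (n / rate)."""
        return self.n_rows / self.sampling_rate

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self) -> "BandPowerRecording":
        return replace(
            self,
            timestamps=self.timestamps.copy(),
            values=self.values.copy(),
            markers=list(self.markers),
            artifacts=None if self.artifacts is None else dict(self.artifacts),
        )

    def equals(self, other: "BandPowerRecording", atol: float = 0.0) -> bool:
        """Field-wise equality; NaNs compare equal, values to ``atol``."""
        if self.n_rows != other.n_rows:
            return False
        if not np.allclose(self.timestamps, other.timestamps, atol=max(atol, 1e-9)):
            return False
        a, b = self.values, other.values
        if not np.array_equal(np.isnan(a), np.isnan(b)):
            return False
        ok = np.isclose(a, b, atol=atol, rtol=1e-7) | np.isnan(a)
        return (
            bool(ok.all())
            and self.label == other.label
            and self.participant_id == other.participant_id
            and len(self.markers) == len(other.markers)
            and all(
                abs(t1 - t2) <= 1e-9 and m1 == m2
                for (t1, m1), (t2, m2) in zip(self.markers, other.markers)
            )
        )


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------

def _parse_timestamps(raw: pd.Series) -> np.ndarray:
    """Accept float seconds or ISO-8601 datetimes; return float seconds."""
    try:
        return raw.astype(float).to_numpy()
    except (TypeError, ValueError):
        pass
    try:
        dt = pd.to_datetime(raw, format="ISO8601")
    except (TypeError, ValueError) as exc:
        raise ParseError(f"cannot parse TimeStamp column: {exc}") from None
    return (dt - dt.iloc[0]).dt.total_seconds().to_numpy()


def read_recording(path) -> BandPowerRecording:
    """Parse a Mind-Monitor-style CSV into a :class:`BandPowerRecording`.

    The file must have a ``TimeStamp`` column and the 20 ``Band_Channel``
    columns (any order). Optional columns: ``Marker`` (integer mark ids on
    boundary rows), ``Label`` and ``Participant`` (constant per recording).
    Blank band cells are flagged missing (NaN).
    """
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        names = header_line.split(",")
        seen: set[str] = set()
        for name in names:
            if name in seen and name in BAND_COLUMNS:
                raise ParseError(f"duplicated band column: {name}")
            seen.add(name)
        missing_cols = [c for c in BAND_COLUMNS if c not in seen]
        if missing_cols:
            raise ParseError(f"missing band column(s): {', '.join(missing_cols)}")
        if "TimeStamp" not in seen:
            raise ParseError("missing TimeStamp column")
        fh.seek(0)
        df = pd.read_csv(fh, dtype={"Label": str, "Participant": str})

    ts = _parse_timestamps(df["TimeStamp"])
    if len(ts) > 1 and not np.all(np.diff(ts) > 0):
        raise ParseError("non-monotone timestamps")

    values = df[list(BAND_COLUMNS)].to_numpy(dtype=float)

    markers: list[tuple[float, int]] = []
    if "Marker" in df.columns:
        mk = pd.to_numeric(df["Marker"], errors="coerce")
        for i in np.flatnonzero(mk.notna().to_numpy()):
            markers.append((float(ts[i]), int(mk.iloc[i])))

    label = UNLABELED
    if "Label" in df.columns:
        non_null = df["Label"].dropna()
        if len(non_null):
            label = str(non_null.iloc[0])
    participant = ""
    if "Participant" in df.columns:
        non_null = df["Participant"].dropna()
        if len(non_null):
            participant = str(non_null.iloc[0])

    from pathlib import Path

    return BandPowerRecording(
        timestamps=ts, values=values, label=label, markers=markers,
        participant_id=participant, recording_id=Path(path).stem,
    )


def write_recording(rec: BandPowerRecording, path) -> None:
    """Write a recording as CSV with a stable column order.

    Column order: ``TimeStamp``, the 20 canonical band columns, ``Marker``,
    ``Label``, ``Participant``. Lossless to :func:`read_recording` up to
    float formatting; write -> read -> write is byte-identical.
    """
    marker_by_row: dict[int, int] = {}
    for t, mid in rec.markers:
        row = int(np.argmin(np.abs(rec.timestamps - t))) if rec.n_rows else 0
        marker_by_row[row] = mid

    buf = io.StringIO()
    buf.write("TimeStamp," + ",".join(BAND_COLUMNS) + ",Marker,Label,Participant\n")
    label = "" if rec.label == UNLABELED else rec.label
    for i in range(rec.n_rows):
        cells = [TIMESTAMP_FMT % rec.timestamps[i]]
        for v in rec.values[i]:
            cells.append("" if np.isnan(v) else VALUE_FMT % v)
        cells.append(str(marker_by_row[i]) if i in marker_by_row else "")
        cells.append(label)
        cells.append(rec.participant_id)
        buf.write(",".join(cells) + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Alignment and gap repair
# ---------------------------------------------------------------------------

def _fill_runs(col: np.ndarray, max_run: int) -> bool:
    """Fill NaN runs of length <= max_run in place; return False if impossible.

    Interior runs are filled by linear interpolation between the bounding
    valid samples; edge runs by nearest-value extension. A run longer than
    ``max_run``, or fewer than 2 valid samples, makes the column unrepairable.
    """
    isnan = np.isnan(col)
    if (~isnan).sum() < 2:
        return False
    if not isnan.any():
        return True
    n = len(col)
    idx = np.flatnonzero(isnan)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    if any(len(run) > max_run for run in runs):
        return False
    for run in runs:
        lo, hi = run[0] - 1, run[-1] + 1
        if lo < 0:
            col[run] = col[hi]
        elif hi >= n:
            col[run] = col[lo]
        else:
            col[run] = np.interp(run, [lo, hi], [col[lo], col[hi]])
    return True


def align_and_interpolate(
    rec: BandPowerRecording, max_gap: float = 0.5
) -> BandPowerRecording:
    """Resample onto a uniform 1/rate grid and fill short missing runs.

    Samples are snapped to the nearest grid point (first sample wins on a
    collision), so cells that were present are carried over unaltered.
    Missing runs no longer than ``max_gap`` seconds are filled by linear
    interpolation (nearest-value at the edges). Any longer run — or a signal
    with fewer than 2 valid samples — flags the recording ``unrepairable``
    and leaves its values untouched for the caller to reject.
    """
    if rec.n_rows < 2:
        out = rec.copy()
        out.unrepairable = True
        return out

    fs = rec.sampling_rate
    t0, t1 = rec.timestamps[0], rec.timestamps[-1]
    n_grid = int(np.floor((t1 - t0) * fs + 1e-9)) + 1
    grid = t0 + np.arange(n_grid) / fs

    values = np.full((n_grid, N_SIGNALS), np.nan)
    slots = np.rint((rec.timestamps - t0) * fs).astype(int)
    np.clip(slots, 0, n_grid - 1, out=slots)
    # reversed iteration => on collision the earlier sample wins
    for i in range(rec.n_rows - 1, -1, -1):
        values[slots[i]] = rec.values[i]

    max_run = int(np.floor(max_gap * fs + 1e-9))
    ok = all(_fill_runs(values[:, j], max_run) for j in range(N_SIGNALS))
    if not ok:
        out = rec.copy()
        out.unrepairable = True
        return out

    markers = [(float(grid[np.argmin(np.abs(grid - t))]), mid) for t, mid in rec.markers]
    return BandPowerRecording(
        timestamps=grid, values=values, label=rec.label, markers=markers,
        participant_id=rec.participant_id, sampling_rate=fs,
        artifacts=None if rec.artifacts is None else dict(rec.artifacts),
        recording_id=rec.recording_id,
    )
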