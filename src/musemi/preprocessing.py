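"""Session truncation, overlapping sliding windows and window averaging.

The feature pipeline: discard the first 2 s of a recording (setup noise),
keep the first ``session_size`` seconds (the classifier's response time),
cut that session into sliding windows with 50% overlap, and compress every
window into one 20-component vector by the arithmetic mean of each signal.
The resulting ``(timesteps, 20)`` tensor — ``2n - 1`` windows for a session
holding ``n = floor(S/W)`` whole windows at 50% overlap — is the network
input.

All row ranges are half-open ``[start, end)``, 0-based, relative to the
recording's first sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from collections import Counter

import numpy as np

from .io_mindmonitor import LABELS, N_SIGNALS, RIGHT, LEFT, BandPowerRecording

#: Session sizes explored by the grid study (seconds).
DEFAULT_SESSION_GRID: tuple[float, ...] = (
    0.01, 0.025, 0.05, 0.1, 0.25, 0.5,
    *[round(1 + 0.5 * k, 1) for k in range(39)],   # 1, 1.5, ..., 20
)

#: Window sizes explored by the grid study (seconds).
DEFAULT_WINDOW_GRID: tuple[float, ...] = (
    0.01, 0.025, 0.05, 0.1, 0.25, 0.5,
    1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0,
)


@dataclass
class SessionConfig:
    """Windowing geometry: session/window sizes (s), overlap, head discard."""

    session_size: float = 2.0
    window_size: float = 2.0
    overlap_fraction: float = 0.5
    head_discard: float = 2.0
    sampling_rate: float = 256.0

    def __post_init__(self) -> None:
        if self.session_size <= 0 or self.window_size <= 0:
            raise ValueError("session_size and window_size must be positive")
        if self.window_size > self.session_size + 1e-12:
            raise ValueError(
                f"window_size ({self.window_size}) exceeds session_size "
                f"({self.session_size})"
            )
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.head_discard < 0:
            raise ValueError("head_discard must be >= 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


@dataclass
class WindowedSample:
    """One classification sample: averaged window vectors plus its label."""

    tensor: np.ndarray            # (timesteps, 20)
    label: str
    source_recording: str = ""
    session_size: float = 0.0
    window_size: float = 0.0

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 2 or self.tensor.shape[1] != N_SIGNALS:
            raise ValueError(
                f"tensor must be (timesteps, {N_SIGNALS}), got {self.tensor.shape}"
            )
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS!r}")

    @property
    def timesteps(self) -> int:
        return self.tensor.shape[0]


@dataclass
class NoiseRules:
    """Automated counterparts of the study's manual noise screening.

    A recording is rejected when any signal's variance falls below
    ``flatline_var_threshold`` (electrode lost skin contact), when any
    signal's fraction of robust z-scores beyond ``outlier_z`` exceeds
    ``max_outlier_fraction``, or when gap repair flagged it unrepairable.
    Participants retaining fewer than ``min_recordings_per_subject``
    recordings are dropped entirely.
    """

    flatline_var_threshold: float = 1e-10
    outlier_z: float = 6.0
    max_outlier_fraction: float = 0.01
    min_recordings_per_subject: int = 14

    def __post_init__(self) -> None:
        if min(self.flatline_var_threshold, self.outlier_z,
               self.max_outlier_fraction) < 0 or self.min_recordings_per_subject < 0:
            raise ValueError("all thresholds must be >= 0")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def points_per_window(window_size: float, rate: float) -> int:
    """Samples per window: ``round(window_size * rate)``, at least 1.

    For a 2.5 s window at 256 Hz this is 640. Rounding absorbs non-integer
    products from sub-sample window sizes (0.025 s * 256 Hz = 6.4 -> 6).
    """
    if window_size <= 0 or rate <= 0:
        raise ValueError("window_size and rate must be positive")
    return max(1, int(round(window_size * rate)))


def truncate_session(
    rec: BandPowerRecording, cfg: SessionConfig
) -> BandPowerRecording:
    """Keep rows in ``[head_discard, head_discard + session_size)`` seconds."""
    fs = cfg.sampling_rate
    start = int(round(cfg.head_discard * fs))
    n = int(round(cfg.session_size * fs))
    if start + n > rec.n_rows:
        raise ValueError(
            f"recording too short: need {(start + n) / fs:.3f} s "
            f"({start + n} rows), have {rec.duration:.3f} s ({rec.n_rows} rows)"
        )
    return replace(
        rec,
        timestamps=rec.timestamps[start:start + n].copy(),
        values=rec.values[start:start + n].copy(),
        markers=[
            (t, m) for t, m in rec.markers
            if rec.timestamps[start] <= t <= rec.timestamps[start + n - 1]
        ],
        artifacts=None,
    )


def segment_windows(
    rec: BandPowerRecording, cfg: SessionConfig
) -> list[tuple[int, int]]:
    """Half-open row ranges of all complete sliding windows.

    Window k starts at time ``k * window_size * (1 - overlap_fraction)``;
    only windows with the full complement of samples are emitted. With 50%
    overlap and a session divisible into n whole windows the count is 2n-1.
    """
    ppw = points_per_window(cfg.window_size, cfg.sampling_rate)
    if ppw > rec.n_rows:
        raise ValueError(
            f"window ({ppw} rows) longer than session ({rec.n_rows} rows)"
        )
    hop = cfg.window_size * (1 - cfg.overlap_fraction)
    ranges = []
    k = 0
    while True:
        start = int(round(k * hop * cfg.sampling_rate))
        if start + ppw > rec.n_rows:
            break
        ranges.append((start, start + ppw))
        k += 1
    return ranges


def average_window(rec: BandPowerRecording, row_range: tuple[int, int]) -> np.ndarray:
    """Arithmetic mean of each of the 20 signals over a row range."""
    start, end = row_range
    if not (0 <= start < end <= rec.n_rows):
        raise ValueError(f"row range {row_range} invalid for {rec.n_rows} rows")
    return rec.values[start:end].mean(axis=0)


def build_sample(rec: BandPowerRecording, cfg: SessionConfig) -> WindowedSample:
    """Truncate, window and average a labelled recording into one sample."""
    if rec.label not in LABELS:
        raise ValueError("recording must be labelled left or right")
    sess = truncate_session(rec, cfg)
    ranges = segment_windows(sess, cfg)
    tensor = np.stack([average_window(sess, r) for r in ranges])
    return WindowedSample(
        tensor=tensor, label=rec.label,
        source_recording=rec.recording_id or rec.participant_id,
        session_size=cfg.session_size, window_size=cfg.window_size,
    )


def segment_continuous(
    rec: BandPowerRecording,
    cfg: SessionConfig,
    first_label: str = RIGHT,
    offset: float = 0.0,
) -> list[WindowedSample]:
    """One labelled sample per marked block of a continuous session.

    Block boundaries come from the recording's markers; labels alternate
    starting from ``first_label`` (the protocol imagines the right hand
    first). Each sample consumes the first ``session_size`` seconds after
    the mark (plus an optional delay ``offset``), then windows and averages
    like a discrete trial. Blocks shorter than ``offset + session_size``
    raise an error listing the offending marks.
    """
    if not rec.markers:
        raise ValueError("continuous recording has no markers")
    fs = cfg.sampling_rate
    need = int(round((offset + cfg.session_size) * fs))
    marks = sorted(rec.markers)
    starts = [int(round((t - rec.timestamps[0]) * fs)) for t, _ in marks]
    ends = starts[1:] + [rec.n_rows]

    bad = [m for (m, s, e) in zip(marks, starts, ends) if e - s < need]
    if bad:
        raise ValueError(
            "blocks shorter than offset + session_size at marks: "
            + ", ".join(f"id={mid} t={t:.3f}" for t, mid in bad)
        )

    other = LEFT if first_label == RIGHT else RIGHT
    sub_cfg = replace(cfg, head_discard=0.0)
    rec_id = rec.recording_id or rec.participant_id
    samples = []
    for i, ((t, mid), s) in enumerate(zip(marks, starts)):
        lo = s + int(round(offset * fs))
        n_take = int(round(cfg.session_size * fs))
        block = BandPowerRecording(
            timestamps=rec.timestamps[lo:lo + n_take],
            values=rec.values[lo:lo + n_take],
            label=first_label if i % 2 == 0 else other,
            participant_id=rec.participant_id,
            sampling_rate=fs,
            recording_id=rec_id,
        )
        samples.append(build_sample(block, sub_cfg))
    return samples


def reject_noisy(
    recs: list[BandPowerRecording], rules: NoiseRules
) -> tuple[list[BandPowerRecording], list[tuple[BandPowerRecording, str]]]:
    """Split recordings into kept and (rejected, reason) per the noise rules.

    Reasons are machine-readable: ``unrepairable``, ``flatline:<signal>``,
    ``outliers:<signal>`` or ``subject_below_minimum``. After per-recording
    screening, every participant with fewer than
    ``min_recordings_per_subject`` kept recordings has all their recordings
    moved to the rejected list.
    """
    kept: list[BandPowerRecording] = []
    rejected: list[tuple[BandPowerRecording, str]] = []

    from .io_mindmonitor import BAND_COLUMNS

    for rec in recs:
        reason = None
        if rec.unrepairable:
            reason = "unrepairable"
        else:
            variances = np.nanvar(rec.values, axis=0)
            low = np.flatnonzero(variances < rules.flatline_var_threshold)
            if low.size:
                reason = f"flatline:{BAND_COLUMNS[low[0]]}"
            else:
                med = np.nanmedian(rec.values, axis=0)
                mad = np.nanmedian(np.abs(rec.values - med), axis=0)
                scale = 1.4826 * mad
                with np.errstate(divide="ignore", invalid="ignore"):
                    z = np.abs(rec.values - med) / scale
                frac = np.nanmean(z > rules.outlier_z, axis=0)
                high = np.flatnonzero(frac > rules.max_outlier_fraction)
                if high.size:
                    reason = f"outliers:{BAND_COLUMNS[high[0]]}"
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec, reason))

    counts = Counter(r.participant_id for r in kept)
    final_kept = []
    for rec in kept:
        if counts[rec.participant_id] < rules.min_recordings_per_subject:
            rejected.append((rec, "subject_below_minimum"))
        else:
            final_kept.append(rec)
    return final_kept, rejected
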