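"""Synthetic band-power EEG generator for motor-imagery experiments.

Emulates what a consumer headband app exports during left/right hand motor
imagery: 20 log-PSD band-power signals (5 bands x 4 channels) at 256 Hz,
either as labelled 20 s discrete trials or as 60 s continuous sessions that
alternate the imagined hand every 6 s with a mark at every block boundary.

Each signal is a stationary AR(1) Gaussian process around a signal-specific
mean. The class difference is a lateralized mean shift: alpha and beta power
move in opposite directions on left-hemisphere (TP9, AF7) versus
right-hemisphere (TP10, AF8) electrodes, mirroring the hemispheric asymmetry
that makes motor imagery detectable at all. Realistic nuisance structure —
missing samples, flat-line "no contact" channels, outlier spikes — is added
by :func:`inject_artifacts` with full ground-truth bookkeeping.

All randomness derives from one master seed through
``numpy.random.SeedSequence(seed, spawn_key=...)`` so per-recording streams
never depend on call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .io_mindmonitor import (
    BAND_COLUMNS,
    BANDS,
    CHANNELS,
    LABELS,
    LEFT,
    RIGHT,
    UNLABELED,
    BandPowerRecording,
)

#: Bands in ascending frequency order, as the headband app lists them.
BANDS_BY_FREQUENCY: tuple[str, ...] = ("Delta", "Theta", "Alpha", "Beta", "Gamma")

#: Typical resting log-PSD baselines (Bels) per band, frontal/temporal sites.
BAND_BASELINES: dict[str, float] = {
    "Delta": 0.9, "Theta": 0.5, "Alpha": 0.4, "Beta": 0.2, "Gamma": -0.1,
}

#: Relative weight of the class-dependent shift per band: the asymmetry is
#: carried by the sensorimotor-reactive alpha and beta rhythms.
BAND_EFFECT_WEIGHTS: dict[str, float] = {
    "Delta": 0.0, "Theta": 0.0, "Alpha": 1.0, "Beta": 0.6, "Gamma": 0.0,
}

#: +1 for left-hemisphere electrodes, -1 for right-hemisphere ones.
CHANNEL_SIDE: dict[str, int] = {"TP9": +1, "AF7": +1, "TP10": -1, "AF8": -1}


@dataclass
class SyntheticConfig:
    """Generator settings; defaults reproduce the study's recording protocol.

    ``class_effect`` may be a single scale (applied through the lateralized
    band/channel pattern above) or an explicit ``{(band, channel): shift}``
    mapping in log-power units. ``noise_sd`` is the stationary within-class
    standard deviation of each signal; ``ar_coefficient`` its lag-1
    autocorrelation (high values give the smooth band-power traces the app
    displays).
    """

    sampling_rate: float = 256.0
    n_channels: int = 4
    bands: tuple[str, ...] = BANDS_BY_FREQUENCY
    trial_duration: float = 20.0
    block_duration: float = 6.0
    session_duration_continuous: float = 60.0
    class_effect: float | dict = 0.3
    noise_sd: float = 0.5
    ar_coefficient: float = 0.97
    p_missing: float = 0.0
    p_flatline: float = 0.0
    p_outlier: float = 0.0
    outlier_magnitude: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        for name in ("p_missing", "p_flatline", "p_outlier"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_channels != len(CHANNELS) or len(self.bands) != len(BANDS):
            raise ValueError("the signal set is fixed at 5 bands x 4 channels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def effect_vector(self) -> np.ndarray:
        """Class mean difference (right minus left) per canonical signal."""
        out = np.empty(len(BANDS) * len(CHANNELS))
        k = 0
        for band in BANDS:
            for ch in CHANNELS:
                if isinstance(self.class_effect, dict):
                    shift = float(self.class_effect.get((band, ch), 0.0))
                else:
                    shift = (
                        float(self.class_effect)
                        * BAND_EFFECT_WEIGHTS[band]
                        * CHANNEL_SIDE[ch]
                    )
                out[k] = shift
                k += 1
        return out

    def baseline_vector(self) -> np.ndarray:
        return np.array([BAND_BASELINES[b] for b in BANDS for _ in CHANNELS])

    def class_means(self, label: str) -> np.ndarray:
        """Per-signal process mean for a class: baseline +/- half the effect."""
        sign = {RIGHT: +1.0, LEFT: -1.0}[label]
        return self.baseline_vector() + sign * 0.5 * self.effect_vector()


def _rng(seed, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def _ar1(n_rows: int, n_sig: int, cfg: SyntheticConfig, rng) -> np.ndarray:
    """Zero-mean stationary AR(1) noise, shape (n_rows, n_sig)."""
    if cfg.noise_sd == 0 or n_rows == 0:
        return np.zeros((n_rows, n_sig))
    rho = cfg.ar_coefficient
    eps = rng.standard_normal((n_rows, n_sig))
    innov_sd = cfg.noise_sd * np.sqrt(1 - rho**2)
    x0 = cfg.noise_sd * eps[0]
    driven = np.vstack([x0, innov_sd * eps[1:]]) if n_rows > 1 else x0[None, :]
    return lfilter([1.0], [1.0, -rho], driven, axis=0)


def generate_trial(
    config: SyntheticConfig, label: str, seed: int
) -> BandPowerRecording:
    """One labelled discrete trial: ``trial_duration`` seconds of 20 signals.

    Each signal is AR(1) around its class-specific mean; no markers.
    """
    if label not in LABELS:
        raise ValueError(f"label must be 'left' or 'right', got {label!r}")
    n = int(round(config.trial_duration * config.sampling_rate))
    rng = _rng(seed, 0)
    values = config.class_means(label) + _ar1(n, len(BANDS) * len(CHANNELS), config, rng)
    ts = np.arange(n) / config.sampling_rate
    return BandPowerRecording(
        timestamps=ts, values=values, label=label,
        sampling_rate=config.sampling_rate,
    )


def generate_continuous_session(
    config: SyntheticConfig, seed: int, participant_id: str = ""
) -> BandPowerRecording:
    """A continuous session alternating the imagined hand every block.

    The session lasts ``session_duration_continuous`` seconds and switches
    label every ``block_duration`` seconds, right hand first. A marker
    (1-based block index) is placed at every block start, so downstream
    segmentation recovers per-block labels from the marks alone. With the
    60 s / 6 s defaults this yields 10 blocks, 5 per class.
    """
    n_blocks_f = config.session_duration_continuous / config.block_duration
    n_blocks = int(round(n_blocks_f))
    if abs(n_blocks_f - n_blocks) > 1e-9 or n_blocks < 1:
        raise ValueError(
            "session_duration_continuous must be an integer multiple of "
            f"block_duration (got {config.session_duration_continuous} / "
            f"{config.block_duration})"
        )
    fs = config.sampling_rate
    n = int(round(config.session_duration_continuous * fs))
    rows_per_block = int(round(config.block_duration * fs))

    block_labels = [RIGHT if i % 2 == 0 else LEFT for i in range(n_blocks)]
    means = np.empty((n, len(BANDS) * len(CHANNELS)))
    for i, lab in enumerate(block_labels):
        lo = i * rows_per_block
        hi = n if i == n_blocks - 1 else (i + 1) * rows_per_block
        means[lo:hi] = config.class_means(lab)

    rng = _rng(seed, 0)
    values = means + _ar1(n, means.shape[1], config, rng)
    ts = np.arange(n) / fs
    markers = [(float(ts[i * rows_per_block]), i + 1) for i in range(n_blocks)]
    return BandPowerRecording(
        timestamps=ts, values=values, label=UNLABELED, markers=markers,
        participant_id=participant_id, sampling_rate=fs,
    )


def inject_artifacts(
    rec: BandPowerRecording, config: SyntheticConfig, seed: int
) -> BandPowerRecording:
    """Add headband nuisance structure with recorded ground truth.

    Draw order from ``default_rng(SeedSequence(seed, spawn_key=(1,)))``:

    1. one uniform draw against ``p_flatline``; on success a uniformly chosen
       channel has its 5 band signals replaced by their means (zero variance);
    2. a uniform matrix against ``p_missing`` -> cells set to NaN;
    3. a uniform matrix against ``p_outlier`` plus a sign matrix -> cells
       shifted by ``±outlier_magnitude * noise_sd``.

    The returned recording's ``artifacts`` dict records the flat-lined
    channel and the (row, column) indices of missing cells and outliers, so
    tests can compare detection against ground truth. All probabilities 0
    returns an identical copy.
    """
    out = rec.copy()
    rng = _rng(seed, 1)

    flat_channel = None
    if rng.random() < config.p_flatline:
        flat_channel = CHANNELS[rng.integers(len(CHANNELS))]
        cols = [
            i for i, c in enumerate(BAND_COLUMNS)
            if c.endswith("_" + flat_channel)
        ]
        out.values[:, cols] = np.nanmean(out.values[:, cols], axis=0)

    missing = rng.random(out.values.shape) < config.p_missing
    outlier = rng.random(out.values.shape) < config.p_outlier
    signs = np.where(rng.random(out.values.shape) < 0.5, -1.0, 1.0)

    out.values[outlier] += (
        config.outlier_magnitude * config.noise_sd * signs[outlier]
    )
    out.values[missing] = np.nan

    out.artifacts = {
        "flatline_channel": flat_channel,
        "missing": np.argwhere(missing),
        "outliers": np.argwhere(outlier & ~missing),
    }
    return out


def generate_dataset(
    config: SyntheticConfig,
    n_trials_per_class: int,
    seed: int,
    participant_id: str = "",
    with_artifacts: bool = False,
) -> list[BandPowerRecording]:
    """Balanced labelled trials: ``2 * n_trials_per_class`` recordings.

    Per-recording seeds are spawned from the master seed by recording index,
    so the dataset is bit-reproducible and independent of generation order.
    """
    if n_trials_per_class < 1:
        raise ValueError("n_trials_per_class must be >= 1")
    recs = []
    for i in range(2 * n_trials_per_class):
        label = LABELS[i % 2]
        child = np.random.SeedSequence(seed, spawn_key=(2, i))
        rec_seed = int(child.generate_state(1)[0] % 2**31)
        rec = generate_trial(config, label, rec_seed)
        if with_artifacts:
            rec = inject_artifacts(rec, config, rec_seed)
        rec.participant_id = participant_id
        rec.recording_id = f"{participant_id or 'P'}/trial{i:03d}"
        recs.append(rec)
    return recs


def generate_continuous_dataset(
    config: SyntheticConfig,
    n_sessions: int,
    seed: int,
    participant_id: str = "",
    with_artifacts: bool = False,
) -> list[BandPowerRecording]:
    """``n_sessions`` continuous sessions for one participant."""
    recs = []
    for i in range(n_sessions):
        child = np.random.SeedSequence(seed, spawn_key=(3, i))
        rec_seed = int(child.generate_state(1)[0] % 2**31)
        rec = generate_continuous_session(config, rec_seed, participant_id)
        if with_artifacts:
            rec = inject_artifacts(rec, config, rec_seed)
        rec.recording_id = f"{participant_id or 'P'}/session{i:03d}"
        recs.append(rec)
    return recs
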