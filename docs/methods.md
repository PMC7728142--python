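# Methods

## Problem and data model

The package classifies left- versus right-hand motor imagery from the
band-power output of a four-electrode EEG headband. The recording app — not
this package — converts raw µV signals to the logarithm of the power
spectral density per canonical band (δ, θ, α, β, γ) and channel (TP9, TP10,
AF7, AF8), notch-filtered at mains frequency, and streams 20 signals at a
nominal 256 Hz. The pipeline therefore starts at band-power level; raw
waveform synthesis and spectral estimation are out of scope.

Internally every recording is a `(n_rows, 20)` matrix in the fixed
band-major order `[α¹..α⁴, β¹..β⁴, δ¹..δ⁴, γ¹..γ⁴, θ¹..θ⁴]` over channels
TP9, TP10, AF7, AF8, regardless of the CSV column order on disk. Missing
cells are NaN.

## Synthetic generator

The original participant recordings are not publicly deposited, so the
generator reproduces the *statistical contract* the analysis depends on,
not real EEG:

- **Process.** Each of the 20 signals is a stationary AR(1) Gaussian process
  `x_t = μ + ρ(x_{t−1} − μ) + √(1−ρ²)·σ·ε_t` around a signal-specific mean.
  One autocorrelation knob `ρ` (`ar_coefficient`, default 0.97) produces the
  smooth band-power traces a headband app displays; `σ` (`noise_sd`, default
  0.5 log-power units) is the stationary within-class SD.
- **Class structure.** The left/right difference is a mean shift of
  magnitude `class_effect` (default 0.3) applied with opposite sign to
  left-hemisphere (TP9, AF7) and right-hemisphere (TP10, AF8) electrodes,
  weighted 1.0 on α and 0.6 on β and zero elsewhere — the sensorimotor
  rhythms that carry the hemispheric asymmetry motor imagery is detected by.
  A `{(band, channel): shift}` mapping can replace the scalar. Each class
  mean is `baseline ± effect/2`. Band baselines (δ 0.9, θ 0.5, α 0.4, β 0.2,
  γ −0.1 log-power units) imitate typical frontal/temporal resting values;
  their exact levels are irrelevant to classification, which sees only the
  difference.
- **Protocols.** Discrete trials are 20 s, one label each, 20 per hand per
  participant. Continuous sessions are 60 s alternating the imagined hand
  every 6 s, right hand first, with an integer mark at every block start —
  10 blocks, 5 per class.
- **Artifacts.** `inject_artifacts` adds, with configurable probabilities,
  one flat-lined channel (all five of its bands replaced by constants — the
  "lost contact" failure), i.i.d. missing cells, and i.i.d. outlier spikes
  of ±`outlier_magnitude`·σ. Ground truth (which channel, which cells) is
  recorded on the output so detection can be tested exactly.
- **Seeding.** Every recording's stream is spawned from one master seed via
  `SeedSequence(seed, spawn_key=(kind, index))`; regeneration is
  bit-identical and independent of call order.

What the generator does **not** model: oculomotor components (the protocol
has participants rotate their eyes toward the target, so real class signal
may be partly ocular — the generator only produces a generic class shift),
1/f spectral structure, cross-signal covariance beyond the shared mean
shifts, non-stationarity within a block, or transition dynamics at block
boundaries. Passing tests therefore demonstrate that the pipeline recovers
the class structure it assumes and stays calibrated under its null — not
that real recordings of any particular participant are this separable.

## Timing repair and quality control

- **Alignment.** Samples are snapped to the nearest point of a uniform
  1/256 s grid spanning the recording (first sample wins a collision), so
  observed cells are never altered by resampling. The app streams with
  small delays but no documented jitter model, so nearest-point snapping is
  the most conservative choice.
- **Interpolation.** Interior NaN runs no longer than `max_gap` (default
  0.5 s) are filled linearly between the bounding samples; edge runs by
  nearest-value extension. Any longer run, or a signal with fewer than two
  valid samples, marks the recording `unrepairable` and leaves its values
  untouched — rejection is the caller's decision.
- **Noise rules.** The original study discarded noisy recordings by manual
  inspection; a repository cannot ship a human in the loop, so rejection is
  automated and reproducible: per-signal variance below
  `flatline_var_threshold` (default 10⁻¹⁰) rejects as flat-line; a fraction
  of robust z-scores (median/MAD) beyond `outlier_z` (default 6) exceeding
  `max_outlier_fraction` (default 1%) rejects as outlier-contaminated.
  Participants with fewer than `min_recordings_per_subject` (default 14)
  surviving recordings are dropped entirely, keeping per-participant
  comparisons meaningful.

## Windowing arithmetic

`points_per_window(W, rate) = round(W·rate)` (640 points for a 2.5 s window
at 256 Hz); rounding absorbs non-integer products from the sub-second grid
sizes (0.025 s · 256 Hz = 6.4 → 6). Sessions keep rows
`[head_discard, head_discard + S)`; window k starts at row
`round(k·W·(1−overlap)·rate)` and only complete windows are emitted, so with
50% overlap a session containing `n = ⌊S/W⌋` whole windows yields `2n − 1`
timesteps. Partial trailing windows are discarded — the `2n − 1` count
implies only complete windows exist. Each window is averaged per signal into
one 20-vector; averaging is permutation-invariant within the window and
exact on constants, which the property tests exploit. All ranges are
half-open and 0-based.

Continuous sessions are segmented at their marks; each block contributes one
sample built from the first `session_size` seconds after the mark (an
optional `offset` accommodates operator latency; default 0, since the 6 s
blocks were chosen precisely to leave slack after the 2 s consumed by
classification). Labels alternate from the protocol's right-first order.

## Classifier

Architecture (fixed by design): kernel-1 1D convolution with 32 filters
(linear activation — a per-timestep signal remix; configurable to ReLU),
LSTM with 32 units, input dropout 0.1 (one inverted-dropout mask per sample,
shared across timesteps) and L2 10⁻⁷ on the input and recurrent kernels,
then a 2-unit softmax. Input contract: `(samples, timesteps, 20)` with the
sample count unknown a priori. Parameter count is a pure function of the
config: 672 + 8 320 + 66 = 9 058.

The network is implemented directly in NumPy — at these sizes (≤ 79
timesteps, 20 features, 32 units, ≤ 200 samples) a vectorised forward pass
and explicit backpropagation-through-time train in milliseconds per epoch,
keep the dependency surface minimal, and make determinism trivial to
control. Correctness is established by finite-difference gradient checks in
the test suite (agreement to ~10⁻⁷ relative). Initialisation follows common
recurrent-network practice: Glorot-uniform input kernels, orthogonal
recurrent kernel, forget-gate bias 1.

Training: Adam (learning rate 10⁻³, β₁ 0.9, β₂ 0.999), cross-entropy loss,
batch size 16, up to 200 epochs, early stopping on validation loss with
patience 10 and best-weight restoration. The loss/optimizer/schedule are
not part of the fixed architecture and sit in `ModelConfig`. The "0.0000001
regularizer" is read as L2 on the LSTM kernels — the most common
interpretation — and dropout 0.1 as LSTM input dropout. Argmax ties break
toward class index 0 (left).

Determinism: split plans and tensors are bit-exact given the seeds; trained
weights are same-seed reproducible on the same platform (floating-point
reduction order is not promised across BLAS builds).

## Split protocol

Splits operate at the **recording** level, stratified by label: overlapping
windows from one recording appearing on both sides of a split would leak
test information into training, so sample-level splitting is ruled out.
Outer split: `n_test = round(0.2·N)` (min 1); inner split:
`n_train = ⌊0.8·(N − n_test)⌋`, remainder validation. For 20 recordings this
gives 12/4/4; with 10 samples per continuous recording, 120/40/40 samples.
Per-class counts use largest-remainder allocation. Each iteration's split
derives from `(seed, iteration)` via `SeedSequence` and is replayable.

## Studies

- **Grid exploration** sweeps S × W (defaults: S ∈ {0.01…0.5} ∪ {1, 1.5,
  …, 20}; W ∈ {0.01…5}), skipping infeasible cells (W > S, or recordings
  shorter than head-discard + S) with a log entry, and reports mean ± SD
  test accuracy per cell over repeated splits. A window size's "stability
  onset" is the smallest S from which accuracy stays ≥ 0.8 (the usual
  usability threshold for binary BCI) through the rest of the grid.
- **Continuous validation** trains a personal model per participant
  (excluding participants with < 5 recordings) for each window size in
  {2, 1.5, 1, 0.5, 0.25, 0.1, 0.05} s at a fixed 2 s session, 5 iterations
  each, and tabulates train/val/test accuracy per participant plus
  cross-participant averages — one row per window size. The 2 s
  response-time claim is operational: each sample consumes exactly 2 s of
  signal after its mark.

Because the grid and validation numbers in the original study come from its
own non-deposited recordings, the synthetic counterparts are calibration
checks, not numeric reproductions: with `class_effect = 0` the 5-iteration
mean test accuracy must stay inside the 95% binomial chance band for a
40-sample test set ([0.35, 0.65], asserted on the mean of 20 independent
repeats because per-recording prediction correlations widen single repeats);
with the documented strong setting `class_effect = 1.0` the mean test
accuracy at S = 2 s, W = 0.5 s must reach ≥ 0.9.

## Problem sizes and configuration

The acceptance script and heavy tests use the protocol sizes (20 recordings
per participant or per class, 3 participants, 5 iterations). Null
calibration and the validation table train at a reduced schedule
(max 10–12 epochs, patience 3) — calibration and table structure depend on
the split protocol and data distribution, not on training to convergence —
while the recovery check trains with the full early-stopped schedule.

Runs are driven by a flat YAML config (versioned schema, unknown keys are
errors) with a single master seed; stage seeds are spawned by fixed keys so
adding a stage never perturbs another stage's randomness, and the run
manifest (config snapshot, seeds, output hashes, version) suffices to
reproduce any stage's tensors bit-identically.

## Known limitations

- The generator's class effect is a stationary mean shift; classifiers that
  exploit temporal dynamics gain nothing over window means on this data, so
  architecture comparisons on synthetic data are not informative.
- Kernel sizes other than 1 are rejected rather than implemented; the
  studied architecture is per-timestep by construction.
- Robust-z outlier rejection assumes roughly symmetric within-signal noise;
  heavy asymmetric drift would be flagged as outliers.
- `points_per_window` rounding means sub-sample window sizes (e.g. 0.01 s at
  256 Hz → 3 points) overlap more than nominally specified; the brute-force
  window oracle in the tests covers exactly this regime.
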