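"""The CNN-LSTM classifier, its nested split protocol and evaluation.

The architecture is fixed by design: a kernel-1 1D convolution with 32
filters remixes the 20 band-power signals per timestep, an LSTM with 32
units (input dropout 0.1, L2 1e-7 on its input and recurrent kernels) reads
the window sequence, and a 2-unit softmax head emits left/right
probabilities. Training uses Adam with cross-entropy loss and early
stopping on validation loss with best-weight restoration.

Splits are made at the *recording* level, stratified by label — overlapping
windows from one recording must never straddle the train/test boundary —
with the nested 80/20 then 80/20 scheme: ``n_test = round(0.2 N)`` (min 1),
then ``n_train = floor(0.8 (N - n_test))`` and the rest validation. For 20
recordings this gives 12/4/4; with 10 samples per recording, 120/40/40
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._network import Adam, CnnLstmNetwork
from .io_mindmonitor import LABELS, LEFT, N_SIGNALS, RIGHT
from .preprocessing import WindowedSample

#: Class index order: ties at argmax resolve to the first class, i.e. left.
CLASS_ORDER: tuple[str, str] = (LEFT, RIGHT)


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    The architectural fields default to the studied network (32 filters,
    kernel 1, 32 LSTM units, dropout 0.1, L2 1e-7, 2 classes). The training
    schedule (optimiser, rate, batch size, epochs, patience) is configurable
    since it is not part of the fixed architecture.
    """

    conv_filters: int = 32
    conv_kernel: int = 1
    lstm_units: int = 32
    dropout: float = 0.1
    l2_coefficient: float = 1e-7
    output_classes: int = 2
    max_epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 1e-3
    early_stop_patience: int = 10
    early_stop_metric: str = "val_loss"
    conv_activation: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conv_filters", "lstm_units", "output_classes",
                     "max_epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.conv_kernel != 1:
            raise ValueError(
                "the studied architecture uses a kernel size of 1; other "
                "kernel sizes are not supported"
            )
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.l2_coefficient < 0:
            raise ValueError("l2_coefficient must be >= 0")
        if self.early_stop_metric not in ("val_loss", "val_accuracy"):
            raise ValueError("early_stop_metric must be val_loss or val_accuracy")
        if self.early_stop_patience < 0:
            raise ValueError("early_stop_patience must be >= 0")


@dataclass
class SplitPlan:
    """Recording-level id sets of one nested 80/20–80/20 split."""

    train_recordings: list[str]
    val_recordings: list[str]
    test_recordings: list[str]
    iteration: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        sets = [set(self.train_recordings), set(self.val_recordings),
                set(self.test_recordings)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("split sets must be disjoint")


@dataclass
class EvalResult:
    """Accuracies of one trained model on one split."""

    train_acc: float
    val_acc: float
    test_acc: float
    participant_id: str = ""
    window_size: float = 0.0
    session_size: float = 0.0
    iteration: int = 0

    def __post_init__(self) -> None:
        for a in (self.train_acc, self.val_acc, self.test_acc):
            if not 0 <= a <= 1:
                raise ValueError("accuracies must lie in [0, 1]")


def build_model(cfg: ModelConfig, timesteps: int) -> CnnLstmNetwork:
    """Instantiate the network for a given sequence length.

    The input contract is ``(samples: unknown a priori, timesteps, 20)``;
    the parameter count is a pure function of the config (the kernel-1
    convolution and the recurrent layer are shared across timesteps).
    """
    if timesteps < 1:
        raise ValueError("timesteps must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    return CnnLstmNetwork(
        n_features=N_SIGNALS,
        conv_filters=cfg.conv_filters,
        lstm_units=cfg.lstm_units,
        n_classes=cfg.output_classes,
        dropout=cfg.dropout,
        l2=cfg.l2_coefficient,
        rng=rng,
        conv_activation=cfg.conv_activation,
    )


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def _allocate(counts: dict[str, int], total: int) -> dict[str, int]:
    """Largest-remainder allocation of `total` across classes."""
    n = sum(counts.values())
    raw = {k: total * v / n for k, v in counts.items()}
    alloc = {k: int(np.floor(r)) for k, r in raw.items()}
    short = total - sum(alloc.values())
    for k in sorted(counts, key=lambda k: (raw[k] - alloc[k], k), reverse=True):
        if short == 0:
            break
        if alloc[k] < counts[k]:
            alloc[k] += 1
            short -= 1
    return alloc


def split_dataset(
    recording_ids: list[str],
    labels: list[str],
    seed: int,
    iteration: int = 0,
) -> SplitPlan:
    """Deterministic stratified recording-level 80/20 then 80/20 split."""
    n = len(recording_ids)
    if n < 5:
        raise ValueError(f"need at least 5 recordings to split, got {n}")
    if len(labels) != n:
        raise ValueError("labels must match recording_ids")

    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(iteration,))
    )
    by_class: dict[str, list[str]] = {}
    for rid, lab in sorted(zip(recording_ids, labels)):
        by_class.setdefault(lab, []).append(rid)
    for ids in by_class.values():
        rng.shuffle(ids)

    counts = {k: len(v) for k, v in by_class.items()}
    n_test = max(1, int(round(0.2 * n)))
    n_build = n - n_test
    n_train = max(1, int(np.floor(0.8 * n_build)))

    test_alloc = _allocate(counts, n_test)
    build_counts = {k: counts[k] - test_alloc[k] for k in counts}
    train_alloc = _allocate(build_counts, n_train)

    test, train, val = [], [], []
    for k, ids in by_class.items():
        test.extend(ids[: test_alloc[k]])
        train.extend(ids[test_alloc[k]: test_alloc[k] + train_alloc[k]])
        val.extend(ids[test_alloc[k] + train_alloc[k]:])
    return SplitPlan(
        train_recordings=sorted(train), val_recordings=sorted(val),
        test_recordings=sorted(test), iteration=iteration, seed=seed,
    )


# ---------------------------------------------------------------------------
# Tensors, training, evaluation
# ---------------------------------------------------------------------------

def stack_samples(samples: list[WindowedSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into ``X (n, T, 20)`` and integer labels (left=0)."""
    if not samples:
        raise ValueError("no samples to stack")
    shapes = {s.tensor.shape for s in samples}
    if len(shapes) > 1:
        raise ValueError(f"samples disagree on tensor shape: {shapes}")
    X = np.stack([s.tensor for s in samples])
    y = np.array([CLASS_ORDER.index(s.label) for s in samples])
    return X, y


def _accuracy(net: CnnLstmNetwork, X: np.ndarray, y: np.ndarray) -> float:
    return float((net.predict_proba(X).argmax(axis=1) == y).mean())


def train(
    net: CnnLstmNetwork,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: ModelConfig,
) -> dict:
    """Mini-batch Adam training with early stopping; returns the history.

    Stops when the monitored metric fails to improve for more than
    ``early_stop_patience`` consecutive epochs (or at ``max_epochs``), then
    restores the best epoch's weights. History holds per-epoch train/val
    loss and accuracy plus ``best_epoch`` and ``stopped_epoch``.
    """
    if X_train.shape[1:] != X_val.shape[1:]:
        raise ValueError(
            f"train/val shape mismatch: {X_train.shape[1:]} vs {X_val.shape[1:]}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    opt = Adam(net.params, lr=cfg.learning_rate)
    history: dict = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
    best_metric = np.inf
    best_params = {k: v.copy() for k, v in net.params.items()}
    best_epoch = 0
    bad_epochs = 0
    n = X_train.shape[0]

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo: lo + cfg.batch_size]
            _, cache = net.forward(X_train[idx], training=True, rng=rng)
            _, grads = net.loss_and_grads(cache, y_train[idx])
            opt.step(net.params, grads)

        probs_tr, _ = net.forward(X_train, training=False)
        probs_va, _ = net.forward(X_val, training=False)
        history["loss"].append(net.loss(probs_tr, y_train))
        history["accuracy"].append(float((probs_tr.argmax(1) == y_train).mean()))
        history["val_loss"].append(net.loss(probs_va, y_val))
        history["val_accuracy"].append(float((probs_va.argmax(1) == y_val).mean()))

        monitored = history["val_loss"][-1]
        if cfg.early_stop_metric == "val_accuracy":
            monitored = -history["val_accuracy"][-1]
        if monitored < best_metric - 1e-12:
            best_metric = monitored
            best_params = {k: v.copy() for k, v in net.params.items()}
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.early_stop_patience:
                break

    net.params.update({k: v.copy() for k, v in best_params.items()})
    history["best_epoch"] = best_epoch
    history["stopped_epoch"] = epoch
    return history


def evaluate(net: CnnLstmNetwork, samples: list[WindowedSample]) -> float:
    """Accuracy (correct / total) with argmax prediction, ties toward left."""
    if not samples:
        raise ValueError("cannot evaluate on an empty test set")
    X, y = stack_samples(samples)
    return _accuracy(net, X, y)


def repeated_evaluation(
    samples: list[WindowedSample],
    cfg: ModelConfig,
    n_iterations: int = 5,
    participant_id: str = "",
) -> tuple[list[EvalResult], dict[str, float]]:
    """The split-train-evaluate protocol averaged over iterations.

    Each iteration draws a fresh recording-level split (derived
    deterministically from ``cfg.seed`` and the iteration index), trains a
    fresh model and records train/val/test accuracy. Returns the
    per-iteration results and their means.
    """
    by_rec: dict[str, list[WindowedSample]] = {}
    rec_label: dict[str, str] = {}
    for s in samples:
        by_rec.setdefault(s.source_recording, []).append(s)
        rec_label[s.source_recording] = s.label

    rec_ids = sorted(by_rec)
    labels = [rec_label[r] for r in rec_ids]
    results: list[EvalResult] = []
    for it in range(n_iterations):
        plan = split_dataset(rec_ids, labels, seed=cfg.seed, iteration=it)
        parts = {}
        for name, recs in (("train", plan.train_recordings),
                           ("val", plan.val_recordings),
                           ("test", plan.test_recordings)):
            parts[name] = stack_samples(
                [s for r in recs for s in by_rec[r]]
            )
        it_seed = int(
            np.random.SeedSequence(cfg.seed, spawn_key=(100 + it,))
            .generate_state(1)[0] % 2**31
        )
        from dataclasses import replace as _replace

        it_cfg = _replace(cfg, seed=it_seed)
        net = build_model(it_cfg, timesteps=parts["train"][0].shape[1])
        train(net, *parts["train"], *parts["val"], it_cfg)
        ws = samples[0].window_size
        ss = samples[0].session_size
        results.append(EvalResult(
            train_acc=_accuracy(net, *parts["train"]),
            val_acc=_accuracy(net, *parts["val"]),
            test_acc=_accuracy(net, *parts["test"]),
            participant_id=participant_id,
            window_size=ws, session_size=ss, iteration=it,
        ))
    summary = {
        "train_acc": float(np.mean([r.train_acc for r in results])),
        "val_acc": float(np.mean([r.val_acc for r in results])),
        "test_acc": float(np.mean([r.test_acc for r in results])),
        "test_sd": float(np.std([r.test_acc for r in results])),
    }
    return results, summary
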