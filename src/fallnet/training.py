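"""Training protocol and trial-level prediction.

The protocol: subject-wise 80/20 train/test split, batch size 64, up to 200
epochs of Adam with early stopping once validation accuracy stalls for 20
consecutive epochs (the best-validation weights are restored), validation
taken as a random 20% of the training windows.  A window counts as a fall
when the softmax fall probability reaches the 0.7 threshold; a trial's
*detected moment* is the end time of the earliest such window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError, DataError
from .nn import Adam, Network, build_network, softmax_cross_entropy
from .windowing import TrialWindows, WindowDataset
from .zoo import ModelSpec
from .evaluation import TrialPrediction


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol constants (defaults follow the evaluation protocol)."""

    batch_size: int = 64
    max_epochs: int = 200
    early_stop_patience: int = 20
    validation_fraction: float = 0.2
    train_fraction_subjects: float = 0.8
    seed: int = 0
    softmax_threshold: float = 0.7
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 1:
            raise ConfigError("validation_fraction must be in (0, 1)")
        if self.early_stop_patience > self.max_epochs:
            raise ConfigError("patience cannot exceed max_epochs")
        if not 0 < self.softmax_threshold < 1:
            raise ConfigError("softmax_threshold must be in (0, 1)")
        if not 0 < self.train_fraction_subjects < 1:
            raise ConfigError("train_fraction_subjects must be in (0, 1)")


def split_subjects(
    subject_ids: Sequence[str], train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive subject-wise split: round(f·n) train, rest test.

    Deterministic given the seed; no subject appears on both sides, so window
    leakage across the split is impossible.
    """
    if not 0 < train_fraction < 1:
        raise ConfigError("train_fraction must be in (0, 1)")
    ids = sorted(set(subject_ids))
    if len(ids) < 2:
        raise ConfigError("need at least 2 subjects for a subject-wise split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)  # both sides non-empty
    train = sorted(ids[i] for i in order[:n_train])
    test = sorted(ids[i] for i in order[n_train:])
    return train, test


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


@dataclass
class TrainedModel:
    """A compiled network plus its spec and training history."""

    network: Network
    spec: ModelSpec
    history: TrainHistory

    def fall_probability(self, windows: np.ndarray) -> np.ndarray:
        """Softmax fall-class probability for a stack of (W, C) windows."""
        return self.network.predict_proba(np.asarray(windows))[:, 1]

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        import json

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path.with_suffix(".npz"), **self.network.state())
        path.with_suffix(".json").write_text(json.dumps(self.spec.to_dict(), indent=1))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        import json

        path = Path(path)
        spec = ModelSpec.from_dict(json.loads(path.with_suffix(".json").read_text()))
        network = build_network(spec, seed=0)
        with np.load(path.with_suffix(".npz")) as data:
            network.load_state({k: data[k] for k in data.files})
        return cls(network=network, spec=spec, history=TrainHistory())


def _accuracy(network: Network, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    pred = network.predict_proba(x, batch_size=batch).argmax(axis=1)
    return float((pred == y).mean())


def train(
    spec: ModelSpec,
    dataset: WindowDataset,
    cfg: TrainConfig = TrainConfig(),
    verbose: bool = False,
) -> TrainedModel:
    """Train a spec on labeled windows; fully reproducible given ``cfg.seed``.

    Raises :class:`DataError` when the training windows contain a single
    class (a degenerate cohort cannot define the decision boundary).
    """
    x, y = dataset.to_arrays()
    if x.shape[1] != spec.input_frames or x.shape[2] != spec.input_channels:
        raise ConfigError(
            f"dataset windows {x.shape[1:]} do not match spec input "
            f"({spec.input_frames}, {spec.input_channels})"
        )
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(x))
    n_val = int(round(cfg.validation_fraction * len(x)))
    n_val = min(max(n_val, 1), len(x) - 1)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    x_tr, y_tr = x[tr_idx], y[tr_idx]
    x_val, y_val = x[val_idx], y[val_idx]
    if len(np.unique(y_tr)) < 2:
        raise DataError("training windows contain a single class")

    network = build_network(spec, seed=cfg.seed)
    optimizer = Adam(network, lr=cfg.learning_rate)
    history = TrainHistory()
    best_val = -np.inf
    best_state = network.state()
    stall = 0

    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(len(x_tr))
        losses, correct = [], 0
        for start in range(0, len(x_tr), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            logits = network.forward(xb, training=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            network.backward(dlogits)
            optimizer.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == yb).sum())
        history.train_loss.append(float(np.mean(losses)))
        history.train_accuracy.append(correct / len(x_tr))
        val_acc = _accuracy(network, x_val, y_val, cfg.batch_size)
        history.val_accuracy.append(val_acc)
        if verbose:
            print(
                f"epoch {epoch + 1:3d}  loss {history.train_loss[-1]:.4f}  "
                f"val_acc {val_acc:.4f}"
            )
        if val_acc > best_val:
            best_val = val_acc
            best_state = network.state()
            history.best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= cfg.early_stop_patience:
                history.stopped_epoch = epoch
                break
    else:
        history.stopped_epoch = cfg.max_epochs - 1

    network.load_state(best_state)
    return TrainedModel(network=network, spec=spec, history=history)


def predict_trial(
    model: TrainedModel,
    trial: TrialWindows,
    threshold: float = 0.7,
) -> TrialPrediction:
    """Score every window of a trial and apply the first-crossing rule.

    The detected moment is the end time of the earliest window whose fall
    probability reaches the threshold (ties detect: comparison is ≥).
    """
    if not trial.windows:
        raise DataError(f"trial {trial.source} has no windows")
    values = np.stack([w.values for w in trial.windows])
    probs = model.fall_probability(values)
    end_times = [w.end_time_s for w in trial.windows]
    detected = None
    for t, p in zip(end_times, probs):
        if p >= threshold:
            detected = float(t)
            break
    return TrialPrediction(
        source=trial.source,
        window_scores=tuple(zip(end_times, map(float, probs))),
        detected_moment_s=detected,
        is_fall_trial=trial.is_fall_trial,
    )
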