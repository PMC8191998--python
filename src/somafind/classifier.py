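"""3D residual-network classification of cell candidates.

A candidate's dual-channel cuboid is standardised per channel and fed to a 3D
residual network with a 2-way softmax head.  The network learns to reject
artefacts by exploiting the channel contract: genuine somata appear only in
the signal channel, artefacts in both.

Training follows the reference regime: Adam, categorical cross-entropy,
batch size 32, learning rate 1e-4, a 10% validation holdback, stochastic
augmentation of training examples, and stopping once the validation loss
plateaus.  ``retrain`` continues optimisation from saved weights on new,
typically much smaller, experiment-specific data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from somafind.cuboid_extraction import Cuboid, augment, extract_cuboid, standardize
from somafind.nn import Adam, ResNet3D, softmax_cross_entropy
from somafind.volume_io import CellRecord, PlaneStackVolume

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "Classification",
    "build_network",
    "train",
    "retrain",
    "classify_candidates",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture selector: depth family {18, 34, 50, 101, 152}, 50 default.

    ``base_width`` (stem channel count) is an implementation knob; the narrow
    default keeps CPU training practical while preserving the stage layout.
    """

    depth: int = 50
    input_shape: tuple[int, int, int, int] = (50, 50, 20, 2)
    n_classes: int = 2
    base_width: int = 16

    def __post_init__(self) -> None:
        if self.depth not in (18, 34, 50, 101, 152):
            raise ValueError(f"unsupported depth {self.depth}")
        if self.input_shape[-1] < 1 or self.n_classes < 2:
            raise ValueError("need >= 1 channel and >= 2 classes")


@dataclass(frozen=True)
class TrainingConfig:
    """Training hyperparameters (defaults are the reference regime)."""

    batch_size: int = 32
    learning_rate: float = 1e-4
    validation_fraction: float = 0.10
    patience: int = 5  # epochs without val-loss improvement before stopping
    min_delta: float = 1e-3  # improvement below this counts as plateau
    max_epochs: int = 100
    seed: int = 0
    augment: bool = True
    class_weight: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.validation_fraction < 0.5):
            raise ValueError("validation_fraction must be in (0, 0.5)")
        if self.batch_size < 1 or self.learning_rate <= 0 or self.max_epochs < 0:
            raise ValueError("invalid training configuration")


@dataclass(frozen=True)
class Classification:
    """One classified candidate: cell probability and thresholded label."""

    candidate: CellRecord
    probability_cell: float
    label: str  # "cell" | "artefact"


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> ResNet3D:
    """Instantiate a randomly initialised network for the given spec."""
    spec = spec or NetworkSpec()
    return ResNet3D(
        depth=spec.depth,
        in_channels=spec.input_shape[-1],
        n_classes=spec.n_classes,
        base_width=spec.base_width,
        seed=seed,
    )


def _to_batch(cuboids: list[Cuboid]) -> np.ndarray:
    """Standardise and reorder cuboids to the network layout (N, C, x, y, z)."""
    return np.stack([standardize(c.data).transpose(3, 0, 1, 2) for c in cuboids])


def _evaluate(
    model: ResNet3D, cuboids: list[Cuboid], labels: np.ndarray, batch_size: int
) -> tuple[float, float]:
    """(cross-entropy, accuracy) in inference mode."""
    losses = []
    correct = 0
    for i in range(0, len(cuboids), batch_size):
        xb = _to_batch(cuboids[i : i + batch_size])
        yb = labels[i : i + batch_size]
        logits = model.forward(xb, train=False)
        loss, probs, _ = softmax_cross_entropy(logits, yb)
        losses.append(loss * len(yb))
        correct += int((probs.argmax(axis=1) == yb).sum())
    n = len(cuboids)
    return sum(losses) / n, correct / n


def train(
    model: ResNet3D,
    labelled_cuboids: list[tuple[Cuboid, int]],
    config: TrainingConfig | None = None,
) -> tuple[ResNet3D, dict[str, list[float]]]:
    """Train in place; returns (model, per-epoch history).

    The history has keys ``loss``, ``accuracy``, ``val_loss``,
    ``val_accuracy``.  Training stops when the validation loss has not
    improved by ``min_delta`` for ``patience`` epochs (or at ``max_epochs``);
    the best-validation weights are restored on exit.
    """
    config = config or TrainingConfig()
    if not labelled_cuboids:
        raise ValueError("no training examples")
    labels_all = np.array([lab for _, lab in labelled_cuboids], dtype=np.int64)
    classes, counts = np.unique(labels_all, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 examples per class")

    rng = np.random.default_rng(config.seed)
    n = len(labelled_cuboids)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.validation_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    cuboids = [c for c, _ in labelled_cuboids]
    val_cuboids = [cuboids[i] for i in val_idx]
    val_labels = labels_all[val_idx]

    weights = None
    if config.class_weight is not None:
        weights = np.array([config.class_weight.get(int(l), 1.0) for l in labels_all])

    opt = Adam(model.params(), lr=config.learning_rate)
    history: dict[str, list[float]] = {
        "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []
    }
    best_loss = np.inf
    best_state = None
    wait = 0

    for _epoch in range(config.max_epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        correct = 0
        for i in range(0, len(order), config.batch_size):
            batch_idx = order[i : i + config.batch_size]
            batch = [cuboids[j] for j in batch_idx]
            if config.augment:
                batch = [augment(c, rng) for c in batch]
            xb = _to_batch(batch)
            yb = labels_all[batch_idx]
            wb = weights[batch_idx] if weights is not None else None
            logits = model.forward(xb, train=True)
            loss, probs, grad = softmax_cross_entropy(logits, yb, wb)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(batch_idx)
            correct += int((probs.argmax(axis=1) == yb).sum())
        history["loss"].append(epoch_loss / len(order))
        history["accuracy"].append(correct / len(order))

        val_loss, val_acc = _evaluate(model, val_cuboids, val_labels, config.batch_size)
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)

        if best_loss - val_loss > config.min_delta:
            best_loss = val_loss
            best_state = model.state_dict()
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def retrain(
    model: ResNet3D,
    new_labelled_cuboids: list[tuple[Cuboid, int]],
    config: TrainingConfig | None = None,
) -> tuple[ResNet3D, dict[str, list[float]]]:
    """Continue optimisation from existing weights on new data only.

    Same stopping rule as :func:`train`; with ``max_epochs=0`` the model is
    returned unchanged.  Fresh optimiser state is used, as is conventional
    when fine-tuning on a new dataset.
    """
    return train(model, new_labelled_cuboids, config)


def classify_candidates(
    model: ResNet3D,
    signal: PlaneStackVolume,
    autofluo: PlaneStackVolume,
    candidates: list[CellRecord],
    threshold: float = 0.5,
    batch_size: int = 32,
) -> list[Classification]:
    """Classify candidates in order; label = cell iff P(cell) >= threshold."""
    out: list[Classification] = []
    for i in range(0, len(candidates), batch_size):
        chunk = candidates[i : i + batch_size]
        cuboids = [
            extract_cuboid(signal, autofluo, (rec.x, rec.y, rec.z)) for rec in chunk
        ]
        probs = model.predict_proba(_to_batch(cuboids), batch_size=batch_size)
        for rec, p in zip(chunk, probs[:, 1]):
            label = "cell" if p >= threshold else "artefact"
            out.append(Classification(rec, float(p), label))
    return out


def save_model(model: ResNet3D, path: str | Path) -> Path:
    """Save weights (.npz) plus a JSON sidecar describing the architecture."""
    weights_path = Path(path)
    if weights_path.suffix != ".npz":
        weights_path = weights_path.with_suffix(weights_path.suffix + ".npz")
    np.savez(weights_path, **model.state_dict())
    sidecar = {
        "depth": model.depth,
        "in_channels": model.in_channels,
        "n_classes": model.n_classes,
        "base_width": model.base_width,
        "input_shape": [50, 50, 20, model.in_channels],
        "normalization": "per-cuboid per-channel standardisation (sd floor 1e-6)",
    }
    sidecar_path = weights_path.with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return weights_path


def load_model(path: str | Path, spec: NetworkSpec | None = None) -> ResNet3D:
    """Load a saved model; errors if the sidecar disagrees with ``spec``."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar_path = path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text())
    if spec is not None and (
        spec.depth != meta["depth"]
        or spec.n_classes != meta["n_classes"]
        or spec.base_width != meta["base_width"]
        or spec.input_shape[-1] != meta["in_channels"]
    ):
        raise ValueError(f"architecture mismatch: saved {meta}, requested {spec}")
    model = ResNet3D(
        depth=meta["depth"],
        in_channels=meta["in_channels"],
        n_classes=meta["n_classes"],
        base_width=meta["base_width"],
    )
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
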