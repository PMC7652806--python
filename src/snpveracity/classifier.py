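"""Training orchestration for the eight-layer SNP veracity classifier.

The network maps the encoded feature vector of one SNP call to the
probability of the call being *incorrect* (the rare class is the positive
class, as in every evaluation metric here).  Architecture: eight dense
layers with gradually decreasing widths, ReLU activations in layers 1-7,
a single sigmoid unit in layer 8, and dropout (rate 0.2) after each of the
first five layers.  Optimization is Adam on binary cross-entropy; a
stratified 10% subset of the training rows (the OPTset) is held out for
early stopping — training stops after `patience` epochs without OPTset
loss improvement and the best-epoch weights are restored.

Three imbalance strategies are supported:

* ``naive``      — plain training;
* ``weighted``   — per-row loss multipliers from :func:`imbalance.class_weights`;
* ``oversample`` — minority rows duplicated by :func:`imbalance.oversample_indices`
  (applied after the OPTset split, so the OPTset holds no duplicates).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import train_test_split

from . import imbalance
from .errors import ConfigError, EncodingError, TrainingError
from .featurize import FeatureMatrix
from .nn import FeedForwardNet, binary_cross_entropy

STRATEGIES = ("naive", "weighted", "oversample")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and optimization settings.

    ``layer_sizes`` must list exactly eight non-increasing widths ending in
    1.  Adam defaults are the standard published values; batch size,
    maximum epochs and the 10% OPTset fraction are desk-scale defaults.
    """

    layer_sizes: tuple[int, ...] = (128, 64, 48, 32, 16, 8, 4, 1)
    dropout_rate: float = 0.2
    dropout_after_layers: tuple[int, ...] = (1, 2, 3, 4, 5)
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    batch_size: int = 512
    max_epochs: int = 500
    patience: int = 25
    optset_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(self.layer_sizes)
        if len(sizes) != 8:
            raise ConfigError(f"exactly 8 layers required, got {len(sizes)}")
        if any(s < 1 for s in sizes) or sizes[-1] != 1:
            raise ConfigError("layer sizes must be positive and end in 1")
        if any(a < b for a, b in zip(sizes, sizes[1:])):
            raise ConfigError(f"layer sizes must be non-increasing, got {sizes}")
        if not set(self.dropout_after_layers) <= {1, 2, 3, 4, 5}:
            raise ConfigError("dropout only after layers 1..5")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if not 0.0 <= self.optset_fraction < 1.0:
            raise ConfigError("optset_fraction must be in [0, 1)")


@dataclass
class TrainingHistory:
    """Per-epoch loss/precision/recall on training rows and the OPTset."""

    epochs: list[dict] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


@dataclass
class TrainedClassifier:
    net: FeedForwardNet
    config: NetworkConfig
    columns: tuple[str, ...]
    history: TrainingHistory
    strategy: str
    ratio: float | None = None
    class_weights: imbalance.ClassWeights | None = None

    def predict_incorrect_probability(self, matrix) -> np.ndarray:
        """Per-row probability of the call being incorrect, in [0, 1]."""
        X = matrix.X if isinstance(matrix, FeatureMatrix) else np.asarray(matrix)
        if isinstance(matrix, FeatureMatrix) and tuple(matrix.columns) != tuple(
            self.columns
        ):
            raise EncodingError("matrix columns differ from the training encoding")
        if X.shape[1] != len(self.columns):
            raise EncodingError(
                f"matrix has {X.shape[1]} columns, model expects {len(self.columns)}"
            )
        return self.net.predict_proba(X)

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        W, b = self.net.get_weights()
        arrays = {f"W{i}": w for i, w in enumerate(W)}
        arrays.update({f"b{i}": bb for i, bb in enumerate(b)})
        np.savez(os.path.join(directory, "weights.npz"), **arrays)
        meta = {
            "config": asdict(self.config),
            "columns": list(self.columns),
            "strategy": self.strategy,
            "ratio": self.ratio,
            "class_weights": (
                asdict(self.class_weights) if self.class_weights else None
            ),
            "history": {
                "epochs": self.history.epochs,
                "stopped_epoch": self.history.stopped_epoch,
                "best_epoch": self.history.best_epoch,
            },
            "n_features": self.net.n_features,
        }
        with open(os.path.join(directory, "model.json"), "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, directory: str) -> "TrainedClassifier":
        with open(os.path.join(directory, "model.json")) as fh:
            meta = json.load(fh)
        cfg_d = dict(meta["config"])
        cfg_d["layer_sizes"] = tuple(cfg_d["layer_sizes"])
        cfg_d["dropout_after_layers"] = tuple(cfg_d["dropout_after_layers"])
        config = NetworkConfig(**cfg_d)
        net = build_network(meta["n_features"], config)
        data = np.load(os.path.join(directory, "weights.npz"))
        n = len(config.layer_sizes)
        net.set_weights(
            ([data[f"W{i}"] for i in range(n)], [data[f"b{i}"] for i in range(n)])
        )
        cw = meta["class_weights"]
        return cls(
            net=net,
            config=config,
            columns=tuple(meta["columns"]),
            history=TrainingHistory(
                epochs=meta["history"]["epochs"],
                stopped_epoch=meta["history"]["stopped_epoch"],
                best_epoch=meta["history"]["best_epoch"],
            ),
            strategy=meta["strategy"],
            ratio=meta["ratio"],
            class_weights=imbalance.ClassWeights(**cw) if cw else None,
        )


def split_optset(
    X: np.ndarray, y: np.ndarray, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified split into (train, OPTset) index arrays preserving the
    class ratio to within rounding; empty OPTset for fraction 0."""
    y = np.asarray(y)
    idx = np.arange(len(y))
    if fraction == 0.0:
        return idx, np.array([], dtype=int), y, np.array([], dtype=int)
    if y.min() == y.max():
        raise ConfigError("stratified split needs both classes present")
    train_idx, opt_idx = train_test_split(
        idx, test_size=fraction, random_state=seed, stratify=y
    )
    return np.sort(train_idx), np.sort(opt_idx), y[np.sort(train_idx)], y[np.sort(opt_idx)]


def build_network(n_features: int, config: NetworkConfig) -> FeedForwardNet:
    """Instantiate the untrained eight-layer network for a feature width."""
    if n_features < 1:
        raise ConfigError("n_features must be >= 1")
    return FeedForwardNet(
        n_features=n_features,
        layer_sizes=config.layer_sizes,
        dropout_rate=config.dropout_rate,
        dropout_after_layers=config.dropout_after_layers,
        seed=config.seed,
    )


def _epoch_metrics(p: np.ndarray, y: np.ndarray, cutoff: float = 0.5) -> tuple[float, float]:
    """(precision, recall) at a fixed cutoff; 0 when undefined."""
    pred = p >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall


def train(
    matrix: FeatureMatrix,
    strategy: str = "naive",
    ratio: float | None = None,
    config: NetworkConfig | None = None,
) -> TrainedClassifier:
    """Train the classifier on an encoded feature matrix.

    The OPTset is split off first; oversampling (if requested) then
    augments only the remaining training rows.  Returns the classifier
    with best-epoch weights restored and the full epoch history.
    """
    if strategy not in STRATEGIES:
        raise ConfigError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")
    config = config or NetworkConfig()
    rng = np.random.default_rng(config.seed)

    tr_idx, opt_idx, _, _ = split_optset(
        matrix.X, matrix.y, config.optset_fraction, config.seed
    )
    X_tr, y_tr = matrix.X[tr_idx], matrix.y[tr_idx]
    X_opt, y_opt = matrix.X[opt_idx], matrix.y[opt_idx]

    weights_obj = None
    if strategy == "weighted":
        weights_obj = imbalance.class_weights(
            int(np.sum(y_tr == 0)), int(np.sum(y_tr == 1))
        )
        row_w = np.where(y_tr == 1, weights_obj.w_incorrect, weights_obj.w_correct)
    elif strategy == "oversample":
        if ratio is None:
            ratio = 1.0
        idx = imbalance.oversample_indices(y_tr, ratio, seed=int(config.seed) + 1)
        X_tr, y_tr = X_tr[idx], y_tr[idx]
        row_w = np.ones(len(y_tr))
    else:
        row_w = np.ones(len(y_tr))

    net = build_network(matrix.n_features, config)
    history = TrainingHistory()
    monitor_opt = len(y_opt) > 0
    best_loss = np.inf
    best_weights = net.get_weights()
    best_epoch = 0
    n = len(y_tr)

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            loss, dW, db = net.gradients(
                X_tr[batch], y_tr[batch], row_w[batch], dropout_rng=rng
            )
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}; learning rate "
                    f"{config.learning_rate}, batch size {config.batch_size}"
                )
            net.adam_step(
                dW,
                db,
                learning_rate=config.learning_rate,
                beta1=config.beta1,
                beta2=config.beta2,
                epsilon=config.epsilon,
            )

        p_tr = net.predict_proba(X_tr)
        train_loss = binary_cross_entropy(p_tr, y_tr, row_w)
        prec, rec = _epoch_metrics(p_tr, y_tr)
        record = {
            "epoch": epoch,
            "loss": train_loss,
            "precision": prec,
            "recall": rec,
        }
        if monitor_opt:
            p_opt = net.predict_proba(X_opt)
            opt_loss = binary_cross_entropy(p_opt, y_opt)
            o_prec, o_rec = _epoch_metrics(p_opt, y_opt)
            record.update(
                {"opt_loss": opt_loss, "opt_precision": o_prec, "opt_recall": o_rec}
            )
            monitored = opt_loss
        else:
            monitored = train_loss
        history.epochs.append(record)

        if monitored < best_loss:
            best_loss = monitored
            best_weights = net.get_weights()
            best_epoch = epoch
        history.stopped_epoch = epoch
        if monitor_opt and epoch - best_epoch >= config.patience:
            break

    history.best_epoch = best_epoch if best_epoch else history.stopped_epoch
    net.set_weights(best_weights)
    return TrainedClassifier(
        net=net,
        config=config,
        columns=tuple(matrix.columns),
        history=history,
        strategy=strategy if strategy != "oversample" else "oversample",
        ratio=ratio if strategy == "oversample" else None,
        class_weights=weights_obj,
    )


def predict_incorrect_probability(classifier: TrainedClassifier, matrix) -> np.ndarray:
    """Module-level alias for :meth:`TrainedClassifier.predict_incorrect_probability`."""
    return classifier.predict_incorrect_probability(matrix)
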