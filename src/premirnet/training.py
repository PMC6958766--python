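"""Mini-batch Adam training with validation monitoring and early stopping.

The loss is the label/prediction cross-entropy averaged over a batch;
training stops once the monitored loss has not improved for ``patience``
epochs (or at ``max_epochs``) and the weights from the best epoch are
restored.  Runs are fully reproducible: shuffling, initialization and
dropout all derive from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .datasets import FoldAssignment, cv_iterate
from .encoding import DEFAULT_ALPHABET, encode_table, stack_batch
from .exceptions import TrainingDivergedError, ValidationError
from .evaluation import EvalMetrics, confusion, metrics
from .io_formats import DatasetTable
from .models import Classifier, build_cnn, build_rnn
from .utils import derive_seed


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 10
    monitor: str = "validation_loss"  # or "training_loss"
    seed: int = 0
    probability_floor: float = 1e-7
    dtype: str = "float32"  # training precision; inference follows the weights

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.batch_size < 1 or self.early_stop_patience < 1 or self.max_epochs < 1:
            raise ValidationError("batch_size, patience and max_epochs must be >= 1")
        if self.monitor not in ("validation_loss", "training_loss"):
            raise ValidationError(f"unknown monitor {self.monitor!r}")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stopped_epoch: int = -1
    best_epoch: int = -1

    def n_epochs(self) -> int:
        return len(self.train_loss)


def cross_entropy(y, s, floor: float = 1e-7) -> float:
    """Cross-entropy -sum(y_i log s_i) between one label distribution and
    one predicted distribution, with the predicted probabilities clipped
    below at ``floor``."""
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    if y.shape != s.shape:
        raise ValidationError(f"label/prediction length mismatch: {y.shape} vs {s.shape}")
    if (s < 0).any() or (s > 1).any():
        raise ValidationError("predicted probabilities must lie in [0, 1]")
    return float(-(y * np.log(np.clip(s, floor, 1.0))).sum())


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    """Accept (matrices, labels) or (X, labels); return X and one-hot y."""
    matrices, labels = data
    X = matrices if isinstance(matrices, np.ndarray) else stack_batch(list(matrices))
    labels = np.asarray(labels, dtype=int)
    if X.shape[0] != labels.shape[0]:
        raise ValidationError("data/label count mismatch")
    y = np.zeros((labels.shape[0], 2))
    y[np.arange(labels.shape[0]), labels] = 1.0
    return X, y


def _epoch_loss_acc(network: nn.Sequential, X, y, loss_fn, batch_size=256):
    total, correct = 0.0, 0
    for start in range(0, X.shape[0], batch_size):
        xb, yb = X[start : start + batch_size], y[start : start + batch_size]
        probs = network.forward(xb, training=False)
        total += loss_fn.forward(probs, yb) * xb.shape[0]
        correct += int((probs.argmax(axis=1) == yb.argmax(axis=1)).sum())
    return total / X.shape[0], correct / X.shape[0]


def train(
    classifier: Classifier,
    train_data,
    val_data,
    config: TrainingConfig = TrainingConfig(),
) -> tuple[Classifier, TrainingHistory]:
    """Fit ``classifier`` in place and return it with its history.

    ``train_data``/``val_data`` are ``(encoded matrices, labels)`` pairs
    (or pre-stacked arrays).  Monitored-loss early stopping restores the
    best epoch's weights.
    """
    X_tr, y_tr = _as_xy(train_data)
    if X_tr.shape[0] == 0:
        raise ValidationError("empty training set")
    X_val, y_val = _as_xy(val_data)
    if config.monitor == "validation_loss" and X_val.shape[0] == 0:
        raise ValidationError("validation monitoring requires a non-empty validation set")

    net = classifier.network
    net.initialize(derive_seed(config.seed, "init"))
    net.cast(np.dtype(config.dtype))
    rng = np.random.default_rng(derive_seed(config.seed, "train"))
    loss_fn = nn.CrossEntropyLoss(floor=config.probability_floor)
    opt = nn.Adam(net.parameters(), config.learning_rate, config.beta1, config.beta2)

    history = TrainingHistory()
    best_monitored = np.inf
    best_weights = net.get_weights()
    n = X_tr.shape[0]

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            probs = net.forward(X_tr[idx], training=True, rng=rng)
            batch_loss = loss_fn.forward(probs, y_tr[idx])
            if not np.isfinite(batch_loss):
                raise TrainingDivergedError(
                    f"non-finite loss {batch_loss} at epoch {epoch}"
                )
            net.backward(loss_fn.backward())
            opt.step(net.gradients())
            epoch_loss += batch_loss * len(idx)
            seen += len(idx)

        # running mean of the minibatch losses (framework convention);
        # avoids a second full pass over the training set each epoch
        history.train_loss.append(epoch_loss / seen)
        if X_val.shape[0]:
            va_loss, va_acc = _epoch_loss_acc(net, X_val, y_val, loss_fn)
        else:
            va_loss, va_acc = np.nan, np.nan
        history.val_loss.append(va_loss)
        history.val_accuracy.append(va_acc)

        monitored = va_loss if config.monitor == "validation_loss" else history.train_loss[-1]
        if monitored < best_monitored:
            best_monitored = monitored
            history.best_epoch = epoch
            best_weights = net.get_weights()
        history.stopped_epoch = epoch
        if epoch - history.best_epoch >= config.early_stop_patience:
            break

    net.set_weights(best_weights)
    classifier.metadata["training"] = {
        "seed": config.seed,
        "monitor": config.monitor,
        "best_epoch": history.best_epoch,
        "stopped_epoch": history.stopped_epoch,
        "probability_floor": config.probability_floor,
    }
    return classifier, history


def _builder_for(model_spec) -> callable:
    from .models import CNNSpec, RNNSpec

    if isinstance(model_spec, CNNSpec):
        return lambda seed: build_cnn(model_spec, seed=seed)
    if isinstance(model_spec, RNNSpec):
        return lambda seed: build_rnn(model_spec, seed=seed)
    raise ValidationError(f"unknown model spec {type(model_spec).__name__}")


def run_cv(
    model_spec,
    table: DatasetTable,
    assignment: FoldAssignment,
    config: TrainingConfig = TrainingConfig(),
    alphabet=DEFAULT_ALPHABET,
    max_len: int | None = None,
    val_fraction: float = 0.1,
) -> list[tuple[Classifier, EvalMetrics]]:
    """Train and evaluate one fresh model per CV fold.

    Early stopping inside each fold monitors a seeded ``val_fraction``
    carve-out of that fold's training records, so the held-out test fold
    never leaks into model selection.
    """
    from .encoding import DEFAULT_MAX_LEN

    max_len = max_len or getattr(model_spec, "max_len", DEFAULT_MAX_LEN)
    builder = _builder_for(model_spec)
    results = []
    for fold, (train_tbl, test_tbl) in enumerate(cv_iterate(assignment, table)):
        try:
            fold_seed = derive_seed(config.seed, f"fold{fold}")
            rng = np.random.default_rng(fold_seed)
            ids = train_tbl.ids()
            n_val = max(1, int(round(val_fraction * len(ids))))
            val_ids = set(np.array(ids)[rng.permutation(len(ids))[:n_val]])
            inner_train = train_tbl.subset([i for i in ids if i not in val_ids])
            inner_val = train_tbl.subset([i for i in ids if i in val_ids])

            clf = builder(fold_seed)
            fold_config = TrainingConfig(
                learning_rate=config.learning_rate, beta1=config.beta1,
                beta2=config.beta2, batch_size=config.batch_size,
                max_epochs=config.max_epochs,
                early_stop_patience=config.early_stop_patience,
                monitor=config.monitor, seed=fold_seed,
                probability_floor=config.probability_floor,
            )
            clf, _ = train(
                clf,
                encode_table(inner_train, alphabet, max_len),
                encode_table(inner_val, alphabet, max_len),
                fold_config,
            )
            mats, labels = encode_table(test_tbl, alphabet, max_len)
            from .models import positive_scores

            scores = positive_scores(clf, mats)
            results.append((clf, metrics(confusion(labels, scores))))
        except Exception as e:
            raise type(e)(f"fold {fold}: {e}") from e
    return results
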