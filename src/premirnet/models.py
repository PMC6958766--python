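"""The two classifier architectures, built from declarative specs.

The CNN stacks three convolution/max-pool cascades (16x4, 32x5, 64x6
filters/kernels, pool 2) followed by a 32-unit fully connected layer
with 0.5 dropout and a 2-way softmax.  The RNN stacks three LSTM layers
(128, 64, 2 units) with 20% input dropout each; the final 2-unit hidden
state feeds the softmax.  Both consume the 180x12 one-hot dimer
encoding, channels last.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .encoding import DEFAULT_ALPHABET, DEFAULT_MAX_LEN, stack_batch
from .exceptions import ValidationError


@dataclass(frozen=True)
class CNNSpec:
    conv_blocks: tuple[tuple[int, int], ...] = ((16, 4), (32, 5), (64, 6))
    pool_size: int = 2
    fc_units: int = 32
    dropout_rate: float = 0.5
    output_units: int = 2
    max_len: int = DEFAULT_MAX_LEN
    channels: int = 12
    padding_mode: str = "valid"

    def __post_init__(self):
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if self.padding_mode not in ("valid", "same"):
            raise ValidationError(f"unknown padding_mode {self.padding_mode!r}")


@dataclass(frozen=True)
class RNNSpec:
    lstm_units: tuple[int, ...] = (128, 64, 2)
    input_dropout_rate: float = 0.2
    output_units: int = 2
    max_len: int = DEFAULT_MAX_LEN
    channels: int = 12

    def __post_init__(self):
        if not (0.0 <= self.input_dropout_rate < 1.0):
            raise ValidationError("input_dropout_rate must lie in [0, 1)")
        if self.lstm_units[-1] != self.output_units:
            raise ValidationError(
                f"final LSTM width {self.lstm_units[-1]} must equal output_units "
                f"{self.output_units}"
            )
        if list(self.lstm_units) != sorted(self.lstm_units, reverse=True):
            warnings.warn("non-decreasing LSTM unit list departs from the default design")


@dataclass
class Classifier:
    """An architecture plus weights plus the encoder metadata it expects."""

    kind: str  # "cnn" | "rnn"
    spec: CNNSpec | RNNSpec
    network: nn.Sequential
    metadata: dict = field(default_factory=dict)

    def n_params(self) -> int:
        return self.network.n_params()


def _default_metadata(kind: str, spec, seed: int) -> dict:
    meta = {
        "kind": kind,
        "alphabet": list(DEFAULT_ALPHABET.symbols),
        "max_len": spec.max_len,
        "seed": seed,
        "deviations": [],
    }
    if kind == "rnn":
        # the cited output-gate equation carries a peephole term V_o*c_t;
        # the standard no-peephole cell is built instead
        meta["deviations"].append("no_peephole_lstm")
    return meta


def cnn_output_length(spec: CNNSpec) -> int:
    """Sequence length remaining after the conv/pool cascade."""
    length = spec.max_len
    for _, kernel in spec.conv_blocks:
        if spec.padding_mode == "valid":
            length = length - kernel + 1
        if length < 1:
            raise ValidationError(f"length collapsed below 1 at conv kernel {kernel}")
        length //= spec.pool_size
        if length < 1:
            raise ValidationError(f"length collapsed below 1 at pool {spec.pool_size}")
    return length


def build_cnn(spec: CNNSpec = CNNSpec(), seed: int = 0) -> Classifier:
    """Assemble the convolutional classifier with seeded initial weights."""
    if spec.padding_mode == "same":
        raise NotImplementedError("padding_mode='same' is not implemented; use 'valid'")
    layers: list[nn.Layer] = []
    channels = spec.channels
    for filters, kernel in spec.conv_blocks:
        layers.append(nn.Conv1D(channels, filters, kernel))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool1D(spec.pool_size))
        channels = filters
    flat = cnn_output_length(spec) * channels
    layers += [
        nn.Flatten(),
        nn.Dense(flat, spec.fc_units),
        nn.ReLU(),
        nn.Dropout(spec.dropout_rate),
        nn.Dense(spec.fc_units, spec.output_units),
        nn.Softmax(),
    ]
    net = nn.Sequential(layers)
    net.initialize(seed)
    return Classifier("cnn", spec, net, _default_metadata("cnn", spec, seed))


def build_rnn(spec: RNNSpec = RNNSpec(), seed: int = 0) -> Classifier:
    """Assemble the stacked-LSTM classifier with seeded initial weights."""
    layers: list[nn.Layer] = []
    n_in = spec.channels
    for i, units in enumerate(spec.lstm_units):
        last = i == len(spec.lstm_units) - 1
        layers.append(
            nn.LSTM(n_in, units, return_sequences=not last,
                    input_dropout=spec.input_dropout_rate)
        )
        n_in = units
    layers.append(nn.Softmax())
    net = nn.Sequential(layers)
    net.initialize(seed)
    return Classifier("rnn", spec, net, _default_metadata("rnn", spec, seed))


def predict(classifier: Classifier, batch) -> np.ndarray:
    """Class-probability pairs (p_negative, p_positive) per input.

    Accepts a list of EncodedMatrix or a pre-stacked (n, max_len, 12)
    array.  Inference is deterministic (dropout disabled).
    """
    if isinstance(batch, np.ndarray):
        x = batch.astype(np.float64)
    else:
        batch = list(batch)
        if not batch:
            return np.zeros((0, 2))
        for m in batch:
            if m.max_len != classifier.metadata["max_len"]:
                raise ValidationError(
                    f"encoded max_len {m.max_len} != model max_len "
                    f"{classifier.metadata['max_len']}"
                )
        x = stack_batch(batch)
    if x.shape[0] == 0:
        return np.zeros((0, 2))
    if x.shape[1:] != (classifier.metadata["max_len"], len(classifier.metadata["alphabet"])):
        raise ValidationError(
            f"batch shape {x.shape[1:]} does not match model input "
            f"({classifier.metadata['max_len']}, {len(classifier.metadata['alphabet'])})"
        )
    return classifier.network.forward(x, training=False)


def positive_scores(classifier: Classifier, batch) -> np.ndarray:
    """Positive-class probability per input."""
    return predict(classifier, batch)[:, 1]


def save_model(classifier: Classifier, path) -> None:
    """Write weights (.npz) plus a JSON metadata/spec sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    weights = classifier.network.get_weights()
    np.savez(path / "weights.npz", **{f"w{i}": w for i, w in enumerate(weights)})
    sidecar = {
        "kind": classifier.kind,
        "spec": asdict(classifier.spec),
        "metadata": classifier.metadata,
    }
    (path / "model.json").write_text(json.dumps(sidecar, indent=2))


def load_model(path, expect_alphabet=None, expect_max_len: int | None = None) -> Classifier:
    """Rebuild a saved classifier; refuses metadata drift.

    ``expect_alphabet``/``expect_max_len`` assert the current encoder
    configuration against the one the model was trained with.
    """
    path = Path(path)
    sidecar_file = path / "model.json"
    if not sidecar_file.exists():
        raise FileNotFoundError(f"no model sidecar at {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    meta = sidecar["metadata"]
    if expect_alphabet is not None and list(expect_alphabet) != list(meta["alphabet"]):
        raise ValidationError("encoder alphabet order differs from the model's metadata")
    if expect_max_len is not None and expect_max_len != meta["max_len"]:
        raise ValidationError(
            f"encoder max_len {expect_max_len} differs from the model's {meta['max_len']}"
        )
    raw = dict(sidecar["spec"])
    if sidecar["kind"] == "cnn":
        raw["conv_blocks"] = tuple(tuple(b) for b in raw["conv_blocks"])
        clf = build_cnn(CNNSpec(**raw), seed=meta.get("seed", 0))
    elif sidecar["kind"] == "rnn":
        raw["lstm_units"] = tuple(raw["lstm_units"])
        clf = build_rnn(RNNSpec(**raw), seed=meta.get("seed", 0))
    else:
        raise ValidationError(f"unknown model kind {sidecar['kind']!r}")
    with np.load(path / "weights.npz") as npz:
        weights = [npz[f"w{i}"] for i in range(len(npz.files))]
    clf.network.set_weights(weights)
    clf.metadata = meta
    return clf
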