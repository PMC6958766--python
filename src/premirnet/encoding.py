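"""Sequence/structure dimer one-hot encoding with zero padding.

Each position of an RNA sequence is merged with its dot-bracket symbol
into a 2-character dimer (e.g. ``G(``), giving a 12-symbol alphabet
({A,U,G,C} x {(, ., )}).  A record becomes a ``max_len x 12`` binary
matrix: one-hot rows for real positions, all-zero rows as padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .io_formats import DatasetTable, NEGATIVE, POSITIVE

#: Default padded length: the benchmark corpus maximum sequence length.
DEFAULT_MAX_LEN = 180

BASES = "AUGC"
STRUCT_SYMBOLS = "(.)"


@dataclass(frozen=True)
class DimerAlphabet:
    """The ordered 12-dimer alphabet.

    Ordering is base-major — ``A(, A., A), U(, ..., C)`` — fixed here and
    serialized into model metadata so encoders and trained models cannot
    drift apart.
    """

    symbols: tuple[str, ...] = tuple(b + s for b in BASES for s in STRUCT_SYMBOLS)
    index: dict = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.symbols) != len(set(self.symbols)):
            raise ValidationError("alphabet symbols must be distinct")
        object.__setattr__(self, "index", {d: i for i, d in enumerate(self.symbols)})

    def __len__(self) -> int:
        return len(self.symbols)


DEFAULT_ALPHABET = DimerAlphabet()


@dataclass(frozen=True)
class EncodedMatrix:
    """One encoded record: ``max_len x 12`` in {0,1} plus its true length."""

    values: np.ndarray
    true_length: int
    max_len: int = DEFAULT_MAX_LEN

    def __post_init__(self):
        v = self.values
        if v.shape != (self.max_len, 12):
            raise ValidationError(f"encoded matrix shape {v.shape} != ({self.max_len}, 12)")
        if not np.isin(v, (0, 1)).all():
            raise ValidationError("encoded matrix must be binary")
        row_sums = v.sum(axis=1)
        if not (row_sums[: self.true_length] == 1).all():
            raise ValidationError("each encoded position must be one-hot")
        if not (row_sums[self.true_length :] == 0).all():
            raise ValidationError("padding rows must be all-zero")


def merge_seq_struct(sequence: str, structure: str) -> list[str]:
    """Positionwise concatenation of base and structure symbol."""
    if len(sequence) != len(structure):
        raise ValidationError(
            f"sequence length {len(sequence)} != structure length {len(structure)}"
        )
    return [b + s for b, s in zip(sequence, structure)]


def one_hot(
    dimers,
    alphabet: DimerAlphabet = DEFAULT_ALPHABET,
    max_len: int = DEFAULT_MAX_LEN,
) -> EncodedMatrix:
    """One-hot encode a dimer list and zero-pad to ``max_len`` rows.

    Inputs longer than ``max_len`` are an error — truncation would
    silently destroy hairpin arms.
    """
    dimers = list(dimers)
    if len(dimers) > max_len:
        raise ValidationError(
            f"sequence of length {len(dimers)} exceeds max_len {max_len}"
        )
    values = np.zeros((max_len, len(alphabet)), dtype=np.int8)
    for pos, d in enumerate(dimers):
        idx = alphabet.index.get(d)
        if idx is None:
            raise ValidationError(f"unknown dimer {d!r} at position {pos}")
        values[pos, idx] = 1
    return EncodedMatrix(values=values, true_length=len(dimers), max_len=max_len)


def decode(matrix: EncodedMatrix, alphabet: DimerAlphabet = DEFAULT_ALPHABET) -> list[str]:
    """Inverse of :func:`one_hot`: recover the dimer list."""
    rows = matrix.values[: matrix.true_length]
    return [alphabet.symbols[i] for i in rows.argmax(axis=1)]


def encode_record(record, alphabet=DEFAULT_ALPHABET, max_len=DEFAULT_MAX_LEN) -> EncodedMatrix:
    if record.structure is None:
        raise ValidationError(f"record {record.id!r} has no structure to encode")
    try:
        return one_hot(merge_seq_struct(record.sequence, record.structure), alphabet, max_len)
    except ValidationError as e:
        raise ValidationError(f"record {record.id!r}: {e}") from e


def encode_table(
    table: DatasetTable,
    alphabet: DimerAlphabet = DEFAULT_ALPHABET,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[list[EncodedMatrix], list[int]]:
    """Encode every record; labels map positive->1, negative->0.

    Order is preserved.  An unlabeled record or any per-record encoding
    failure aborts with the record id.
    """
    matrices, labels = [], []
    for rec in table:
        if rec.label == POSITIVE:
            labels.append(1)
        elif rec.label == NEGATIVE:
            labels.append(0)
        else:
            raise ValidationError(f"record {rec.id!r} is unlabeled; cannot encode for training")
        matrices.append(encode_record(rec, alphabet, max_len))
    return matrices, labels


def stack_batch(matrices) -> np.ndarray:
    """Stack encoded matrices into an ``(n, max_len, 12)`` float array."""
    if not matrices:
        return np.zeros((0, DEFAULT_MAX_LEN, 12))
    return np.stack([m.values for m in matrices]).astype(np.float64)
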