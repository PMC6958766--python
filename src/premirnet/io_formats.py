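"""Reading and writing sequence records and annotated dataset tables.

Two on-disk formats are understood: plain FASTA (via Biopython) and the
annotated delimited table used by the pre-miRNA benchmark datasets,
whose structure column is conventionally named ``RNAFolds``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO

from .exceptions import ParseError, ValidationError
from .structure import validate_dotbracket

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unlabeled"

_LABEL_TOKENS = {
    "positive": POSITIVE, "pos": POSITIVE, "1": POSITIVE, "true": POSITIVE,
    "negative": NEGATIVE, "neg": NEGATIVE, "0": NEGATIVE, "false": NEGATIVE,
}

_RNA_ALPHABET = set("ACGU")


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Uppercase, map T->U, and reject anything outside {A,C,G,U}.

    Ambiguity codes (including N) are rejected: the 12-dimer feature
    alphabet has exactly one slot per canonical base.
    """
    seq = raw.strip().upper().replace("T", "U")
    if not seq:
        raise ValidationError(f"record {record_id!r}: empty sequence")
    bad = set(seq) - _RNA_ALPHABET
    if bad:
        raise ValidationError(
            f"record {record_id!r}: characters {sorted(bad)} are not encodable "
            "(alphabet is A/C/G/U; T is converted; IUPAC ambiguity codes are rejected)"
        )
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """One RNA sequence with optional dot-bracket structure and label."""

    id: str
    sequence: str
    structure: str | None = None
    label: str = UNLABELED

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        if self.label not in (POSITIVE, NEGATIVE, UNLABELED):
            raise ValidationError(f"record {self.id!r}: unknown label {self.label!r}")
        if self.structure is not None:
            if len(self.structure) != len(self.sequence):
                raise ValidationError(
                    f"record {self.id!r}: structure length {len(self.structure)} "
                    f"!= sequence length {len(self.sequence)}"
                )
            try:
                validate_dotbracket(self.structure, min_loop=0)
            except ValidationError as e:
                raise ValidationError(f"record {self.id!r}: {e}") from e


@dataclass(frozen=True)
class DatasetTable:
    """An ordered collection of records with unique ids."""

    records: tuple[SequenceRecord, ...]
    source: str = "memory"

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValidationError(f"duplicate record id {rec.id!r} in {self.source}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def subset(self, ids, source: str | None = None) -> "DatasetTable":
        """Records with the given ids, in the given order."""
        by_id = {r.id: r for r in self.records}
        return DatasetTable(
            records=tuple(by_id[i] for i in ids),
            source=source or self.source,
        )

    def with_source(self, source: str) -> "DatasetTable":
        return replace(self, source=source)


def read_fasta(path) -> DatasetTable:
    """Read a FASTA file into a table of unlabeled, structure-less records.

    Sequences are normalized (uppercase, T->U); a sequence line before
    any header, or a non-encodable character, aborts the read with a
    located error.
    """
    with open(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: sequence data before any FASTA header"
                )
            break
    records = []
    for entry in SeqIO.parse(io.StringIO(text), "fasta"):
        records.append(
            SequenceRecord(
                id=entry.id,
                sequence=normalize_sequence(str(entry.seq), record_id=entry.id),
            )
        )
    return DatasetTable(records=tuple(records), source=str(path))


@dataclass(frozen=True)
class TableDialect:
    """Column-name mapping for annotated dataset tables.

    Defaults match the benchmark layout: a structure column named
    ``RNAFolds`` next to ``sequence`` and an optional ``label``.  The id
    column is optional; missing ids are synthesized as ``rec0, rec1...``.
    """

    id: str = "id"
    sequence: str = "sequence"
    structure: str = "RNAFolds"
    label: str = "label"


def _parse_label(token, record_id: str) -> str:
    if token is None or (isinstance(token, float) and pd.isna(token)):
        return UNLABELED
    norm = str(token).strip().lower()
    if norm in _LABEL_TOKENS:
        return _LABEL_TOKENS[norm]
    raise ValidationError(f"record {record_id!r}: unknown label token {token!r}")


def read_annotated_table(
    path, dialect: TableDialect = TableDialect(), default_label: str | None = None
) -> DatasetTable:
    """Read a comma- or tab-delimited annotated table.

    Requires at least the sequence and structure columns of ``dialect``;
    the label column is optional (``default_label`` fills in for tables
    that are all one class, as the benchmark positive/negative files are).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    for col in (dialect.sequence, dialect.structure):
        if col not in df.columns:
            raise ParseError(
                f"{path}: required column {col!r} not found "
                f"(columns present: {list(df.columns)})"
            )
    has_id = dialect.id in df.columns
    has_label = dialect.label in df.columns
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        rid = str(row[dialect.id]) if has_id else f"rec{i}"
        seq = normalize_sequence(str(row[dialect.sequence]), record_id=rid)
        raw_struct = row[dialect.structure]
        if raw_struct is None or (isinstance(raw_struct, float) and pd.isna(raw_struct)):
            struct = None  # blank cell: structure genuinely absent
        else:
            struct = str(raw_struct).strip() or None
        if has_label:
            label = _parse_label(row[dialect.label], rid)
        else:
            label = default_label or UNLABELED
        records.append(SequenceRecord(id=rid, sequence=seq, structure=struct, label=label))
    return DatasetTable(records=tuple(records), source=str(path))


def write_annotated_table(table: DatasetTable, path, dialect: TableDialect = TableDialect()) -> None:
    """Write a table in the annotated-table layout (CSV)."""
    df = pd.DataFrame(
        {
            dialect.id: [r.id for r in table],
            dialect.sequence: [r.sequence for r in table],
            dialect.structure: [r.structure if r.structure is not None else "" for r in table],
            dialect.label: [r.label for r in table],
        }
    )
    df.to_csv(path, index=False)


def read_table_auto(path, **kwargs) -> DatasetTable:
    """Dispatch on file content: FASTA if it starts with '>', else table."""
    with open(path) as fh:
        head = fh.read(1)
    if head == ">":
        return read_fasta(path)
    return read_annotated_table(path, **kwargs)


def write_predictions(table: DatasetTable, scores, path, threshold: float = 0.5) -> None:
    """Write per-record positive-class probabilities and hard labels.

    A score exactly at the threshold is called positive (fixed tie rule).
    """
    scores = list(scores)
    if len(scores) != len(table):
        raise ValidationError(
            f"{len(scores)} scores for {len(table)} records"
        )
    for s in scores:
        if not (0.0 <= s <= 1.0):
            raise ValidationError(f"score {s} outside [0, 1]")
    df = pd.DataFrame(
        {
            "id": table.ids(),
            "probability": scores,
            "predicted_label": [POSITIVE if s >= threshold else NEGATIVE for s in scores],
        }
    )
    df.to_csv(path, index=False)
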