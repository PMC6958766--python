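"""Class balancing, train/validation/test splitting, and k-fold CV.

All sampling is a pure function of (input, seed): identical seeds give
bit-identical partitions.  Splits and folds are stratified by default so
per-partition class counts stay within one record of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import ValidationError
from .io_formats import DatasetTable, NEGATIVE, POSITIVE


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class SplitSpec:
    """Proportions for the train/validation/test partition.

    Defaults 0.64/0.16/0.20 reproduce the benchmark sizes
    (2408/602/752) from a 3762-record balanced merge.
    """

    train_frac: float = 0.64
    val_frac: float = 0.16
    test_frac: float = 0.20
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if any(not (0.0 < f < 1.0) for f in fracs):
            raise ValidationError("all split fractions must lie in (0, 1)")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValidationError(f"split fractions sum to {sum(fracs)}, not 1")


@dataclass(frozen=True)
class FoldAssignment:
    """Record id -> fold index map for k-fold cross-validation."""

    k: int
    fold_of: dict = field(repr=False)
    seed: int = 0

    def __post_init__(self):
        sizes = self.fold_sizes()
        if len(sizes) != self.k or max(sizes) - min(sizes) > 1:
            raise ValidationError(f"fold sizes {sizes} differ by more than 1")

    def fold_sizes(self) -> list[int]:
        counts = [0] * self.k
        for f in self.fold_of.values():
            counts[f] += 1
        return counts

    def ids_in_fold(self, fold: int) -> list[str]:
        return [rid for rid, f in self.fold_of.items() if f == fold]


def balance(positives: DatasetTable, negatives: DatasetTable, seed: int) -> DatasetTable:
    """Merge positives with an equal-size seeded subsample of negatives.

    The negative subsample is drawn without replacement; the merged
    table is then shuffled deterministically.
    """
    n_pos, n_neg = len(positives), len(negatives)
    if n_neg < n_pos:
        raise ValidationError(
            f"need at least as many negatives ({n_neg}) as positives ({n_pos})"
        )
    for rec in positives:
        if rec.label != POSITIVE:
            raise ValidationError(f"record {rec.id!r} in positive table has label {rec.label!r}")
    for rec in negatives:
        if rec.label != NEGATIVE:
            raise ValidationError(f"record {rec.id!r} in negative table has label {rec.label!r}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_neg, size=n_pos, replace=False)
    merged = list(positives.records) + [negatives.records[i] for i in sorted(chosen)]
    order = rng.permutation(len(merged))
    return DatasetTable(
        records=tuple(merged[i] for i in order),
        source=f"balanced({positives.source},{negatives.source})",
    )


def _partition_sizes(n: int, spec: SplitSpec) -> tuple[int, int, int]:
    # Nearest-integer rounding for val/test, remainder to train: this rule
    # maps 3762 at 0.64/0.16/0.20 to exactly (2408, 602, 752).
    n_val = _round_half_up(n * spec.val_frac)
    n_test = _round_half_up(n * spec.test_frac)
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) <= 0:
        raise ValidationError(
            f"split of {n} records at {spec.train_frac}/{spec.val_frac}/{spec.test_frac} "
            "yields an empty partition"
        )
    return n_train, n_val, n_test


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    exact = weights / weights.sum() * total
    base = np.floor(exact).astype(int)
    short = total - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:short]] += 1
    return base


def split(table: DatasetTable, spec: SplitSpec) -> tuple[DatasetTable, DatasetTable, DatasetTable]:
    """Seeded train/validation/test split; stratified by default."""
    n = len(table)
    n_train, n_val, n_test = _partition_sizes(n, spec)
    rng = np.random.default_rng(spec.seed)

    if not spec.stratified:
        order = rng.permutation(n)
        idx_train = order[:n_train]
        idx_val = order[n_train : n_train + n_val]
        idx_test = order[n_train + n_val :]
    else:
        labels = np.array(table.labels())
        classes = sorted(set(labels))
        idx_train, idx_val, idx_test = [], [], []
        class_indices = [np.nonzero(labels == c)[0] for c in classes]
        counts = np.array([len(ix) for ix in class_indices], dtype=float)
        val_per_class = _largest_remainder(n_val, counts)
        test_per_class = _largest_remainder(n_test, counts)
        for ix, nv, nt in zip(class_indices, val_per_class, test_per_class):
            ix = rng.permutation(ix)
            idx_val.extend(ix[:nv])
            idx_test.extend(ix[nv : nv + nt])
            idx_train.extend(ix[nv + nt :])
        idx_train = rng.permutation(np.array(idx_train, dtype=int))
        idx_val = rng.permutation(np.array(idx_val, dtype=int))
        idx_test = rng.permutation(np.array(idx_test, dtype=int))

    ids = table.ids()
    parts = tuple(
        table.subset([ids[i] for i in idx], source=f"{name}({table.source})")
        for idx, name in ((idx_train, "train"), (idx_val, "val"), (idx_test, "test"))
    )
    return parts


def make_folds(table: DatasetTable, k: int = 10, seed: int = 0, stratified: bool = True) -> FoldAssignment:
    """Assign every record to one of ``k`` near-equal folds."""
    n = len(table)
    if k < 2:
        raise ValidationError("k must be at least 2")
    if n < k:
        raise ValidationError(f"cannot make {k} folds from {n} records")
    ids = table.ids()
    labels = table.labels()
    # stratification is impossible once a class is smaller than k
    # (e.g. singleton folds); fall back to a plain shuffled partition
    smallest_class = min(labels.count(c) for c in set(labels))
    if stratified and smallest_class >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        iterator = splitter.split(np.zeros(n), labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        iterator = splitter.split(np.zeros(n))
    fold_of = {}
    for fold, (_, test_idx) in enumerate(iterator):
        for i in test_idx:
            fold_of[ids[i]] = fold
    return FoldAssignment(k=k, fold_of=fold_of, seed=seed)


def cv_iterate(assignment: FoldAssignment, table: DatasetTable):
    """Yield ``(train, test)`` table pairs, fold ``i`` held out as test."""
    ids = table.ids()
    missing = [i for i in ids if i not in assignment.fold_of]
    if missing:
        raise ValidationError(f"records without fold assignment: {missing[:5]}")
    for fold in range(assignment.k):
        test_ids = [i for i in ids if assignment.fold_of[i] == fold]
        train_ids = [i for i in ids if assignment.fold_of[i] != fold]
        yield (
            table.subset(train_ids, source=f"cv-train-{fold}"),
            table.subset(test_ids, source=f"cv-test-{fold}"),
        )


def write_assignment_sidecar(path, split_of: dict) -> None:
    """Serialize a record-id -> partition/fold mapping as TSV."""
    with open(path, "w") as fh:
        fh.write("id\tpartition\n")
        for rid, part in split_of.items():
            fh.write(f"{rid}\t{part}\n")
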