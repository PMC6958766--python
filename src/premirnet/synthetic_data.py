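"""Synthetic hairpin corpus generator.

Positives emulate miRNA precursors: a 5' arm, a short terminal loop and
the arm's reverse complement, with a small rate of seeded stem
mismatches and unpaired flanks; the recorded dot-bracket follows the
construction.  Negatives emulate pseudo hairpins only in the property
that matters to the classifier — weak, fragmented pairing — via random
sequences drawn from a pairing-poor (A/C-heavy) base composition and
rejection-sampled until their Nussinov fold pairs at most
``negative_pairing_target`` of their bases.  (A composition matched to
the positives cannot reach such a target: maximum base pairing on
uniform random RNA with GU wobble pairs well over half of all bases.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import DEFAULT_MAX_LEN
from .exceptions import ValidationError
from .io_formats import DatasetTable, NEGATIVE, POSITIVE, SequenceRecord
from .structure import fold_nussinov
from .utils import derive_seed

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_BASES = np.array(list("AUGC"))


@dataclass(frozen=True)
class SyntheticSpec:
    n_pos: int = 200
    n_neg: int = 200
    length_range: tuple[int, int] = (60, 120)
    stem_length_range: tuple[int, int] = (18, 35)
    loop_length_range: tuple[int, int] = (4, 10)
    mutation_rate: float = 0.05
    negative_pairing_target: float = 0.35
    seed: int = 0
    max_attempts: int = 200

    def __post_init__(self):
        for lo, hi in (self.length_range, self.stem_length_range, self.loop_length_range):
            if lo > hi or lo < 1:
                raise ValidationError("ranges must be non-empty and positive")
        if self.length_range[1] > DEFAULT_MAX_LEN:
            raise ValidationError(
                f"lengths above the encoder maximum {DEFAULT_MAX_LEN} are not generable"
            )
        if 2 * self.stem_length_range[0] + self.loop_length_range[0] > self.length_range[1]:
            raise ValidationError("minimum stem+loop exceeds the maximum length")
        if not (0.0 <= self.mutation_rate < 0.5):
            raise ValidationError("mutation_rate must lie in [0, 0.5)")
        if not (0.0 < self.negative_pairing_target < 1.0):
            raise ValidationError("negative_pairing_target must lie in (0, 1)")


def _random_sequence(rng, n: int, p=None) -> str:
    return "".join(rng.choice(_BASES, size=n, p=p))


def _make_positive(rng, spec: SyntheticSpec, rid: str) -> SequenceRecord:
    lo_len, hi_len = spec.length_range
    total = int(rng.integers(lo_len, hi_len + 1))
    s_lo, s_hi = spec.stem_length_range
    l_lo, l_hi = spec.loop_length_range
    # largest stem/loop combination that fits the drawn total length
    s_hi = min(s_hi, (total - l_lo) // 2)
    if s_hi < s_lo:
        total = 2 * s_lo + l_lo
        s_hi = s_lo
    stem = int(rng.integers(s_lo, s_hi + 1))
    l_hi_eff = min(l_hi, total - 2 * stem)
    loop = int(rng.integers(l_lo, l_hi_eff + 1)) if l_hi_eff > l_lo else l_lo
    flank_total = total - 2 * stem - loop
    flank5 = int(rng.integers(0, flank_total + 1))
    flank3 = flank_total - flank5

    arm5 = _random_sequence(rng, stem)
    arm3 = "".join(_COMPLEMENT[b] for b in reversed(arm5))
    loop_seq = _random_sequence(rng, loop)
    struct5 = ["("] * stem
    struct3 = [")"] * stem
    arm3 = list(arm3)
    # seeded mismatches: mutate a 3' arm base, unpairing both partners.
    # Surviving pairs never drop below the guaranteed minimum paired
    # fraction 2*stem_min/length_max, keeping the class separation an
    # invariant of the construction rather than a statistical accident.
    s_min, l_max = spec.stem_length_range[0], spec.length_range[1]
    required_pairs = int(np.ceil(s_min * total / l_max))
    surviving = stem
    for k in range(stem):
        if surviving > required_pairs and rng.random() < spec.mutation_rate:
            partner = stem - 1 - k
            choices = [b for b in "AUGC" if b != arm3[k]]
            arm3[k] = choices[int(rng.integers(0, 3))]
            struct5[partner] = "."
            struct3[k] = "."
            surviving -= 1
    sequence = (
        _random_sequence(rng, flank5) + arm5 + loop_seq + "".join(arm3)
        + _random_sequence(rng, flank3)
    )
    structure = (
        "." * flank5 + "".join(struct5) + "." * loop + "".join(struct3) + "." * flank3
    )
    return SequenceRecord(id=rid, sequence=sequence, structure=structure, label=POSITIVE)


def _make_negative(rng, spec: SyntheticSpec, rid: str) -> SequenceRecord:
    lo_len, hi_len = spec.length_range
    for _ in range(spec.max_attempts):
        total = int(rng.integers(lo_len, hi_len + 1))
        # pairing-poor composition: heavy in A and C, which cannot pair
        # with each other under Watson-Crick + wobble rules
        a = rng.uniform(0.32, 0.48)
        c = rng.uniform(0.32, 0.48)
        u = rng.uniform(0.02, 0.12)
        g = rng.uniform(0.02, 0.12)
        p = np.array([a, u, g, c]) / (a + u + g + c)
        sequence = _random_sequence(rng, total, p=p)
        db = fold_nussinov(sequence)
        if db.paired_fraction() <= spec.negative_pairing_target:
            return SequenceRecord(
                id=rid, sequence=sequence, structure=db.symbols, label=NEGATIVE
            )
    raise ValidationError(
        f"could not sample a negative with pairing fraction <= "
        f"{spec.negative_pairing_target} in {spec.max_attempts} attempts"
    )


def generate(spec: SyntheticSpec = SyntheticSpec()) -> DatasetTable:
    """Generate a labeled synthetic corpus, deterministic given the seed."""
    rng_pos = np.random.default_rng(derive_seed(spec.seed, "positives"))
    rng_neg = np.random.default_rng(derive_seed(spec.seed, "negatives"))
    records = [
        _make_positive(rng_pos, spec, f"pos{i:04d}") for i in range(spec.n_pos)
    ] + [
        _make_negative(rng_neg, spec, f"neg{i:04d}") for i in range(spec.n_neg)
    ]
    order = np.random.default_rng(derive_seed(spec.seed, "shuffle")).permutation(len(records))
    return DatasetTable(
        records=tuple(records[i] for i in order), source=f"synthetic(seed={spec.seed})"
    )


#: Frozen seed of the shared test corpus; changing it changes every
#: downstream expectation, so it is part of the package contract.
FIXTURE_SEED = 20200113
FIXTURE_SIZE = 200  # per class


def fixture_corpus(seed: int = FIXTURE_SEED) -> DatasetTable:
    """The small fixed corpus (200+200 records) used across the test suite."""
    return generate(SyntheticSpec(n_pos=FIXTURE_SIZE, n_neg=FIXTURE_SIZE, seed=seed))


def paired_fraction_gap(table: DatasetTable) -> float:
    """Mean paired-base fraction of positives minus that of negatives.

    A quantitative separation check that keeps classifier-recovery tests
    meaningful rather than vacuous.
    """
    from .structure import validate_dotbracket

    pos, neg = [], []
    for rec in table:
        frac = validate_dotbracket(rec.structure, min_loop=0).paired_fraction()
        (pos if rec.label == POSITIVE else neg).append(frac)
    if not pos or not neg:
        raise ValidationError("need both classes to measure the separation gap")
    return float(np.mean(pos) - np.mean(neg))
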