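"""RNA secondary structure: dot-bracket parsing and folding.

Structures are plain nested (pseudoknot-free) dot-bracket strings.  A
built-in Nussinov maximum base-pairing fold serves sequences that arrive
without a structure; an adapter shells out to an external folder (RNAfold
convention) when minimum-free-energy structures are wanted instead.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, ParseError, ValidationError

#: Watson-Crick plus wobble pairs admitted by the built-in folder.
ALLOWED_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

#: Minimum number of unpaired bases enclosed by a pair (hairpin-loop
#: convention of MFE folders).
DEFAULT_MIN_LOOP = 3

_STRUCT_RE = re.compile(r"^[().]+$")


@dataclass(frozen=True)
class DotBracket:
    """A validated dot-bracket string with its derived base pairs.

    ``pairs`` are 0-based ``(i, j)`` with ``i < j``, recovered by stack
    matching; nesting makes them mutually non-crossing by construction.
    """

    symbols: str
    pairs: tuple[tuple[int, int], ...] = field(default=())

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.symbols)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def paired_fraction(self) -> float:
        """Fraction of bases involved in a pair."""
        return 2 * len(self.pairs) / len(self.symbols) if self.symbols else 0.0


def validate_dotbracket(s: str, min_loop: int = DEFAULT_MIN_LOOP) -> DotBracket:
    """Parse and validate a dot-bracket string.

    Checks the 3-symbol alphabet, bracket balance, and the minimum
    hairpin-loop size of every derived pair.

    Raises
    ------
    ValidationError
        On an empty string, a foreign character, an unmatched bracket
        (the error names the offending position), or a loop shorter
        than ``min_loop``.
    """
    if not s:
        raise ValidationError("empty dot-bracket string")
    if not _STRUCT_RE.match(s):
        bad = next(i for i, c in enumerate(s) if c not in "().")
        raise ValidationError(
            f"invalid structure character {s[bad]!r} at position {bad}"
        )
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(s):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValidationError(f"unmatched ')' at position {i}")
            j = stack.pop()
            if i - j - 1 < min_loop:
                raise ValidationError(
                    f"pair ({j},{i}) encloses a loop of {i - j - 1} < {min_loop} bases"
                )
            pairs.append((j, i))
    if stack:
        raise ValidationError(f"unmatched '(' at position {stack[-1]}")
    return DotBracket(s, tuple(sorted(pairs)))


def _pair_matrix(sequence: str) -> np.ndarray:
    n = len(sequence)
    ok = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if (sequence[i], sequence[j]) in ALLOWED_PAIRS:
                ok[i, j] = True
    return ok


def fold_nussinov(sequence: str, min_loop: int = DEFAULT_MIN_LOOP) -> DotBracket:
    """Maximum base-pairing fold (Nussinov dynamic program).

    Maximizes the number of nested AU/GC/GU pairs subject to a minimum
    loop of ``min_loop`` unpaired bases.  The traceback is
    deterministic: when several choices achieve the optimum, position
    ``i`` is paired with the largest admissible partner ``j``.

    Returns the dot-bracket; the pair count is the global optimum, the
    particular structure is the fixed tie-break representative.
    """
    if not sequence:
        raise ValidationError("cannot fold an empty sequence")
    bad = set(sequence) - set("AUGC")
    if bad:
        raise ValidationError(f"sequence contains non-RNA characters {sorted(bad)}")
    n = len(sequence)
    if min_loop < 0:
        raise ValidationError("min_loop must be >= 0")

    ok = _pair_matrix(sequence)
    # M[i, j] = max pairs within sequence[i..j]; padded one row/col so the
    # vectorized split M[k+1, j] is safe at k == j.
    M = np.zeros((n + 1, n + 1), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1, j]
            ks = np.nonzero(ok[i, i + min_loop + 1 : j + 1])[0]
            if ks.size:
                ks = ks + i + min_loop + 1
                cand = 1 + M[i + 1, ks - 1] + M[ks + 1, j]
                best = max(best, int(cand.max()))
            M[i, j] = best

    symbols = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1:
            continue
        target = M[i, j]
        ks = np.nonzero(ok[i, i + min_loop + 1 : j + 1])[0]
        chosen = -1
        if ks.size:
            ks = ks + i + min_loop + 1
            cand = 1 + M[i + 1, ks - 1] + M[ks + 1, j]
            hits = ks[cand == target]
            if hits.size:
                chosen = int(hits.max())  # tie-break: largest admissible j
        if chosen >= 0:
            symbols[i] = "("
            symbols[chosen] = ")"
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))
        else:
            stack.append((i + 1, j))
    return validate_dotbracket("".join(symbols), min_loop=min_loop)


_ENERGY_SUFFIX = re.compile(r"\s*\(\s*-?\d+(\.\d+)?\s*\)\s*$")


def fold_external(
    sequence: str,
    tool_command: tuple[str, ...] = ("RNAfold", "--noPS"),
    timeout: float = 60.0,
) -> DotBracket:
    """Fold one sequence with an external tool (RNAfold output dialect).

    The tool receives the sequence on stdin and must print the sequence
    line followed by a dot-bracket line, optionally suffixed with a
    free-energy annotation like ``( -1.20)``, which is stripped.

    Raises
    ------
    ConfigurationError
        If the executable is missing (callers may fall back to
        :func:`fold_nussinov`).
    ParseError
        If no structure line of the right length can be extracted; the
        raw output is attached to the message.
    """
    if not sequence:
        raise ValidationError("cannot fold an empty sequence")
    exe = tool_command[0]
    if shutil.which(exe) is None:
        raise ConfigurationError(
            f"external folding tool {exe!r} not found on PATH; "
            "use structure mode 'builtin' (Nussinov) instead"
        )
    proc = subprocess.run(
        list(tool_command),
        input=sequence + "\n",
        capture_output=True,
        text=True,
        timeout=timeout,
    )
    if proc.returncode != 0:
        raise ParseError(
            f"{exe} exited with status {proc.returncode}: {proc.stderr.strip()}"
        )
    for line in proc.stdout.splitlines():
        candidate = _ENERGY_SUFFIX.sub("", line.strip())
        if candidate and _STRUCT_RE.match(candidate):
            if len(candidate) != len(sequence):
                raise ValidationError(
                    f"{exe} returned a structure of length {len(candidate)} "
                    f"for a sequence of length {len(sequence)}"
                )
            return validate_dotbracket(candidate)
    raise ParseError(
        f"could not find a dot-bracket line in {exe} output:\n{proc.stdout}"
    )


def ensure_structures(table, mode: str = "builtin", tool_command: tuple[str, ...] = ("RNAfold", "--noPS")):
    """Return a copy of ``table`` in which every record has a structure.

    Records that already carry a structure are passed through untouched;
    bare records are folded with the built-in Nussinov folder
    (``mode="builtin"``) or the external tool (``mode="external"``).
    """
    from .io_formats import DatasetTable, SequenceRecord

    if mode not in ("builtin", "external"):
        raise ValidationError(f"unknown structure mode {mode!r}")
    out = []
    for rec in table.records:
        if rec.structure is not None:
            out.append(rec)
            continue
        if mode == "builtin":
            db = fold_nussinov(rec.sequence)
        else:
            db = fold_external(rec.sequence, tool_command=tool_command)
        out.append(
            SequenceRecord(
                id=rec.id, sequence=rec.sequence, structure=db.symbols, label=rec.label
            )
        )
    return DatasetTable(records=out, source=table.source)
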