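"""Small shared helpers."""

from __future__ import annotations

import zlib


def derive_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from one global seed.

    Deterministic fan-out (documented: ``crc32(stage) xor`` mix, folded
    into 31 bits) so pipeline stages can be rerun independently yet
    reproducibly from a single run seed.
    """
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)
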