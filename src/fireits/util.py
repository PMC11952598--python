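"""Small shared helpers."""

from __future__ import annotations

import zlib

__all__ = ["derive_seed"]


def derive_seed(master: int, label: str) -> int:
    """Stable per-stage seed derived from a master seed and a stage label.

    Hashing the label means adding a stage never shifts the randomness of
    the others. Always below 2**31.
    """
    return zlib.crc32(f"{int(master)}:{label}".encode()) & 0x7FFFFFFF
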