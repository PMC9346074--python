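"""Deterministic derivation of per-task seeds from a master seed."""

from __future__ import annotations

import hashlib


def derive_seed(*parts) -> int:
    """Hash arbitrary parts (seed, method name, N, trial index, ...) into a
    31-bit seed, stable across processes and platforms."""
    payload = "\x1f".join(str(p) for p in parts).encode("utf-8")
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
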