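"""Deterministic derivation of per-stage seeds from one global seed."""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, stage: str) -> int:
    """Map (global seed, stage name) to a stable 32-bit stage seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big")
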