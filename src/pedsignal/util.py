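"""Small shared helpers: deterministic seed derivation."""

from __future__ import annotations

import hashlib

__all__ = ["seed_for"]


def seed_for(master_seed: int, *tokens) -> int:
    """Derive a reproducible child seed (< 2**31) from a master seed and tokens.

    Stable across processes and platforms (sha256-based, not ``hash()``).
    """
    key = ":".join([str(int(master_seed))] + [str(t) for t in tokens])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
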