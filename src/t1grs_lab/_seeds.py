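"""Deterministic child-seed derivation.

Every stochastic operation in the package derives its own seed from a master
seed and the operation's name, so that modules are independently reproducible:
re-running one stage never perturbs the random stream of another.
"""

from __future__ import annotations

import hashlib


def child_seed(master: int, name: str) -> int:
    """Derive a stable 31-bit child seed from ``(master, name)``.

    Uses SHA-256 so that distinct operation names give effectively
    independent streams and the mapping is stable across platforms.
    """
    digest = hashlib.sha256(f"{int(master)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
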