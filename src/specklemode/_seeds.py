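"""Deterministic seed splitting.

Every stochastic stage derives its own 31-bit seed from a master seed plus a
string path of tags via SHA-256, so suites are reproducible end to end while
stages stay statistically independent.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master: int, *tags: object) -> int:
    """31-bit child seed from (master, tag path); stable across platforms."""
    key = str(int(master)) + "/" + "/".join(str(t) for t in tags)
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
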