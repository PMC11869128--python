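"""Deterministic seed derivation.

A single user-facing seed is expanded into independent per-component
substreams by hashing the seed together with a tuple of string/int tokens.
Adding a new component therefore never perturbs the draws of existing ones.
All derived seeds are < 2**31 so they remain portable.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "substream"]


def derive_seed(base: int, *tokens: object) -> int:
    """Hash ``(base, tokens...)`` into a stable seed in ``[0, 2**31)``."""
    h = hashlib.sha256()
    h.update(str(int(base)).encode())
    for t in tokens:
        h.update(b"\x1f")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def substream(base: int, *tokens: object) -> np.random.Generator:
    """A ``numpy`` Generator seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(base, *tokens))
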