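"""Splittable, identifier-keyed random streams.

Every stochastic operation takes one integer seed; sub-streams for a pool,
site or sample are derived by hashing string identifiers into the seed
sequence, so the order in which pools or sites are evaluated can never change
the outcome.
"""

from __future__ import annotations

import hashlib

import numpy as np

_MASK31 = (1 << 31) - 1


def ident_hash(*parts: str) -> int:
    """Stable 32-bit hash of string identifiers (independent of PYTHONHASHSEED)."""
    h = hashlib.blake2b("/".join(parts).encode("utf-8"), digest_size=4)
    return int.from_bytes(h.digest(), "big")


def rng_for(seed: int, *parts: str) -> np.random.Generator:
    """A generator keyed by (seed, identifiers): same inputs, same stream."""
    entropy = [int(seed) & _MASK31] + [ident_hash(p) for p in parts]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def subseed(seed: int, *parts: str) -> int:
    """Derive a child integer seed (< 2**31) from a parent seed and labels."""
    return int(rng_for(seed, *parts).integers(0, _MASK31))
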