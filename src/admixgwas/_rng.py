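"""Seed handling.

All randomness in the package flows from a single integer seed. Independent
streams for different stages (admixture draw, local ancestry, genotypes,
features, traits, ...) are derived by hashing a string path into a
``numpy.random.SeedSequence`` entropy list, so any stage can be re-run in
isolation and reproduces bit-identically.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _label_to_uint32(label: str) -> int:
    digest = hashlib.blake2s(label.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little")


def substream(seed: int, *path: str) -> np.random.Generator:
    """Return a Generator for stream ``path`` derived from ``seed``.

    ``substream(seed, "trait", "rep3")`` is independent of
    ``substream(seed, "genotypes")`` but deterministic given the seed.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    entropy = [int(seed) & 0xFFFFFFFF, int(seed) >> 32]
    entropy.extend(_label_to_uint32(p) for p in path)
    return np.random.default_rng(np.random.SeedSequence(entropy))
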