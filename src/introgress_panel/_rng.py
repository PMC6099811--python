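"""Seed-stream helpers.

Every stochastic operation in the package takes an integer seed and derives an
independent, named substream from it, so stages can be re-run in isolation and
adding replicates never perturbs earlier ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key: int | str) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key)
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys: int | str) -> np.random.Generator:
    """Return a Generator for the substream named by ``keys`` under ``seed``.

    The same (seed, keys) pair always yields the same stream; distinct key
    tuples yield statistically independent streams.
    """
    entropy = [int(seed)] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
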