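"""Named random substreams derived from a single global seed.

Every stochastic operation in the package draws from a substream obtained
by hashing a stable stream name (CRC-32 of the UTF-8 name) into the
``spawn_key`` of a :class:`numpy.random.SeedSequence` whose entropy is the
user seed.  Adding a new generator therefore never perturbs the stream of
an existing one, and a (seed, name) pair always yields the same stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    Parameters
    ----------
    seed:
        Non-negative integer master seed.
    name:
        Stable stream label, e.g. ``"soil_table"`` or ``"bootstrap"``.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))
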