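"""Seed plumbing: one global integer seed, stable named substreams per stage."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator derived from ``seed`` and a stage label path.

    The same (seed, labels) pair always yields the same stream, and streams
    for different labels are independent, so reordering pipeline stages does
    not silently change any stage's randomness.
    """
    key = "/".join(str(l) for l in labels)
    digest = zlib.crc32(key.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, digest]))
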