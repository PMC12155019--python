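"""Named, independent random streams derived from one master seed.

Every stochastic component (data generation, parameter init, k-means,
batch shuffling, ...) pulls its own generator via :func:`seed_stream`, so
experiments can vary a single stream (e.g. the model seed) while holding all
others fixed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["seed_stream", "stream_entropy"]


def stream_entropy(master_seed: int, name: str) -> list[int]:
    """Deterministic entropy for a named stream under a master seed."""
    return [int(master_seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8"))]


def seed_stream(master_seed: int, name: str) -> np.random.Generator:
    """A generator for the named stream, independent across names."""
    return np.random.default_rng(stream_entropy(master_seed, name))
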