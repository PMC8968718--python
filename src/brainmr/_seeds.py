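"""Named substreams from a single master seed.

Every stochastic operation in the package draws from its own substream so
that stages can be regenerated independently without perturbing each other.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(master_seed: int, name: str) -> np.random.SeedSequence:
    """Deterministic seed sequence for the substream ``name``.

    crc32 of the name keeps the derivation stable across Python versions
    (the builtin ``hash`` is salted per process).
    """
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def substream(master_seed: int, name: str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` seeded from (master_seed, name)."""
    return np.random.default_rng(substream_seed(master_seed, name))
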