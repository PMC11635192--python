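"""Named random streams derived from a single master seed.

Every source of randomness in the package (fixed-pattern mismatch,
trial-to-trial noise, the genetic algorithm) draws from its own named
child stream of one master seed, so that runs are reproducible and the
streams are statistically independent of each other.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "stream_seed"]


def _key(names: tuple[str, ...]) -> tuple[int, ...]:
    return tuple(zlib.crc32(name.encode("utf-8")) for name in names)


def stream(master_seed: int, *names: str) -> np.random.Generator:
    """Return the generator for the named child stream of ``master_seed``.

    The mapping (master seed, names) -> stream is stable across runs and
    platforms: each name is hashed with CRC-32 into the spawn key of a
    :class:`numpy.random.SeedSequence`.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=_key(names))
    return np.random.default_rng(ss)


def stream_seed(master_seed: int, *names: str) -> int:
    """A 31-bit integer seed for the named child stream (for logging)."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=_key(names))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
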