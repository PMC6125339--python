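"""Deterministic random-stream management.

Every source of randomness in the package flows from a single master seed.
Stages draw from named substreams so that re-running one stage does not
perturb the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(master_seed: int, name: str) -> int:
    """Derive a stable 31-bit child seed for a named stage."""
    if not isinstance(master_seed, (int, np.integer)):
        raise TypeError(f"master seed must be an integer, got {master_seed!r}")
    tag = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(tag,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def substream(master_seed: int, name: str) -> np.random.Generator:
    """A Generator for the given stage name, deterministic in (seed, name)."""
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=(tag,))
    )
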