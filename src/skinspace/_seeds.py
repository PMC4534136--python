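"""Named, reproducible random substreams derived from a single master seed."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(master_seed: int, name: str) -> int:
    """Derive a deterministic child seed for a named pipeline stage.

    Uses CRC32 of the stage name so the mapping is stable across runs,
    platforms and Python processes (unlike the builtin ``hash``).
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode("utf-8"))])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31 - 1))


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return a fresh Generator for the named substream."""
    return np.random.default_rng(substream_seed(master_seed, name))
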