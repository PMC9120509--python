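"""Named, stable random streams.

Every stochastic stage derives its own child generator from a single root
seed plus a short stream name, so adding a new stage (or reordering calls)
never perturbs the draws of an existing one.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(seed: int, name: str) -> np.random.SeedSequence:
    """SeedSequence for the stream `name` under root `seed`."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Generator for the stream `name` under root `seed` (deterministic)."""
    return np.random.default_rng(child_seed(seed, name))
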