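"""Named RNG substreams.

Every stochastic operation draws from a generator derived from
``(seed, stream-name)``, so adding a new generator or reordering calls
never perturbs another operation's stream.
"""

from __future__ import annotations

import hashlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a stable hash of ``name``."""
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def child_seed(seed: int, name: str) -> int:
    """A derived integer seed (< 2**31) for libraries that take plain ints."""
    return int(substream(seed, name).integers(0, 2**31 - 1))
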