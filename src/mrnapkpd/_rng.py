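"""Named random substreams.

Every stochastic operation in the package draws from a substream derived
from a single root seed plus a tuple of string/int keys.  Substreams are
independent, so e.g. adding an observable (its residual-error stream) never
perturbs the subject-level random-effect draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _entropy(seed: int, keys: tuple) -> list[int]:
    ent = [int(seed)]
    for k in keys:
        ent.append(zlib.crc32(str(k).encode("utf-8")))
    return ent


def substream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the substream named by ``keys`` under ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(_entropy(seed, keys)))


def child_seed(seed: int, *keys) -> int:
    """A deterministic integer seed (< 2**31) for the named substream."""
    state = np.random.SeedSequence(_entropy(seed, keys)).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF
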