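"""Seed management.

A single 64-bit study seed fans out to per-stage child generators through
``numpy.random.SeedSequence.spawn``; stage k of a run is therefore
independently reproducible given (seed, stage index), and the whole run is
bitwise reproducible given the seed alone.
"""

from __future__ import annotations

import numpy as np


def generator(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


def child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Deterministically split one seed into ``n`` independent streams."""
    return np.random.SeedSequence(seed).spawn(n)


def child_generators(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in child_seeds(seed, n)]
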