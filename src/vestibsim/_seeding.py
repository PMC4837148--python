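"""Deterministic sub-seed derivation.

Every stochastic operation in the package draws from a Generator obtained
here, so that scans and multi-seed averages are reproducible bit-for-bit
given a master seed, while cells/phases remain statistically independent.
"""
from __future__ import annotations

import numpy as np


def spawn_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Return a Generator for the stream identified by (master_seed, key).

    Distinct keys give independent streams; the same (seed, key) pair always
    gives the same stream.
    """
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key)))
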