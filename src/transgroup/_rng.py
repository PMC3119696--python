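"""Seed handling shared by all stochastic operations."""
from __future__ import annotations

import numpy as np

RngLike = "int | np.random.Generator | np.random.SeedSequence | None"


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, or Generator to a Generator.

    Passing a Generator through unchanged lets callers thread one RNG
    through a whole batch while still accepting plain integer seeds at
    the API surface.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seed(rng: np.random.Generator) -> int:
    """Draw an independent 31-bit child seed from *rng*."""
    return int(rng.integers(0, 2**31 - 1))
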