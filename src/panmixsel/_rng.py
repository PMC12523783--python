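"""Seed handling shared by all modules."""
from __future__ import annotations

import numpy as np

SeedLike = "int | np.random.Generator | np.random.SeedSequence | None"


def as_rng(seed) -> np.random.Generator:
    """Return a numpy Generator from an int seed, a SeedSequence, an existing
    Generator (passed through), or None (OS entropy)."""
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(seed)


def spawn(seed, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from a seed by counter-based
    spawning, so adding streams never perturbs earlier ones."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    elif isinstance(seed, np.random.Generator):
        # fall back to drawing child seeds from the generator
        return [np.random.default_rng(s) for s in seed.integers(0, 2**31 - 1, n)]
    else:
        ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]
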