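"""Shared RNG plumbing."""

import numpy as np

SeedLike = "int | np.random.Generator"


def as_rng(seed):
    """Return a numpy Generator from an int seed (or pass a Generator through)."""
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("an explicit seed (or Generator) is required")
    return np.random.default_rng(int(seed))


def kernel_seed(rng):
    """Derive a 31-bit sub-seed for the numba kernel stream."""
    return int(rng.integers(1, 2**31 - 1))
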