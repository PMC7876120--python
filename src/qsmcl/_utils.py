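"""Shared helpers: RNG normalization and stable per-stage seed derivation."""

from __future__ import annotations

import hashlib

import numpy as np

RNGLike = "int | np.random.Generator | None"


def as_rng(seed) -> np.random.Generator:
    """Return a numpy Generator from an int seed, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def derive_seed(master_seed: int, stage: str) -> int:
    """Expand one master seed into a stable per-stage seed (< 2**31).

    Hashing the stage name means adding a new stage never perturbs the
    random stream of existing stages.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
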