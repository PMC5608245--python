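"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["sigmoid", "spawn_rng", "as_rng"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable elementwise logistic function."""
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed or an existing Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rng(seed: int, *keys: str) -> np.random.Generator:
    """Derive a named, reproducible substream from a master seed.

    Every stochastic stage of the pipeline draws from a substream keyed by
    its stage name, so a single master seed makes a whole run reproducible
    while stages stay independent.
    """
    material = [int(seed)] + [int.from_bytes(k.encode(), "little") % (2**32) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(material))
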