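"""Seeded random-number streams.

Every stochastic component draws from a named child stream of a single root
seed, so toggling one source of randomness (e.g. PN noise) never perturbs the
draws of another (e.g. connectivity).
"""

from __future__ import annotations

import numpy as np

# Fixed order defines the spawn key of each named stream; append only.
_STREAMS = (
    "connectivity",
    "weights",
    "thresholds",
    "pn_noise",
    "synthetic",
    "stats",
)


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of ``seed``."""
    try:
        idx = _STREAMS.index(name)
    except ValueError:
        raise KeyError(f"unknown RNG stream {name!r}; known: {_STREAMS}") from None
    ss = np.random.SeedSequence(seed, spawn_key=(idx,))
    return np.random.default_rng(ss)


def as_generator(seed) -> np.random.Generator:
    """Coerce an int seed or Generator to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
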