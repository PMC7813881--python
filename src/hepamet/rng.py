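"""Named, independent random streams derived from one scenario seed.

Tissue generation and simulation stochasticity draw from separate streams so
that a tissue is reproducible independent of downstream randomness.
"""

from __future__ import annotations

import zlib

import numpy as np

# fixed stream tags; never reuse a tag for a new purpose
_STREAMS = ("tissue", "simulation", "division", "tiebreak", "sweep")


def rng_stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named stream of a scenario seed."""
    if name not in _STREAMS:
        raise KeyError(f"unknown rng stream {name!r}")
    tag = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
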