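"""Single-seed fan-out: every stochastic component draws a named substream.

Adding a component does not perturb existing streams, and derived seeds stay
below 2**31.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master: int, *names: str) -> int:
    """Deterministic child seed for a named component."""
    tags = [zlib.crc32(n.encode()) for n in names]
    ss = np.random.SeedSequence([int(master)] + tags)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def derive_rng(master: int, *names: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, *names))
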