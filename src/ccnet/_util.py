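"""Shared helpers: canonical edge ordering, seed derivation, logging."""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger("ccnet")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered gene pair (a, b) in canonical (sorted) order."""
    return (a, b) if a <= b else (b, a)


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed.

    Uses numpy's SeedSequence spawning so stages sharing a master seed get
    statistically independent, reproducible streams.
    """
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def rng_from(seed) -> np.random.Generator:
    return np.random.default_rng(seed)
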