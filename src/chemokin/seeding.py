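"""Seed plumbing: one top-level seed fans out into named substreams.

Every stochastic stage (trajectory generation, shot noise, Ca2+ noise,
bootstrap) draws from its own child of a single top-level SeedSequence,
so stages are independently reproducible and enlarging one ensemble does
not perturb the others.
"""

from __future__ import annotations

import numpy as np

__all__ = ["as_seed_sequence"]


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Accept an int seed or an already-spawned SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)
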