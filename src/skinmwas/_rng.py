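"""Seed plumbing: one integer master seed, labeled per-stage child streams.

Each simulation stage draws from its own ``numpy`` Generator derived from the
master seed and a fixed stage label, so a stage's output is reproducible
independently of how many draws earlier stages made.
"""

from __future__ import annotations

import numpy as np

# Fixed label -> spawn-key table. Never reorder or reuse ids; append only.
_STAGES = {
    "cohort": 0,
    "taxa": 1,
    "genes": 2,
    "characters": 3,
    "cap_permutation": 4,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return the dedicated Generator for *stage* under the master *seed*."""
    try:
        key = _STAGES[stage]
    except KeyError:
        raise KeyError(f"unknown RNG stage {stage!r}; known: {sorted(_STAGES)}")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
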