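"""Hierarchical random-number streams.

One root seed spawns a named substream for every (purpose, index...) pair via
``numpy.random.SeedSequence`` spawn keys, so each random quantity of each
individual / replicate / arm has its own reproducible stream: adding
individuals or replicates never perturbs draws already made for earlier
ones.
"""

from __future__ import annotations

import numpy as np

# Stable integer codes for named streams.  Never reorder or reuse a code:
# they are part of the reproducibility contract of a seed.
_PURPOSE_CODES = {
    "age": 1,
    "k": 2,
    "d_max": 3,
    "onset": 4,
    "other_death": 5,
    "detect_burn_in": 6,
    "detect_study": 7,
    "cancer_death": 8,
    "bootstrap": 9,
    "misc": 10,
}


class StreamFactory:
    """Factory of independent Generators keyed by (purpose, *indices)."""

    def __init__(self, seed: int):
        if not 0 <= int(seed) < 2**63:
            raise ValueError("seed must be a non-negative 63-bit integer")
        self.seed = int(seed)

    def rng(self, purpose: str, *indices: int) -> np.random.Generator:
        code = _PURPOSE_CODES[purpose]
        key = (code, *[int(i) for i in indices])
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=key))

    def child_seed(self, *indices: int) -> int:
        """Derive a reproducible 31-bit integer seed for a sub-task."""
        ss = np.random.SeedSequence(self.seed, spawn_key=tuple(int(i) for i in indices))
        return int(ss.generate_state(1, np.uint32)[0] % (2**31))
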