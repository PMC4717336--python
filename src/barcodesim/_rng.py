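"""Deterministic random-stream derivation.

One root seed governs a whole study.  Every stage (dataset, estimator
schedule, subsample size) receives its own independent stream derived from
the root seed plus documented integer offsets, so any stage can be re-run
in isolation and reproduce its output bit for bit.
"""

from __future__ import annotations

import numpy as np

__all__ = ["derive_rng", "derive_seedseq"]


def derive_seedseq(root_seed: int, *offsets: int) -> np.random.SeedSequence:
    """Build a ``SeedSequence`` from a root seed and integer stream offsets.

    The entropy pool is the tuple ``(root_seed, *offsets)``; distinct offset
    tuples yield statistically independent streams.
    """
    return np.random.SeedSequence([int(root_seed), *map(int, offsets)])


def derive_rng(root_seed: int, *offsets: int) -> np.random.Generator:
    """A ``numpy`` generator on the stream identified by ``offsets``."""
    return np.random.default_rng(derive_seedseq(root_seed, *offsets))
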