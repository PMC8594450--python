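"""Seed-tree utilities.

All randomness in the package flows through named streams derived from a
single master seed. Streams are identified by fixed integer ids, so adding a
new stream name never perturbs draws of existing streams, and any image can be
re-created from ``(master_seed, stream, *indices)``.
"""

from __future__ import annotations

import numpy as np

# Fixed ids; append only, never renumber.
STREAM_IDS = {
    "clb": 1,
    "signal": 2,
    "mc": 3,
    "noise": 4,
    "shuffle": 5,
    "init": 6,
    "training": 7,
    "misc": 8,
}


def child_seed(master_seed: int, stream: str, *indices: int) -> tuple[int, ...]:
    """Return the entropy chain for a named child stream."""
    if stream not in STREAM_IDS:
        raise KeyError(f"unknown stream {stream!r}; known: {sorted(STREAM_IDS)}")
    return (int(master_seed), STREAM_IDS[stream], *map(int, indices))


def stream_rng(master_seed: int, stream: str, *indices: int) -> np.random.Generator:
    """Independent generator for a named stream of the seed tree."""
    return np.random.default_rng(np.random.SeedSequence(child_seed(master_seed, stream, *indices)))
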