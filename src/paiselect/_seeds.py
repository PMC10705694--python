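"""Deterministic expansion of one global seed into per-stage seeds.

Every stochastic stage (simulation, treatment assignment, fold shuffling,
bootstrap, permutation, matching order) draws its own child seed from the
global seed plus a stage label, so stages stay decoupled: adding repeats to
one stage never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31  # keep child seeds well inside int32 range


def child_seed(seed: int, label: str, index: int = 0) -> int:
    """Derive a reproducible child seed from (seed, label, index)."""
    entropy = [int(seed), zlib.crc32(label.encode("utf-8")), int(index)]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % _MOD)


def rng_for(seed: int, label: str, index: int = 0) -> np.random.Generator:
    """A numpy Generator seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(seed, label, index))
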