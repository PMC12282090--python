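"""Seed handling: one user-facing seed, per-stage substreams."""

from __future__ import annotations

import numpy as np

_STAGE_OFFSETS = {
    "sources": 0,
    "activities": 1,
    "expression_noise": 2,
    "ica": 3,
    "process": 4,
    "simulation": 5,
}


def stage_seed_sequence(seed: int, stage: str) -> np.random.SeedSequence:
    """Derive a stage-specific SeedSequence from one global seed.

    Each named stage gets an independent substream so that, e.g., changing
    the number of ICA restarts never perturbs the synthetic data itself.
    """
    if stage not in _STAGE_OFFSETS:
        raise KeyError(f"unknown RNG stage {stage!r}")
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE_OFFSETS[stage],))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed_sequence(seed, stage))


def child_ints(ss: np.random.SeedSequence, n: int) -> list[int]:
    """n reproducible integer seeds (< 2**31) derived from a SeedSequence."""
    return [int(s) % (2**31) for s in ss.generate_state(n)]
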