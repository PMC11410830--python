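"""Seed-stream derivation.

Every stage of the pipeline draws its randomness from an independent stream
derived from one master seed by hashing the stage name, so changing the
bootstrap depth of one stage never perturbs the draws of another.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stage_seed", "stage_rng"]

_MOD = 2**31 - 1


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stable 31-bit seed for ``stage`` from ``master_seed``."""
    digest = hashlib.sha256(f"{int(master_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % _MOD


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """A ``numpy`` Generator seeded for one named pipeline stage."""
    return np.random.default_rng(stage_seed(master_seed, stage))
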