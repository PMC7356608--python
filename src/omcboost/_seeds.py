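"""Deterministic derivation of sub-seeds from one master seed.

Every stage of the pipeline (test split, fold assignment, per-fold boosters,
final ensemble seeds, y-randomization) draws its seed from a named channel so
each stage is independently reproducible from the master seed alone.
"""

from __future__ import annotations

import numpy as np

# Channel indices are part of the reproducibility contract: changing them
# changes every downstream result.
CHANNELS = {
    "split": 0,
    "folds": 1,
    "cv_booster": 2,
    "final_omc": 3,
    "final_all": 4,
    "y_randomization": 5,
    "synthetic": 6,
}

_MAX_SEED = 2**31  # xgboost and legacy RNG interfaces want signed 32-bit ints


def derive_seed(master_seed: int, channel: str, index: int = 0) -> int:
    """Return a sub-seed for ``channel`` (optionally the ``index``-th of a series)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(CHANNELS[channel], index))
    return int(ss.generate_state(1)[0] % _MAX_SEED)


def derive_seeds(master_seed: int, channel: str, n: int) -> list[int]:
    """Return ``n`` sub-seeds for a series of runs on one channel."""
    return [derive_seed(master_seed, channel, i) for i in range(n)]
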