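"""Winner-take-all preference maps between two encoding models.

For every voxel with r_CV under both models, the winner is the model with
the larger cross-validated prediction correlation and the strength is the
margin |r_a - r_b| (the color-saturation quantity on a cortical map).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import DataError

logger = logging.getLogger(__name__)

TIE = 0
MISSING = -1


@dataclass
class PreferenceMap:
    """Per-voxel model comparison.

    winner: 1 where the first model wins, 2 for the second, 0 for exact
    ties, -1 where either r_CV was missing; strength: |r_a - r_b|, zero
    on ties and missing voxels.
    """

    winner: np.ndarray
    strength: np.ndarray
    model_names: tuple[str, str]
    n_dropped: int = 0


def preference_map(r_a: np.ndarray, r_b: np.ndarray,
                   model_names: tuple[str, str] = ("model_a", "model_b"),
                   ) -> PreferenceMap:
    """Compare two per-voxel r_CV maps voxel-wise."""
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    if r_a.shape != r_b.shape:
        raise DataError("r_CV maps index different voxels")
    missing = np.isnan(r_a) | np.isnan(r_b)
    n_dropped = int(missing.sum())
    if n_dropped:
        logger.info("preference map: dropped %d voxels with missing r_CV",
                    n_dropped)
    winner = np.full(r_a.shape, MISSING, dtype=int)
    strength = np.zeros(r_a.shape)
    valid = ~missing
    winner[valid & (r_a > r_b)] = 1
    winner[valid & (r_b > r_a)] = 2
    winner[valid & (r_a == r_b)] = TIE
    strength[valid] = np.abs(r_a[valid] - r_b[valid])
    return PreferenceMap(winner=winner, strength=strength,
                         model_names=tuple(model_names),
                         n_dropped=n_dropped)
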