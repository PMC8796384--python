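"""Objective-variable clamping and the Kennard-Stone train/test split.

The regression target is the plasma protein binding rate clamped to
[50, 95] (%PPB50-95): values below 50% are practically equivalent for drug
candidates and values above 95% saturate the assay's useful resolution.

The Kennard-Stone algorithm picks a space-covering subset deterministically:
seed with the two points at maximum Euclidean distance, then repeatedly add
the point whose minimum distance to the already-selected set is largest.
The selected points form the *test* set, so the held-out data uniformly
covers descriptor space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["PPB_FLOOR", "PPB_CEIL", "PPBRecord", "clamp_ppb", "kennard_stone_split"]

PPB_FLOOR = 50.0
PPB_CEIL = 95.0


@dataclass(frozen=True)
class PPBRecord:
    """A peptide with its raw and clamped %PPB label."""

    peptide_id: str
    y_raw: float
    y_clamped: float

    @staticmethod
    def from_raw(peptide_id: str, y_raw: float) -> "PPBRecord":
        return PPBRecord(peptide_id, float(y_raw), float(clamp_ppb(y_raw)))


def clamp_ppb(y):
    """Clamp %PPB to [50, 95]; accepts scalars or arrays.

    Raises ``ValueError`` if any value lies outside [0, 100].
    """
    arr = np.asarray(y, dtype=float)
    if np.any(arr < 0) or np.any(arr > 100) or np.any(~np.isfinite(arr)):
        raise ValueError("%PPB must lie within [0, 100]")
    out = np.clip(arr, PPB_FLOOR, PPB_CEIL)
    return float(out) if np.isscalar(y) or arr.ndim == 0 else out


def kennard_stone_split(
    features: pd.DataFrame | np.ndarray, test_fraction: float
) -> tuple[list, list]:
    """Split rows into (train ids, test ids) with the Kennard-Stone algorithm.

    ``features`` should already be standardized.  The test-set size is
    ``ceil(test_fraction * N)``.  Distance ties are broken by the smallest
    row index, making the split fully deterministic.  Returned id lists
    preserve the original row order.
    """
    if isinstance(features, pd.DataFrame):
        ids = list(features.index)
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        ids = list(range(x.shape[0]))
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    k = math.ceil(test_fraction * n)
    if k < 1 or k >= n:
        raise ValueError(
            f"test size {k} out of range for N={n} (test_fraction={test_fraction})"
        )

    dist = cdist(x, x)
    # seed pair at maximum distance; np.argmax returns the first (smallest
    # lexicographic index pair) on ties
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    selected = [int(i), int(j)]
    in_sel = np.zeros(n, dtype=bool)
    in_sel[[i, j]] = True
    min_dist = np.minimum(dist[i], dist[j])

    while len(selected) < k:
        cand = np.where(~in_sel, min_dist, -np.inf)
        nxt = int(np.argmax(cand))
        selected.append(nxt)
        in_sel[nxt] = True
        min_dist = np.minimum(min_dist, dist[nxt])

    test_mask = in_sel
    train_ids = [ids[t] for t in range(n) if not test_mask[t]]
    test_ids = [ids[t] for t in range(n) if test_mask[t]]
    return train_ids, test_ids
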