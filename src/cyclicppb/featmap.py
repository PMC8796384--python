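"""Fixed-length feature maps and cyclic rotation/translation augmentation.

A peptide with n substructures (n <= 15) becomes a D x 15 array: the n
descriptor vectors occupy a contiguous span, centered among zero padding.
Because the molecule is a ring, neither the start residue nor the placement
within the 15 slots is physically meaningful; augmentation therefore
enumerates every cyclic rotation r in 0..n-1 of the residue order at every
translation t in 0..15-n of the span, yielding n * (15 - n + 1) replicas per
peptide.  Column t + j of a replica holds the descriptor vector of ring
position (j + r) mod n.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["MAX_LENGTH", "FeatureMap", "build_feature_map", "augment", "replica_count"]

#: maximum number of substructures a map can hold
MAX_LENGTH = 15


@dataclass(frozen=True)
class FeatureMap:
    """A D x L descriptor array with its occupied span and provenance."""

    values: np.ndarray  # shape (D, L), zeros outside the span
    start: int  # span start == translation t
    n: int  # occupied length (number of substructures)
    peptide_id: str = ""
    rotation: int = 0

    @property
    def translation(self) -> int:
        return self.start

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.n)

    def ring_vectors(self) -> np.ndarray:
        """The (n, D) substructure vectors in ring order (rotation undone)."""
        block = self.values[:, self.start : self.start + self.n].T  # (n, D)
        return np.roll(block, self.rotation, axis=0)


def build_feature_map(
    substructure_vectors, L: int = MAX_LENGTH, peptide_id: str = ""
) -> FeatureMap:
    """Place the ring-ordered substructure vectors centered in a D x L map.

    ``substructure_vectors`` is an (n, D) array or sequence of D-vectors in
    ring order.  The span start is floor((L - n) / 2); rotation is 0.
    """
    vecs = np.asarray(substructure_vectors, dtype=float)
    if vecs.ndim == 1:
        vecs = vecs[:, None]
    n = vecs.shape[0]
    if n < 1:
        raise ValueError("need at least one substructure vector")
    if n > L:
        raise ValueError(f"peptide too long for Max_length: n={n} > L={L}")
    d = vecs.shape[1]
    start = (L - n) // 2
    values = np.zeros((d, L))
    values[:, start : start + n] = vecs.T
    return FeatureMap(values=values, start=start, n=n, peptide_id=peptide_id)


def replica_count(n: int, L: int = MAX_LENGTH) -> int:
    """Number of augmentation replicas for a peptide of n substructures."""
    return n * (L - n + 1)


def augment(fmap: FeatureMap) -> list[FeatureMap]:
    """All rotation x translation replicas of a feature map.

    Returns n * (L - n + 1) maps including the identity replica (the input's
    own rotation and translation).  Replicas are enumerated deterministically:
    rotations in 0..n-1 (outer), translations in 0..L-n (inner).
    """
    d, L = fmap.values.shape
    n = fmap.n
    ring = fmap.ring_vectors()  # (n, D), rotation undone
    out = []
    for r in range(n):
        rotated = np.roll(ring, -r, axis=0)  # row j holds ring position (j+r) mod n
        for t in range(L - n + 1):
            values = np.zeros((d, L))
            values[:, t : t + n] = rotated.T
            out.append(
                FeatureMap(
                    values=values,
                    start=t,
                    n=n,
                    peptide_id=fmap.peptide_id,
                    rotation=r,
                )
            )
    return out
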