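"""Gradient saliency: which substructure drives the predicted binding rate.

The saliency score of input entry x_ij is the absolute partial derivative of
the raw (unclamped) model output with respect to that entry, evaluated by a
single backward pass (VanillaGrad).  The gradient is taken before clamping:
the clamp saturates to zero gradient at the boundaries and would erase
attribution exactly for the strongly bound peptides one most wants to
explain.  Replica saliencies are mapped back to ring positions through their
(rotation, translation) provenance and averaged, so the arbitrary anchor of
the decomposition cancels out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .featmap import FeatureMap, augment
from .model import Network

__all__ = ["SaliencyMap", "saliency", "aggregate_saliency"]


@dataclass
class SaliencyMap:
    """Replica-averaged attribution per (descriptor, ring position)."""

    peptide_id: str
    scores: np.ndarray  # (D, n)

    @property
    def per_substructure(self) -> np.ndarray:
        """Total attribution per ring position (sum over descriptors)."""
        return self.scores.sum(axis=0)


def saliency(model: Network, fmap: FeatureMap) -> np.ndarray:
    """|d y_hat / d x| for one feature map, shape (D, L).

    Evaluated in eval mode (batch-norm running statistics), so the gradient
    belongs to this input alone.
    """
    x = fmap.values[None]
    spans = np.array([[fmap.start, fmap.n]], dtype=np.intp)
    model.forward(x, spans, train=False)
    grad = model.backward(np.ones((1, 1)))
    return np.abs(grad[0])


def aggregate_saliency(
    model: Network, fmap: FeatureMap, augment_input: bool = True
) -> SaliencyMap:
    """Average saliency over augmentation replicas, mapped to ring positions.

    Column t + j of a replica with rotation r attributes to ring position
    (j + r) mod n; padding columns are discarded.
    """
    maps = augment(fmap) if augment_input else [fmap]
    d = fmap.values.shape[0]
    n = fmap.n
    acc = np.zeros((d, n))
    for rep in maps:
        if rep.peptide_id != fmap.peptide_id:
            raise ValueError("replica provenance mismatch: different peptide ids")
        s = saliency(model, rep)
        span = s[:, rep.start : rep.start + rep.n]
        ring_pos = (np.arange(rep.n) + rep.rotation) % rep.n
        acc[:, ring_pos] += span
    acc /= len(maps)
    return SaliencyMap(peptide_id=fmap.peptide_id, scores=acc)
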