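"""2D physicochemical descriptors, Z-score standardization, frequency weighting.

The three descriptors the pipeline ultimately feeds into the network are
open-source surrogates of the classic commercial trio for plasma-protein
binding work:

* ``logP_crippen`` — Crippen atomic-contribution octanol/water logP
  (surrogate for logP(o/w));
* ``peoe_vsa_neg1`` — Gasteiger-charge-binned van der Waals surface area,
  most negative charge bin (surrogate for PEOE_VSA-1);
* ``logS_esol`` — Delaney-style estimated aqueous solubility
  (surrogate for logS).

A wider configurable set of 2D descriptors is exposed so that feature
selection has a realistic search space.  The engine name is recorded in
output metadata so values from different engines are never mixed.

Standardization uses the Z-score z = (x - mu) / sigma where mu and sigma are
the mean and *population* standard deviation of the whole-peptide descriptor
over the training reference set; substructure descriptor values are scaled
with the same whole-peptide statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

__all__ = [
    "ENGINE_NAME",
    "DEFAULT_DESCRIPTORS",
    "available_descriptors",
    "compute_descriptors",
    "compute_matrix",
    "DescriptorMatrix",
    "standardize",
    "weight_by_frequency",
]

ENGINE_NAME = "rdkit-2d-surrogate"


def _esol_logs(mol: Chem.Mol) -> float:
    """Delaney ESOL estimated log10 aqueous solubility (mol/L)."""
    logp = Crippen.MolLogP(mol)
    mw = Descriptors.MolWt(mol)
    rb = Descriptors.NumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    ap = (
        sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()) / heavy
        if heavy
        else 0.0
    )
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rb - 0.74 * ap


_REGISTRY: dict[str, Callable[[Chem.Mol], float]] = {
    "logP_crippen": Crippen.MolLogP,
    "peoe_vsa_neg1": Descriptors.PEOE_VSA1,
    "logS_esol": _esol_logs,
    "mol_weight": Descriptors.MolWt,
    "tpsa": Descriptors.TPSA,
    "molar_refractivity": Crippen.MolMR,
    "heavy_atom_count": Descriptors.HeavyAtomCount,
    "h_bond_donors": Descriptors.NumHDonors,
    "h_bond_acceptors": Descriptors.NumHAcceptors,
    "rotatable_bonds": Descriptors.NumRotatableBonds,
    "ring_count": Descriptors.RingCount,
    "aromatic_rings": Descriptors.NumAromaticRings,
    "fraction_csp3": Descriptors.FractionCSP3,
    "balaban_j": Descriptors.BalabanJ,
    "bertz_ct": Descriptors.BertzCT,
    "hall_kier_alpha": Descriptors.HallKierAlpha,
    "kappa1": Descriptors.Kappa1,
    "kappa2": Descriptors.Kappa2,
    "kappa3": Descriptors.Kappa3,
    "chi0v": Descriptors.Chi0v,
    "chi1v": Descriptors.Chi1v,
    "chi2v": Descriptors.Chi2v,
    "chi3v": Descriptors.Chi3v,
    "chi4v": Descriptors.Chi4v,
    "labute_asa": Descriptors.LabuteASA,
    "num_heteroatoms": Descriptors.NumHeteroatoms,
    "num_amide_bonds": rdMolDescriptors.CalcNumAmideBonds,
    "max_partial_charge": Descriptors.MaxPartialCharge,
    "min_partial_charge": Descriptors.MinPartialCharge,
}
# charge-binned and logP-binned surface-area families
for _i in range(2, 15):
    _REGISTRY[f"peoe_vsa_{_i}"] = getattr(Descriptors, f"PEOE_VSA{_i}")
for _i in range(1, 11):
    _REGISTRY[f"smr_vsa_{_i}"] = getattr(Descriptors, f"SMR_VSA{_i}")
for _i in range(1, 13):
    _REGISTRY[f"slogp_vsa_{_i}"] = getattr(Descriptors, f"SlogP_VSA{_i}")

#: the trio used by default throughout the pipeline
DEFAULT_DESCRIPTORS: tuple[str, ...] = ("logP_crippen", "peoe_vsa_neg1", "logS_esol")


def available_descriptors() -> list[str]:
    """Names of every descriptor the engine can compute."""
    return list(_REGISTRY)


def compute_descriptors(
    smiles: str, descriptor_set: list[str] | tuple[str, ...] = DEFAULT_DESCRIPTORS
) -> pd.Series:
    """Compute the named descriptors for one molecule.

    Raises ``ValueError`` for an unparseable SMILES and ``KeyError`` for an
    unknown descriptor name.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    unknown = [n for n in descriptor_set if n not in _REGISTRY]
    if unknown:
        raise KeyError(f"unknown descriptor name(s): {unknown}")
    return pd.Series(
        {name: float(_REGISTRY[name](mol)) for name in descriptor_set},
        dtype=float,
    )


def compute_matrix(
    smiles: Mapping[str, str],
    descriptor_set: list[str] | tuple[str, ...] = DEFAULT_DESCRIPTORS,
) -> "DescriptorMatrix":
    """Descriptor matrix for a mapping of row id -> SMILES."""
    rows = {rid: compute_descriptors(s, descriptor_set) for rid, s in smiles.items()}
    data = pd.DataFrame.from_dict(rows, orient="index")[list(descriptor_set)]
    return DescriptorMatrix(data=data)


@dataclass
class DescriptorMatrix:
    """Named descriptor values for a set of peptides or substructures.

    ``mu``/``sigma`` are populated once the matrix has been standardized and
    record the whole-peptide reference statistics that were applied.
    """

    data: pd.DataFrame
    mu: pd.Series | None = None
    sigma: pd.Series | None = None
    engine: str = ENGINE_NAME
    meta: dict = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def save_params(self, path: str | Path) -> None:
        """Write standardization parameters as a JSON sidecar."""
        if self.mu is None or self.sigma is None:
            raise ValueError("matrix has no standardization parameters")
        payload = {
            "engine": self.engine,
            "mu": self.mu.to_dict(),
            "sigma": self.sigma.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @staticmethod
    def load_params(path: str | Path) -> tuple[pd.Series, pd.Series]:
        payload = json.loads(Path(path).read_text())
        return pd.Series(payload["mu"]), pd.Series(payload["sigma"])


def standardize(
    matrix: DescriptorMatrix, reference: DescriptorMatrix
) -> DescriptorMatrix:
    """Z-score ``matrix`` column-wise with the reference's mean and population
    standard deviation.

    The reference is the whole-peptide matrix of the training split; the same
    statistics are applied verbatim to substructure matrices so whole-peptide
    and residue-level values live on one scale.
    """
    if list(matrix.data.columns) != list(reference.data.columns):
        raise ValueError("column mismatch between matrix and reference")
    if reference.mu is not None:
        mu, sigma = reference.mu, reference.sigma
    else:
        mu = reference.data.mean()
        sigma = reference.data.std(ddof=0)
    zero = sigma[sigma == 0]
    if len(zero):
        raise ValueError(
            f"zero-variance reference column(s): {list(zero.index)}; "
            "remove constant descriptors before standardizing"
        )
    z = (matrix.data - mu) / sigma
    return DescriptorMatrix(
        data=z, mu=mu.copy(), sigma=sigma.copy(), engine=matrix.engine
    )


_WEIGHTING = {
    "none": lambda rel: np.ones_like(rel),
    "linear": lambda rel: rel,
    "sqrt": np.sqrt,
}


def weight_by_frequency(
    matrix: DescriptorMatrix,
    counts: Mapping[str, int],
    strategy: str = "linear",
    key: Callable[[str], str] | None = None,
) -> DescriptorMatrix:
    """Scale each substructure row by a monotone function of its appearance
    frequency in the training data.

    The default strategy multiplies row ``s`` by ``count(s) / max_count``;
    substructures unseen in training fall back to count 1.
    """
    if strategy not in _WEIGHTING:
        raise ValueError(f"unknown weighting strategy {strategy!r}")
    if not counts:
        raise ValueError("empty count table")
    bad = {k: v for k, v in counts.items() if v <= 0}
    if bad:
        raise ValueError(f"non-positive substructure counts: {bad}")
    max_count = max(counts.values())
    keys = [key(rid) if key else rid for rid in matrix.data.index]
    rel = np.array([counts.get(k, 1) / max_count for k in keys], dtype=float)
    w = _WEIGHTING[strategy](rel)
    data = matrix.data.mul(w, axis=0)
    return DescriptorMatrix(
        data=data, mu=matrix.mu, sigma=matrix.sigma, engine=matrix.engine,
        meta={**matrix.meta, "weighting": strategy},
    )
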