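"""Synthetic cyclic peptides with lipophilicity-driven %PPB labels.

Real plasma-protein-binding panels for cyclic peptides are proprietary, so
every pipeline stage is exercised against generated data with a known,
controllable structure:

* head-to-tail amide-cyclized peptides of 5-15 proteinogenic residues (with
  an optional terminal-cysteine disulfide closure), residue counts peaking
  around 7-10;
* a label model %PPB = clamp(a + b * mean_s logP(s) + c * max_s logP(s) + e),
  e ~ Normal(0, sigma^2), where logP(s) is the Crippen logP of the capped
  substructure s.  Lipophilicity is the dominant physical driver of binding
  to serum albumin's hydrophobic pocket, and the max term plants a single
  "important residue" that attribution methods should find.

Labels are clamped to [50, 95]; the default coefficients put visible mass on
both clamp boundaries while keeping most labels interior.  Everything is
reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen

from .dataset import clamp_ppb
from .decompose import decompose, parse_peptide

__all__ = ["RESIDUES", "SyntheticSpec", "generate_peptide", "generate_dataset"]

#: one-letter code -> side-chain SMILES branch on the alpha carbon
RESIDUES: dict[str, str] = {
    "G": "",
    "A": "C",
    "S": "CO",
    "T": "C(C)O",
    "C": "CS",
    "V": "C(C)C",
    "L": "CC(C)C",
    "I": "C(C)CC",
    "M": "CCSC",
    "F": "Cc1ccccc1",
    "Y": "Cc1ccc(O)cc1",
    "W": "Cc1c[nH]c2ccccc12",
    "N": "CC(N)=O",
    "Q": "CCC(N)=O",
    "D": "CC(=O)O",
    "E": "CCC(=O)O",
    "K": "CCCCN",
    "R": "CCCNC(=N)N",
    "H": "Cc1c[nH]cn1",
}

#: residue-count probabilities over 5..15, peaked near 7-10
DEFAULT_LENGTH_WEIGHTS: dict[int, float] = {
    5: 0.05, 6: 0.10, 7: 0.17, 8: 0.18, 9: 0.15, 10: 0.12,
    11: 0.08, 12: 0.06, 13: 0.04, 14: 0.03, 15: 0.02,
}

DEFAULT_ALPHABET = tuple("GASTVLIMFYWNQEK")


def _unit(code: str, n_methyl: bool) -> str:
    side = RESIDUES[code]
    nn = "N(C)" if n_methyl else "N"
    if side == "":
        return f"{nn}CC(=O)"
    return f"{nn}C({side})C(=O)"


def generate_peptide(
    n_residues: int,
    alphabet=DEFAULT_ALPHABET,
    seed: int | np.random.Generator = 0,
    disulfide: bool = False,
    n_methyl_prob: float = 0.0,
) -> str:
    """One random cyclic-peptide SMILES of ``n_residues`` residues.

    Head-to-tail amide cyclization by default; with ``disulfide`` the chain
    is closed by a disulfide bridge between first and last residue (both
    forced to cysteine, free termini kept), giving n_residues - 1 backbone
    amides plus one S-S bond on the macrocycle.
    """
    if not 5 <= n_residues <= 15:
        raise ValueError("n_residues must be in 5..15")
    bad = [a for a in alphabet if a not in RESIDUES]
    if bad:
        raise ValueError(f"unknown residue code(s): {bad}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = [str(rng.choice(list(alphabet))) for _ in range(n_residues)]
    nme = [rng.random() < n_methyl_prob for _ in range(n_residues)]

    if disulfide:
        mids = "".join(_unit(c, m) for c, m in zip(codes[1:-1], nme[1:-1]))
        smiles = "NC(CS%99)C(=O)" + mids + "NC(CS%99)C(=O)O"
    else:
        units = [_unit(c, m) for c, m in zip(codes, nme)]
        first = units[0].replace("N", "N%99", 1) if not nme[0] else "N(C)%99" + units[0][4:]
        # ring closure: first unit's N binds the last unit's carbonyl carbon
        smiles = first + "".join(units[1:-1]) + units[-1][:-4] + "%99=O"
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - construction is valid by design
        raise RuntimeError(f"generated invalid SMILES: {smiles}")
    return Chem.MolToSmiles(mol)


@dataclass
class SyntheticSpec:
    """Generator settings; the defaults are the package's study conditions."""

    n_peptides: int = 300
    length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    disulfide_prob: float = 0.1
    n_methyl_prob: float = 0.0
    a: float = 60.0
    b: float = 24.0
    c: float = 16.0
    sigma: float = 3.0
    seed: int = 0


def generate_dataset(spec: SyntheticSpec) -> tuple[pd.DataFrame, dict]:
    """Generate (records, truth): a peptide table and the label-model truth.

    ``records`` has columns id, smiles, ppb (clamped to [50, 95]).  ``truth``
    carries the coefficients, the per-peptide noiseless signal and the index
    of the most lipophilic substructure (the planted important residue).
    """
    rng = np.random.default_rng(spec.seed)
    lengths = np.array(sorted(spec.length_weights))
    probs = np.array([spec.length_weights[int(k)] for k in lengths], dtype=float)
    probs /= probs.sum()

    rows = []
    details = {}
    for i in range(spec.n_peptides):
        pid = f"pep{i:04d}"
        n = int(rng.choice(lengths, p=probs))
        disulfide = bool(rng.random() < spec.disulfide_prob)
        smiles = generate_peptide(
            n, spec.alphabet, rng, disulfide=disulfide, n_methyl_prob=spec.n_methyl_prob
        )
        peptide = parse_peptide(pid, smiles)
        subs = decompose(peptide)
        logp = np.array(
            [Crippen.MolLogP(Chem.MolFromSmiles(s.capped_smiles)) for s in subs]
        )
        signal = spec.a + spec.b * float(logp.mean()) + spec.c * float(logp.max())
        y = clamp_ppb(float(np.clip(signal + rng.normal(0.0, spec.sigma), 0.0, 100.0)))
        rows.append({"id": pid, "smiles": smiles, "ppb": y})
        details[pid] = {
            "n_residues": len(subs),
            "signal": signal,
            "max_logp_position": int(np.argmax(logp)),
            "substructure_logp": [float(v) for v in logp],
        }
    records = pd.DataFrame(rows)
    truth = {
        "a": spec.a, "b": spec.b, "c": spec.c, "sigma": spec.sigma,
        "seed": spec.seed, "peptides": details,
    }
    return records, truth


def write_dataset(records: pd.DataFrame, truth: dict, out_csv, truth_json) -> None:
    records.to_csv(out_csv, index=False)
    Path(truth_json).write_text(json.dumps(truth, indent=2))
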