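import numpy as np
import pandas as pd
import pytest

from cyclicppb.decompose import parse_peptide
from cyclicppb.synthetic import SyntheticSpec, generate_dataset


def cyclo(side_chains: list[str]) -> str:
    """Head-to-tail cyclic peptide SMILES from side-chain fragments."""
    units = [f"NC({sc})C(=O)" if sc else "NCC(=O)" for sc in side_chains]
    first = units[0].replace("N", "N%99", 1)
    return first + "".join(units[1:-1]) + units[-1][:-4] + "%99=O"


CYCLO_ALA6 = cyclo(["C"] * 6)
#: Cys-Ala-Ala-Ala-Ala-Cys closed by a terminal-cysteine disulfide
DISULFIDE_HEX = "NC(CS%99)C(=O)" + "NC(C)C(=O)" * 4 + "NC(CS%99)C(=O)O"
#: cyclo(Ala5-Gln) — carries a side-chain amide that must not be cut
CYCLO_ALA5_GLN = cyclo(["C"] * 5 + ["CCC(N)=O"])
LINEAR_PEPTIDE = "NC(C)C(=O)" * 5 + "NC(C)C(=O)O"


@pytest.fixture(scope="session")
def ala6_peptide():
    return parse_peptide("ala6", CYCLO_ALA6)


@pytest.fixture(scope="session")
def small_dataset() -> tuple[pd.DataFrame, dict]:
    """40 default-condition synthetic peptides with label-model truth."""
    return generate_dataset(SyntheticSpec(n_peptides=40, seed=1234))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
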