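"""Residue-level decomposition of cyclic peptides.

A cyclic peptide is defined by a single macrocycle closed by backbone amide
bonds and/or one disulfide bridge.  The macrocycle is cut at every backbone
amide (the C(=O)-N bond) and at the disulfide S-S bond, and each cut end is
chemically completed so the fragment keeps the electronic character of the
intact chain:

* the amide nitrogen receives a methyl group (tertiary-amide-like cap),
* the carbonyl carbon becomes an aldehyde (implicit H),
* each disulfide sulfur becomes a free thiol.

Amide bonds that do not lie on the macrocycle (side-chain amides of Asn/Gln,
exocyclic termini) are never cut.  Fragments are reported in ring-adjacency
order, traversed N-to-C, starting from a canonical anchor: the fragment whose
capped canonical SMILES sorts first lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

__all__ = [
    "DecompositionError",
    "NotCyclicPeptideError",
    "TooFewResiduesError",
    "CappingError",
    "CleavableBond",
    "CyclicPeptide",
    "Substructure",
    "identify_cleavable_bonds",
    "parse_peptide",
    "decompose",
]

#: minimum macrocycle size (heavy atoms) for a ring to count as the macrocycle
MIN_MACROCYCLE_SIZE = 12
#: peptides with fewer than 5 residues (cleavable bonds) are rejected
MIN_RESIDUES = 5

_AMIDE = Chem.MolFromSmarts("[CX3](=[OX1])[NX3]")
_DISULFIDE = Chem.MolFromSmarts("[#16X2]-[#16X2]")


class DecompositionError(ValueError):
    """Base class for decomposition failures."""


class NotCyclicPeptideError(DecompositionError):
    """No macrocycle of sufficient size was found."""


class TooFewResiduesError(DecompositionError):
    """The macrocycle carries fewer than MIN_RESIDUES cleavable bonds."""


class CappingError(DecompositionError):
    """A fragment failed valence sanitization after capping."""


@dataclass(frozen=True)
class CleavableBond:
    """A macrocycle bond that decomposition will cut.

    For ``backbone_amide`` the atom pair is ordered (carbonyl C, amide N);
    for ``disulfide`` the two sulfurs in arbitrary (index) order.
    """

    atoms: tuple[int, int]
    kind: str  # "backbone_amide" | "disulfide"


@dataclass
class CyclicPeptide:
    """A parsed cyclic peptide with its identified macrocycle."""

    id: str
    smiles: str
    mol: Chem.Mol = field(repr=False)
    macrocycle_atoms: tuple[int, ...]
    cleavable_bonds: list[CleavableBond]

    @property
    def n_residues(self) -> int:
        return len(self.cleavable_bonds)


@dataclass(frozen=True)
class Substructure:
    """One capped residue-level fragment of a cyclic peptide."""

    position: int
    capped_smiles: str
    parent_atoms: tuple[int, ...]
    n_total: int


def _ring_bond_pairs(ring: tuple[int, ...]) -> set[frozenset[int]]:
    return {
        frozenset((ring[i], ring[(i + 1) % len(ring)])) for i in range(len(ring))
    }


def _amide_bonds_on_ring(mol: Chem.Mol, ring: tuple[int, ...]) -> list[tuple[int, int]]:
    pairs = _ring_bond_pairs(ring)
    out = []
    for c, _o, n in mol.GetSubstructMatches(_AMIDE):
        if frozenset((c, n)) in pairs:
            out.append((c, n))
    return out


def _select_macrocycle(mol: Chem.Mol) -> tuple[int, ...]:
    """Largest SSSR ring of >= MIN_MACROCYCLE_SIZE atoms holding >= 2 backbone
    amide bonds; ties broken by amide-bond count, then by first appearance."""
    best = None
    best_key = None
    for ring in Chem.GetSymmSSSR(mol):
        ring = tuple(ring)
        if len(ring) < MIN_MACROCYCLE_SIZE:
            continue
        n_amide = len(_amide_bonds_on_ring(mol, ring))
        if n_amide < 2:
            continue
        key = (len(ring), n_amide)
        if best is None or key > best_key:
            best, best_key = ring, key
    if best is None:
        raise NotCyclicPeptideError("not a cyclic peptide: no macrocycle found")
    return best


def identify_cleavable_bonds(mol: Chem.Mol) -> list[CleavableBond]:
    """Return every backbone amide C(=O)-N bond and every S-S bond lying on
    the peptide's macrocycle.

    Raises
    ------
    NotCyclicPeptideError
        If no ring of at least MIN_MACROCYCLE_SIZE heavy atoms with two or
        more backbone amide bonds exists.
    TooFewResiduesError
        If fewer than MIN_RESIDUES cleavable bonds lie on the macrocycle.
    """
    ring = _select_macrocycle(mol)
    pairs = _ring_bond_pairs(ring)
    bonds = [
        CleavableBond(atoms=(c, n), kind="backbone_amide")
        for c, n in _amide_bonds_on_ring(mol, ring)
    ]
    seen: set[frozenset[int]] = set()
    for s1, s2 in mol.GetSubstructMatches(_DISULFIDE):
        key = frozenset((s1, s2))
        if key in pairs and key not in seen:
            seen.add(key)
            bonds.append(CleavableBond(atoms=(min(s1, s2), max(s1, s2)), kind="disulfide"))
    if len(bonds) < MIN_RESIDUES:
        raise TooFewResiduesError(
            f"too few residues: {len(bonds)} cleavable bonds on the macrocycle "
            f"(minimum {MIN_RESIDUES})"
        )
    return bonds


def parse_peptide(peptide_id: str, smiles: str) -> CyclicPeptide:
    """Parse a SMILES string into a :class:`CyclicPeptide`."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DecompositionError(f"unparseable SMILES for {peptide_id!r}: {smiles!r}")
    bonds = identify_cleavable_bonds(mol)
    ring = _select_macrocycle(mol)
    return CyclicPeptide(
        id=peptide_id,
        smiles=Chem.MolToSmiles(mol),
        mol=mol,
        macrocycle_atoms=ring,
        cleavable_bonds=bonds,
    )


def _cleave_and_cap(mol: Chem.Mol, bonds: list[CleavableBond]) -> Chem.Mol:
    rw = Chem.RWMol(mol)
    for bond in bonds:
        a, b = bond.atoms
        rw.RemoveBond(a, b)
        if bond.kind == "backbone_amide":
            # a = carbonyl C -> aldehyde via implicit H; b = N -> add methyl
            methyl = rw.AddAtom(Chem.Atom(6))
            rw.AddBond(b, methyl, Chem.BondType.SINGLE)
        # disulfide: both sulfurs pick up an implicit H (free thiols)
    capped = rw.GetMol()
    try:
        Chem.SanitizeMol(capped)
    except Exception as exc:  # pragma: no cover - valence failures are exotic
        raise CappingError(f"capping failure: {exc}") from exc
    return capped


def decompose(peptide: CyclicPeptide) -> list[Substructure]:
    """Cut all cleavable bonds simultaneously, cap the ends and return the
    fragments in ring-adjacency order (N-to-C, canonical anchor first).

    The parent heavy atoms of the returned substructures partition the
    peptide's heavy atoms; cap atoms added during the cut are excluded from
    ``parent_atoms``.
    """
    mol = peptide.mol
    n_parent = mol.GetNumAtoms()
    capped = _cleave_and_cap(mol, peptide.cleavable_bonds)

    frag_indices = Chem.GetMolFrags(capped)
    frag_mols = Chem.GetMolFrags(capped, asMols=True, sanitizeFrags=True)
    if len(frag_indices) != len(peptide.cleavable_bonds):
        raise DecompositionError(
            f"{peptide.id}: expected {len(peptide.cleavable_bonds)} fragments, "
            f"got {len(frag_indices)} (macrocycle mis-identified?)"
        )

    atom_to_frag: dict[int, int] = {}
    parent_atoms: list[tuple[int, ...]] = []
    smiles_list: list[str] = []
    for fi, (idx_tuple, fmol) in enumerate(zip(frag_indices, frag_mols)):
        parents = tuple(sorted(i for i in idx_tuple if i < n_parent))
        parent_atoms.append(parents)
        for i in parents:
            atom_to_frag[i] = fi
        smiles_list.append(Chem.MolToSmiles(fmol))

    order = _ring_order(peptide, atom_to_frag)
    # canonical anchor: lexicographically smallest capped SMILES; ties broken
    # by the smallest parent atom index so the start is always well defined
    anchor_pos = min(
        range(len(order)),
        key=lambda p: (smiles_list[order[p]], parent_atoms[order[p]][0]),
    )
    ordered = order[anchor_pos:] + order[:anchor_pos]

    n = len(ordered)
    return [
        Substructure(
            position=pos,
            capped_smiles=smiles_list[fi],
            parent_atoms=parent_atoms[fi],
            n_total=n,
        )
        for pos, fi in enumerate(ordered)
    ]


def _ring_order(peptide: CyclicPeptide, atom_to_frag: dict[int, int]) -> list[int]:
    """Fragment indices in macrocycle traversal order, oriented N-to-C.

    Crossing a cut amide bond from the carbonyl carbon to the nitrogen is the
    N-to-C direction; the ring tuple is flipped if it disagrees."""
    ring = list(peptide.macrocycle_atoms)
    amides = [b.atoms for b in peptide.cleavable_bonds if b.kind == "backbone_amide"]
    pos = {a: i for i, a in enumerate(ring)}
    fwd = 0
    for c, n in amides:
        if pos[n] == (pos[c] + 1) % len(ring):
            fwd += 1
    if fwd < len(amides) - fwd:
        ring = ring[::-1]

    seq: list[int] = []
    for a in ring:
        fi = atom_to_frag[a]
        if not seq or seq[-1] != fi:
            seq.append(fi)
    if seq and seq[0] == seq[-1] and len(seq) > 1:
        seq.pop()
    if sorted(seq) != sorted(set(atom_to_frag.values())):
        raise DecompositionError(
            f"{peptide.id}: fragments are not contiguous arcs of the macrocycle"
        )
    return seq
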