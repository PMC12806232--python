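"""Molecular graphs and the SMILES boundary.

A drug molecule is an undirected graph whose nodes are heavy atoms and whose
edges are bonds.  RDKit does all SMILES parsing/writing; the rest of the
package only ever sees :class:`MolecularGraph`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: element vocabulary for the learnable atom-type embedding table; anything
#: outside it maps to the trailing "other" slot
ATOM_VOCAB: tuple[str, ...] = (
    "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Si", "other",
)

BOND_TYPES: tuple[str, ...] = ("single", "double", "triple", "aromatic")


def atom_type_index(symbol: str) -> int:
    try:
        return ATOM_VOCAB.index(symbol)
    except ValueError:
        return len(ATOM_VOCAB) - 1


@dataclass
class MolecularGraph:
    """Undirected heavy-atom graph of one drug molecule.

    Parameters
    ----------
    atom_symbols : list of str
        Element symbol per node, in a stable atom ordering.
    edges : list of (int, int)
        Undirected bonds; each pair stored once.
    bond_types : list of str, optional
        Parallel to ``edges``; one of :data:`BOND_TYPES`.
    """

    atom_symbols: list
    edges: list
    bond_types: list = field(default=None)

    def __post_init__(self):
        n = self.n_atoms
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on atom {u}")
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u},{v}) out of range for {n} atoms")
        if self.bond_types is not None and len(self.bond_types) != len(self.edges):
            raise ValueError("bond_types must parallel edges")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_symbols)

    @property
    def atom_type_indices(self) -> list:
        return [atom_type_index(s) for s in self.atom_symbols]

    def neighbors(self, v: int) -> list:
        out = []
        for u, w in self.edges:
            if u == v:
                out.append(w)
            elif w == v:
                out.append(u)
        return out


_RD_BOND = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


def graph_from_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Raises ``ValueError`` on unparsable input (the caller reports which drug).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    edges, btypes = [], []
    for b in mol.GetBonds():
        edges.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        btypes.append(_RD_BOND.get(b.GetBondType(), "single"))
    return MolecularGraph(symbols, edges, btypes)


def smiles_from_graph(graph: MolecularGraph) -> str:
    """Write a single-bond molecular graph back out as canonical SMILES."""
    mol = Chem.RWMol()
    for sym in graph.atom_symbols:
        mol.AddAtom(Chem.Atom(sym))
    for k, (u, v) in enumerate(graph.edges):
        bt = graph.bond_types[k] if graph.bond_types else "single"
        rd = {v: k for k, v in _RD_BOND.items()}[bt]
        mol.AddBond(u, v, rd)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)
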