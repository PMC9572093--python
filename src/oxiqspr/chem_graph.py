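"""Hydrogen-explicit molecular graphs with ring-membership flags.

Structures are read with RDKit (SMILES or SDF/V2000), hydrogens are made
explicit, aromatic systems are kekulized, and the result is exposed as a
plain atom/bond graph.  Bond orders are retained only so that a graph can be
serialized back to a molblock; the descriptor machinery downstream treats
every bond as a bare adjacency.

Ring membership is perceived on the graph itself: an atom is cyclic exactly
when it lies on at least one simple cycle (equivalently, when it belongs to
a basis cycle of the bond graph).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import networkx as nx
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # rdkit parse chatter; errors are re-raised with context

_BOND_TYPES = {
    1.0: Chem.BondType.SINGLE,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
}


@dataclass(frozen=True)
class Atom:
    """One atom: index, element symbol, formal charge, cyclicity flag."""

    index: int
    element: str
    formal_charge: int = 0
    in_ring: bool = False

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"atom index must be >= 0, got {self.index}")
        if not self.element or not self.element[0].isalpha():
            raise ValueError(f"invalid element symbol {self.element!r}")


@dataclass
class MolecularGraph:
    """Hydrogen-explicit molecular graph.

    ``bonds`` is a set of unordered index pairs stored as sorted tuples.
    ``bond_orders`` maps each pair to its order (1/2/3); it is carried only
    for serialization and never consulted by descriptor code.
    """

    atoms: list[Atom]
    bonds: frozenset[tuple[int, int]]
    bond_orders: dict[tuple[int, int], float] = field(default_factory=dict)
    id: Optional[str] = None
    activity: Optional[float] = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen = {a.index for a in self.atoms}
        if len(seen) != n:
            raise ValueError("duplicate atom indices")
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if i not in seen or j not in seen:
                raise ValueError(f"bond ({i}, {j}) references unknown atom")

    # -- convenience ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom(self, index: int) -> Atom:
        return self._atom_map()[index]

    def _atom_map(self) -> dict[int, Atom]:
        return {a.index: a for a in self.atoms}

    def neighbors(self, index: int) -> list[int]:
        out = []
        for i, j in self.bonds:
            if i == index:
                out.append(j)
            elif j == index:
                out.append(i)
        return sorted(out)

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {a.index: [] for a in self.atoms}
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def heavy_indices(self) -> list[int]:
        return [a.index for a in self.atoms if a.element != "H"]

    def to_networkx(self, heavy_only: bool = False) -> nx.Graph:
        g = nx.Graph()
        keep = set(self.heavy_indices()) if heavy_only else {a.index for a in self.atoms}
        for a in self.atoms:
            if a.index in keep:
                g.add_node(a.index, element=a.element)
        for i, j in self.bonds:
            if i in keep and j in keep:
                g.add_edge(i, j)
        return g

    # -- serialization ----------------------------------------------------

    def to_rdkit(self) -> Chem.Mol:
        rw = Chem.RWMol()
        order = sorted(self.atoms, key=lambda a: a.index)
        remap = {}
        for a in order:
            at = Chem.Atom(a.element)
            at.SetFormalCharge(a.formal_charge)
            at.SetNoImplicit(True)
            remap[a.index] = rw.AddAtom(at)
        for i, j in sorted(self.bonds):
            bt = _BOND_TYPES.get(self.bond_orders.get((i, j), 1.0), Chem.BondType.SINGLE)
            rw.AddBond(remap[i], remap[j], bt)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        return mol

    def to_molblock(self) -> str:
        mol = self.to_rdkit()
        if self.id:
            mol.SetProp("_Name", self.id)
        return Chem.MolToMolBlock(mol)

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self.to_rdkit())


def perceive_rings(g: MolecularGraph) -> MolecularGraph:
    """Return a copy of ``g`` with ``in_ring`` true exactly for atoms on a simple cycle."""
    cyclic: set[int] = set()
    for cycle in nx.cycle_basis(g.to_networkx()):
        cyclic.update(cycle)
    atoms = [replace(a, in_ring=(a.index in cyclic)) for a in g.atoms]
    return replace(g, atoms=atoms)


def _graph_from_rdkit(mol: Chem.Mol, mol_id: str, activity: Optional[float]) -> MolecularGraph:
    mol = Chem.AddHs(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    atoms = [
        Atom(a.GetIdx(), a.GetSymbol(), a.GetFormalCharge(), False)
        for a in mol.GetAtoms()
    ]
    bonds = set()
    orders = {}
    for b in mol.GetBonds():
        i, j = sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        bonds.add((i, j))
        orders[(i, j)] = b.GetBondTypeAsDouble()
    g = MolecularGraph(atoms, frozenset(bonds), orders, id=mol_id, activity=activity)
    return perceive_rings(g)


def parse_structures(source: str, format: str = "smiles") -> list[MolecularGraph]:
    """Parse a SMILES flat file or SDF text into molecular graphs.

    SMILES format is one record per line: ``structure [id [activity]]``
    (whitespace-separated).  Record order is preserved; ids default to
    ``mol<k>``.  Unparsable records raise ``ValueError`` naming the
    offending line or record.
    """
    if format not in ("smiles", "sdf"):
        raise ValueError(f"unknown format {format!r}")
    graphs: list[MolecularGraph] = []
    if format == "smiles":
        for lineno, raw in enumerate(source.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{len(graphs) + 1}"
            activity = float(parts[2]) if len(parts) > 2 else None
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                raise ValueError(f"unparsable SMILES on line {lineno}: {smiles!r}")
            graphs.append(_graph_from_rdkit(mol, mol_id, activity))
    else:
        text = source if source.rstrip().endswith("$$$$") else source.rstrip("\n") + "\n$$$$\n"
        supplier = Chem.ForwardSDMolSupplier(io.BytesIO(text.encode()), removeHs=False)
        for k, mol in enumerate(supplier, start=1):
            if mol is None:
                raise ValueError(f"unparsable SDF record {k}")
            name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{k}"
            graphs.append(_graph_from_rdkit(mol, name, None))
    if not graphs:
        raise ValueError("no structures found in input")
    return graphs
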