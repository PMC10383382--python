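"""Hydrogen-depleted molecular graphs for 2D descriptor calculation.

All topological descriptors in this package operate on the heavy-atom
(hydrogen-depleted) graph, following the Dragon/alvaDesc convention for
2D indices.  Hydrogen counts are retained per atom so that whole-molecule
quantities (McGowan volume, drug-likeness properties) can include them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
from rdkit import Chem

_PT = Chem.GetPeriodicTable()

#: Bondi-style van der Waals volumes, (4/3)*pi*r^3 from the element radius.
def _vdw_volume(symbol: str) -> float:
    import math

    r = _PT.GetRvdw(_PT.GetAtomicNumber(symbol))
    return 4.0 / 3.0 * math.pi * r**3


@dataclass
class Atom:
    element: str
    mass: float
    vdw_volume: float
    degree: int
    n_hydrogens: int = 0


@dataclass
class MolecularGraph:
    """Undirected simple labeled graph of the heavy atoms of one molecule.

    ``bonds`` hold ``(i, j, order)`` with aromatic order 1.5.  ``degree``
    of each atom equals its incident heavy-bond count (validated on
    construction).
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    hydrogen_depleted: bool = True
    rdkit_mol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        counts = [0] * n
        seen = set()
        for i, j, _order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i},{j}) for {n} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            counts[i] += 1
            counts[j] += 1
        for idx, atom in enumerate(self.atoms):
            if atom.degree != counts[idx]:
                raise ValueError(
                    f"atom {idx}: declared degree {atom.degree} != incident bonds {counts[idx]}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def degrees(self) -> list[int]:
        return [a.degree for a in self.atoms]

    def weights(self, kind: str, scale_to_carbon: bool = True) -> list[float]:
        """Per-atom weights for autocorrelation descriptors.

        ``kind`` is ``'mass'`` or ``'vdw_volume'``; by default values are
        divided by the carbon value (Dragon convention) so carbon has
        weight 1.
        """
        if kind == "mass":
            vals = [a.mass for a in self.atoms]
            ref = _PT.GetAtomicWeight(6)
        elif kind == "vdw_volume":
            vals = [a.vdw_volume for a in self.atoms]
            ref = _vdw_volume("C")
        else:
            raise ValueError(f"unknown weight kind {kind!r}")
        return [v / ref for v in vals] if scale_to_carbon else vals

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_weighted_edges_from(self.bonds, weight="order")
        return g

    def is_connected(self) -> bool:
        if self.n_atoms == 0:
            return True
        return nx.is_connected(self.to_networkx())

    @classmethod
    def from_adjacency(cls, edges: Sequence[tuple[int, int]], n: int,
                       masses: Optional[Sequence[float]] = None) -> "MolecularGraph":
        """Build an abstract (element-free) graph, mainly for testing.

        All atoms are carbon unless ``masses`` overrides the mass labels.
        """
        deg = [0] * n
        for i, j in edges:
            deg[i] += 1
            deg[j] += 1
        c_mass = _PT.GetAtomicWeight(6)
        c_vol = _vdw_volume("C")
        atoms = [
            Atom("C", masses[k] if masses is not None else c_mass, c_vol, deg[k])
            for k in range(n)
        ]
        return cls(atoms, [(i, j, 1.0) for i, j in edges])


def build_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-depleted :class:`MolecularGraph`.

    Raises ``ValueError`` naming the input when RDKit cannot parse it.
    Aromatic bonds carry order 1.5.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    atoms = []
    for a in mol.GetAtoms():
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                mass=_PT.GetAtomicWeight(a.GetAtomicNum()),
                vdw_volume=_vdw_volume(a.GetSymbol()),
                degree=a.GetDegree(),
                n_hydrogens=a.GetTotalNumHs(),
            )
        )
    bonds = []
    for b in mol.GetBonds():
        order = 1.5 if b.GetIsAromatic() else b.GetBondTypeAsDouble()
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return MolecularGraph(atoms, bonds, rdkit_mol=mol)
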