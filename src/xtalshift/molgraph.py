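"""Molecular graph parsing and the spectroscopic site model.

A molecule is reduced to *sites*, the resonance units actually observed in
the spectra: one site per carbon, and one site per proton except that the
protons of a fast-rotating group (CH3, NH2, NH3+) are magnetically
equivalent and collapse to a single site.  All assignment constraints are
expressed through the minimum covalent bond distance between sites, so the
only structural input the pipeline needs is two-dimensional connectivity;
no coordinates are consumed anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Atom",
    "MolecularGraph",
    "Site",
    "BondDistanceMatrix",
    "parse_structure",
    "build_sites",
    "bond_distance_matrix",
]

#: rotor groups whose protons are treated as a single equivalent site,
#: keyed by heavy element and number of attached hydrogens
_ROTOR_GROUPS = {("C", 3), ("N", 2), ("N", 3)}


@dataclass(frozen=True)
class Atom:
    atom_id: int
    element: str
    heavy_neighbor_ids: tuple[int, ...]


@dataclass
class MolecularGraph:
    """Connected molecular graph with explicit hydrogens.

    ``canonical_order`` maps atom_id to a canonical rank used for
    deterministic, input-order-independent site labelling.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    canonical_order: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [a.atom_id for a in self.atoms]
        if len(ids) != len(set(ids)):
            raise ValueError("atom_ids must be unique")
        g = self.to_networkx()
        if len(self.atoms) and not nx.is_connected(g):
            n = nx.number_connected_components(g)
            raise ValueError(f"{n} disconnected components")
        for atom in self.atoms:
            if atom.element == "H":
                heavy = [b for b in g[atom.atom_id]
                         if self.atom(b).element != "H"]
                if len(list(g[atom.atom_id])) != 1 or len(heavy) != 1:
                    raise ValueError(
                        f"H atom {atom.atom_id} must bond exactly one heavy atom"
                    )
        if not self.canonical_order:
            self.canonical_order = _morgan_ranks(self)
        self._by_id = {a.atom_id: a for a in self.atoms}

    def atom(self, atom_id: int) -> Atom:
        try:
            return self._by_id[atom_id]
        except AttributeError:
            self._by_id = {a.atom_id: a for a in self.atoms}
            return self._by_id[atom_id]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.atom_id, element=a.element)
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g

    def hydrogens_on(self, heavy_id: int) -> list[int]:
        g = self.to_networkx()
        return sorted(
            n for n in g[heavy_id] if self.atom(n).element == "H"
        )


def _morgan_ranks(graph: MolecularGraph) -> dict[int, int]:
    """Order-independent atom ranking by iterative neighbourhood hashing.

    Automorphic atoms receive tied hashes; ties are broken by hash value
    so any two input orderings of the same molecule produce isomorphic
    labellings.
    """
    g = nx.Graph()
    for a in graph.atoms:
        g.add_node(a.atom_id)
    for i, j, _ in graph.bonds:
        g.add_edge(i, j)
    inv = {a.atom_id: hash((a.element, g.degree(a.atom_id))) for a in graph.atoms}
    for _ in range(len(graph.atoms)):
        inv = {
            i: hash((inv[i], tuple(sorted(inv[j] for j in g[i]))))
            for i in inv
        }
    order = sorted(graph.atoms, key=lambda a: (a.element == "H", inv[a.atom_id], a.atom_id))
    return {a.atom_id: rank for rank, a in enumerate(order)}


def parse_structure(structure_text: str) -> MolecularGraph:
    """Parse a SMILES string or a MOL/SDF V2000 block into a molecular graph.

    Hydrogens are made explicit.  The input must describe a single connected
    molecule; fragment inputs (e.g. salts written with a dot) are rejected
    with the fragment count in the message.
    """
    from rdkit import Chem

    text = structure_text.strip()
    if "V2000" in text or "\n" in text:
        mol = Chem.MolFromMolBlock(text, removeHs=False)
    else:
        mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ValueError(f"could not parse structure: {text[:60]!r}")
    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        raise ValueError(f"{len(frags)} disconnected components")
    mol = Chem.AddHs(mol)
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))

    atoms = []
    for a in mol.GetAtoms():
        heavy = tuple(sorted(
            n.GetIdx() for n in a.GetNeighbors() if n.GetSymbol() != "H"
        ))
        atoms.append(Atom(a.GetIdx(), a.GetSymbol(), heavy))
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in mol.GetBonds()
    ]
    # heavy atoms before hydrogens in the canonical order
    heavy_first = sorted(
        atoms,
        key=lambda a: (a.element == "H", ranks[a.atom_id]),
    )
    order = {a.atom_id: i for i, a in enumerate(heavy_first)}
    return MolecularGraph(atoms=atoms, bonds=bonds, canonical_order=order)


@dataclass(frozen=True)
class Site:
    """One expected resonance: a carbon, or an equivalence group of protons."""

    label: str
    nucleus: str  # "H1" or "C13"
    member_atom_ids: frozenset[int]
    attached_carbon_label: str | None = None
    is_quaternary: bool = False
    is_heteroatom_bound: bool = False

    def __post_init__(self) -> None:
        if self.nucleus not in ("H1", "C13"):
            raise ValueError(f"unknown nucleus {self.nucleus!r}")


def build_sites(
    graph: MolecularGraph,
    label_map: dict[int, str] | None = None,
) -> list[Site]:
    """Derive the site list from a molecular graph.

    One C13 site per carbon.  Protons on the same rotor group (CH3, NH2,
    NH3+) collapse to one H1 site; every other proton, including aromatic
    and exchangeable O-H/N-H protons, is an individual site.  ``label_map``
    assigns user labels to heavy atoms (e.g. to reproduce a published
    numbering); hydrogen site labels are derived from the label of the
    attached heavy atom (C9 -> H9, O24 -> H24), with letter suffixes when
    several inequivalent protons share one heavy atom.
    """
    heavy = [a for a in graph.atoms if a.element != "H"]
    heavy_sorted = sorted(heavy, key=lambda a: graph.canonical_order.get(a.atom_id, a.atom_id))
    if label_map is None:
        labels = {
            a.atom_id: f"{a.element}{i + 1}" for i, a in enumerate(heavy_sorted)
        }
    else:
        missing = [a.atom_id for a in heavy if a.atom_id not in label_map]
        if missing:
            raise ValueError(f"label map missing heavy atoms {missing}")
        labels = dict(label_map)

    sites: list[Site] = []
    for a in heavy_sorted:
        if a.element != "C":
            continue
        h_ids = graph.hydrogens_on(a.atom_id)
        sites.append(Site(
            label=labels[a.atom_id],
            nucleus="C13",
            member_atom_ids=frozenset({a.atom_id}),
            is_quaternary=not h_ids,
        ))
    for a in heavy_sorted:
        h_ids = graph.hydrogens_on(a.atom_id)
        if not h_ids:
            continue
        base = "H" + "".join(c for c in labels[a.atom_id] if c.isdigit())
        hetero = a.element not in ("C",)
        attached = labels[a.atom_id] if a.element == "C" else None
        if (a.element, len(h_ids)) in _ROTOR_GROUPS:
            groups = [h_ids]
        else:
            groups = [[h] for h in h_ids]
        for k, grp in enumerate(groups):
            suffix = "" if len(groups) == 1 else "abc"[k]
            sites.append(Site(
                label=base + suffix,
                nucleus="H1",
                member_atom_ids=frozenset(grp),
                attached_carbon_label=attached,
                is_heteroatom_bound=hetero,
            ))
    seen: set[str] = set()
    for s in sites:
        if s.label in seen:
            raise ValueError(f"duplicate site label {s.label!r}")
        seen.add(s.label)
    return sites


@dataclass
class BondDistanceMatrix:
    """Minimum covalent bond counts between site pairs.

    The distance between two sites is the minimum over their member atoms
    of the shortest bond path; a site to itself is 0.
    """

    labels: list[str]
    matrix: np.ndarray

    def __getitem__(self, pair: tuple[str, str]) -> int:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return int(self.matrix[i, j])

    def distance(self, a: str, b: str) -> int:
        return self[a, b]


def bond_distance_matrix(
    sites: list[Site], graph: MolecularGraph
) -> BondDistanceMatrix:
    g = graph.to_networkx()
    splen = dict(nx.all_pairs_shortest_path_length(g))
    labels = [s.label for s in sites]
    n = len(sites)
    mat = np.zeros((n, n), dtype=int)
    for i, si in enumerate(sites):
        for j in range(i + 1, n):
            sj = sites[j]
            d = min(
                splen[a][b] for a in si.member_atom_ids for b in sj.member_atom_ids
            )
            mat[i, j] = mat[j, i] = d
    return BondDistanceMatrix(labels=labels, matrix=mat)
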