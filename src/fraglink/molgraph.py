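"""Molecular-graph data model, atom-type registry, valency rules and I/O.

Molecules are heavy-atom graphs: nodes carry a type from a restricted
registry of (element, formal charge, maximum valence) triples, edges carry
an integer bond order in {1, 2, 3}, and hydrogens are implied by the
valence slack.  Aromatic input is accepted but stored kekulized, because
the decoder's bond-label alphabet is single/double/triple only.
Stereochemistry is ignored throughout.

Anchors — the atoms where a generated linker attaches — are marked with
dummy atoms (``[*]``) in line notation and become ``anchor`` indices here.

RDKit handles parsing, canonicalization and SDF; this module owns the
in-memory representation the rest of the package computes on.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


class ParseError(ValueError):
    """Unparsable line notation."""


class UnsupportedAtomError(ValueError):
    """Atom outside the permitted type registry."""


class ValidityError(ValueError):
    """Graph violates its structural invariants."""


@dataclass(frozen=True)
class AtomType:
    symbol: str
    charge: int
    max_valence: int

    def __post_init__(self):
        if not (0 < self.max_valence <= 6):
            raise ValueError(f"max valence must be in 1..6, got {self.max_valence}")


class AtomTypeRegistry:
    """Permitted atom types for generation.

    The default mirrors a drug-like organic subset: 14 entries covering
    C, N, N+, O, O-, F, S (three valence states), Cl, Br, I and P (two
    valence states).  Multi-valence elements get one entry per valence
    state; an atom resolves to the smallest state that accommodates its
    explicit bonds.
    """

    def __init__(self, entries: list[AtomType]):
        if not entries:
            raise ValueError("registry must not be empty")
        self.entries = list(entries)

    @property
    def size(self) -> int:
        return len(self.entries)

    @classmethod
    def default(cls) -> "AtomTypeRegistry":
        spec = [
            ("C", 0, 4), ("N", 0, 3), ("N", 1, 4), ("O", 0, 2), ("O", -1, 1),
            ("F", 0, 1), ("S", 0, 2), ("S", 0, 4), ("S", 0, 6),
            ("Cl", 0, 1), ("Br", 0, 1), ("I", 0, 1), ("P", 0, 3), ("P", 0, 5),
        ]
        return cls([AtomType(*e) for e in spec])

    def resolve(self, symbol: str, charge: int, valence: int) -> int:
        """Index of the smallest type accommodating `valence` explicit bonds."""
        best, best_val = None, None
        for i, t in enumerate(self.entries):
            if t.symbol == symbol and t.charge == charge and t.max_valence >= valence:
                if best_val is None or t.max_valence < best_val:
                    best, best_val = i, t.max_valence
        if best is None:
            raise UnsupportedAtomError(
                f"atom {symbol}{charge:+d} with valence {valence} not in registry"
            )
        return best

    def __getitem__(self, i: int) -> AtomType:
        return self.entries[i]


DEFAULT_REGISTRY = AtomTypeRegistry.default()


@dataclass
class Conformer:
    """N x 3 coordinates in Angstrom, aligned to heavy-atom indices."""

    positions: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")

    def __len__(self) -> int:
        return len(self.positions)


class MolecularGraph:
    """Heavy-atom molecular graph with typed atoms and integer bond orders.

    atoms    : list of registry type indices
    bonds    : dict mapping frozenset({i, j}) -> order in {1, 2, 3}
    anchors  : set of atom indices marked as linker attachment points
    positions: optional (N, 3) coordinates in Angstrom
    """

    def __init__(self, registry: AtomTypeRegistry | None = None):
        self.registry = registry or DEFAULT_REGISTRY
        self.atoms: list[int] = []
        self.bonds: dict[frozenset, int] = {}
        self.anchors: set[int] = set()
        self.positions: np.ndarray | None = None

    # -- construction -------------------------------------------------
    def add_atom(self, type_index: int) -> int:
        type_index = int(type_index)
        if not (0 <= type_index < self.registry.size):
            raise ValueError(f"atom type index {type_index} out of range")
        self.atoms.append(type_index)
        return len(self.atoms) - 1

    def add_bond(self, i: int, j: int, order: int):
        i, j, order = int(i), int(j), int(order)
        if i == j:
            raise ValidityError("self-loops are not allowed")
        for k in (i, j):
            if not (0 <= k < len(self.atoms)):
                raise ValidityError(f"bond references missing atom {k}")
        if order not in (1, 2, 3):
            raise ValidityError(f"bond order must be 1, 2 or 3, got {order}")
        key = frozenset((i, j))
        if key in self.bonds:
            raise ValidityError(f"duplicate bond {i}-{j}")
        self.bonds[key] = order

    def copy(self) -> "MolecularGraph":
        g = MolecularGraph(self.registry)
        g.atoms = list(self.atoms)
        g.bonds = dict(self.bonds)
        g.anchors = set(self.anchors)
        g.positions = None if self.positions is None else self.positions.copy()
        return g

    # -- queries ------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def bond_list(self) -> list[tuple[int, int, int]]:
        out = []
        for key, order in self.bonds.items():
            i, j = sorted(key)
            out.append((i, j, order))
        return sorted(out)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for key in self.bonds:
            if i in key:
                (j,) = key - {i}
                out.append(j)
        return sorted(out)

    def valence(self, i: int) -> int:
        return sum(o for key, o in self.bonds.items() if i in key)

    def free_valence(self, i: int) -> int:
        return self.registry[self.atoms[i]].max_valence - self.valence(i)

    def atom_symbol(self, i: int) -> str:
        return self.registry[self.atoms[i]].symbol

    def has_bond(self, i: int, j: int) -> bool:
        return frozenset((i, j)) in self.bonds

    def conformer(self) -> Conformer:
        if self.positions is None:
            raise ValidityError("graph has no coordinates")
        return Conformer(self.positions)

    def validate(self):
        """Raise ValidityError on any structural-invariant violation."""
        for (key, order) in self.bonds.items():
            if len(key) != 2:
                raise ValidityError("self-loop bond")
            for k in key:
                if not (0 <= k < self.n_atoms):
                    raise ValidityError(f"bond references missing atom {k}")
        bad = check_valence(self)
        if bad:
            raise ValidityError(f"valence exceeded at atoms {bad}")
        for a in self.anchors:
            if not (0 <= a < self.n_atoms):
                raise ValidityError(f"anchor mark on missing atom {a}")

    # -- conversions --------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, t in enumerate(self.atoms):
            at = self.registry[t]
            g.add_node(i, symbol=at.symbol, charge=at.charge)
        for i, j, order in self.bond_list():
            g.add_edge(i, j, order=order)
        return g

    def subgraph(self, keep: list[int]) -> tuple["MolecularGraph", dict]:
        """Induced subgraph on `keep` (original order); returns (graph, old->new map)."""
        keep = sorted(keep)
        remap = {old: new for new, old in enumerate(keep)}
        g = MolecularGraph(self.registry)
        for old in keep:
            g.add_atom(self.atoms[old])
        for i, j, order in self.bond_list():
            if i in remap and j in remap:
                g.add_bond(remap[i], remap[j], order)
        g.anchors = {remap[a] for a in self.anchors if a in remap}
        if self.positions is not None:
            g.positions = self.positions[keep].copy()
        return g, remap

    def to_rdkit(self, anchor_dummies: bool = False) -> Chem.Mol:
        mol = Chem.RWMol()
        for t in self.atoms:
            at = self.registry[t]
            a = Chem.Atom(at.symbol)
            a.SetFormalCharge(at.charge)
            mol.AddAtom(a)
        order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
        for i, j, order in self.bond_list():
            mol.AddBond(i, j, order_map[order])
        if anchor_dummies:
            for a in sorted(self.anchors):
                d = mol.AddAtom(Chem.Atom(0))
                mol.AddBond(a, d, Chem.BondType.SINGLE)
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        return m


# ---------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------

def from_rdkit(mol: Chem.Mol, registry: AtomTypeRegistry | None = None) -> MolecularGraph:
    """Convert an RDKit Mol (kekulized, dummies -> anchors) to a MolecularGraph."""
    registry = registry or DEFAULT_REGISTRY
    mol = Chem.Mol(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)

    dummy_ids = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    anchors_old: set[int] = set()
    for d in dummy_ids:
        atom = mol.GetAtomWithIdx(d)
        nbrs = [n.GetIdx() for n in atom.GetNeighbors()]
        if len(nbrs) != 1:
            raise ParseError("dummy anchor atom must have exactly one neighbor")
        anchors_old.add(nbrs[0])

    keep = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() != 0]
    remap = {old: new for new, old in enumerate(keep)}
    g = MolecularGraph(registry)
    order_map = {Chem.BondType.SINGLE: 1, Chem.BondType.DOUBLE: 2, Chem.BondType.TRIPLE: 3}

    bonds = []
    valences = {old: 0 for old in keep}
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i not in remap or j not in remap:
            continue  # bond to a dummy: drop, the anchor mark carries it
        if b.GetBondType() not in order_map:
            raise ParseError(f"unsupported bond type {b.GetBondType()}")
        order = order_map[b.GetBondType()]
        bonds.append((remap[i], remap[j], order))
        valences[i] += order
        valences[j] += order

    for old in keep:
        atom = mol.GetAtomWithIdx(old)
        g.add_atom(registry.resolve(atom.GetSymbol(), atom.GetFormalCharge(), valences[old]))
    for i, j, order in bonds:
        g.add_bond(i, j, order)
    g.anchors = {remap[a] for a in anchors_old}

    if mol.GetNumConformers() > 0:
        conf = mol.GetConformer()
        g.positions = np.array([list(conf.GetAtomPosition(old)) for old in keep])
    return g


def parse_structure(text: str, registry: AtomTypeRegistry | None = None) -> MolecularGraph:
    """Parse line notation (SMILES) into a MolecularGraph.

    Dummy atoms ``[*]`` are removed and their unique neighbor becomes an
    anchor mark.  Aromatic rings are kekulized to alternating orders.
    """
    if not text or not text.strip():
        raise ParseError("empty structure string")
    mol = Chem.MolFromSmiles(text.strip())
    if mol is None:
        raise ParseError(f"could not parse structure: {text!r}")
    return from_rdkit(mol, registry)


def write_canonical(graph: MolecularGraph, anchor_dummies: bool = False) -> str:
    """Canonical line-notation string, invariant under atom-index relabeling.

    With `anchor_dummies`, anchor marks are emitted as ``[*]`` neighbors so
    fragments round-trip through :func:`parse_structure`.
    """
    graph.validate()
    mol = graph.to_rdkit(anchor_dummies=anchor_dummies)
    return Chem.MolToSmiles(mol)


def check_valence(graph: MolecularGraph) -> list[int]:
    """Indices of atoms whose summed bond orders exceed their registry valence."""
    bad = []
    for i in range(graph.n_atoms):
        if graph.valence(i) > graph.registry[graph.atoms[i]].max_valence:
            bad.append(i)
    return bad


def connected_components(graph: MolecularGraph) -> list[list[int]]:
    """Components as sorted index lists, ordered by (-size, lowest index)."""
    seen: set[int] = set()
    comps = []
    for start in range(graph.n_atoms):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            v = stack.pop()
            comp.append(v)
            for u in graph.neighbors(v):
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        comps.append(sorted(comp))
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def largest_component(graph: MolecularGraph) -> MolecularGraph:
    """Connected component with the most atoms (ties: lowest original index)."""
    if graph.n_atoms == 0:
        return graph.copy()
    comps = connected_components(graph)
    sub, _ = graph.subgraph(comps[0])
    return sub


def is_connected(graph: MolecularGraph) -> bool:
    return graph.n_atoms == 0 or len(connected_components(graph)) == 1


def graphs_isomorphic(a: MolecularGraph, b: MolecularGraph,
                      match_anchors: bool = False) -> bool:
    """Exact isomorphism on (symbol, charge)-typed nodes and order-typed edges."""
    ga, gb = a.to_networkx(), b.to_networkx()
    if match_anchors:
        for g, mg in ((ga, a), (gb, b)):
            for n in g.nodes:
                g.nodes[n]["anchor"] = n in mg.anchors
        nm = nx.algorithms.isomorphism.categorical_node_match(
            ["symbol", "charge", "anchor"], [None, None, None])
    else:
        nm = nx.algorithms.isomorphism.categorical_node_match(
            ["symbol", "charge"], [None, None])
    em = nx.algorithms.isomorphism.categorical_edge_match("order", None)
    return nx.is_isomorphic(ga, gb, node_match=nm, edge_match=em)


# ---------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------

def read_smiles_csv(path, registry: AtomTypeRegistry | None = None,
                    column: str = "smiles") -> list[MolecularGraph]:
    import pandas as pd

    df = pd.read_csv(path)
    if column not in df.columns:
        raise ValueError(f"CSV has no {column!r} column")
    return [parse_structure(s, registry) for s in df[column]]


def write_smiles_list(path, graphs, anchor_dummies: bool = False, ids=None):
    import pandas as pd

    rows = []
    for k, g in enumerate(graphs):
        rows.append({
            "id": (ids[k] if ids is not None else k),
            "smiles": write_canonical(g, anchor_dummies=anchor_dummies),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sdf(path, registry: AtomTypeRegistry | None = None) -> list[MolecularGraph]:
    """Read an SDF (V2000) file; 3D coordinates are kept when present."""
    out = []
    for mol in Chem.SDMolSupplier(str(path), removeHs=True):
        if mol is None:
            raise ParseError(f"unreadable record in {path}")
        out.append(from_rdkit(mol, registry))
    return out


def write_sdf(path, graphs):
    """Write graphs (with coordinates when available) as SDF V2000."""
    writer = Chem.SDWriter(str(path))
    try:
        for g in graphs:
            mol = g.to_rdkit()
            if g.positions is not None:
                conf = Chem.Conformer(mol.GetNumAtoms())
                for i, p in enumerate(g.positions):
                    conf.SetAtomPosition(i, [float(x) for x in p])
                mol.AddConformer(conf)
            writer.write(mol)
    finally:
        writer.close()
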