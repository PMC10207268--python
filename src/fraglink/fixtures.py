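"""Seeded synthetic library of fragment-linker-fragment molecules.

Real training data for PROTAC linker design comes from large libraries of
whole molecules segmented into warhead-linker-warhead triples.  This
module emulates that construction so every other module is testable
without downloads: each synthetic molecule is two warhead-like fragments
drawn from a small vocabulary, joined by a linker sampled from a grammar
of alkyl/ether/amine chains with optional in-chain carbocycles — the
chemotypes that dominate real PROTAC linkers (PEG-like and alkyl chains).

Ground-truth segmentation is recorded for every molecule, and idealized
3D coordinates (fixed 1.5 A bond length, near-tetrahedral angles, seeded
dihedrals) supply the anchor distance/angle descriptor.  The geometry is
deliberately not a force-field embed: ring closures are approximate, but
exit vectors and inter-anchor distances — the only coordinates the
network consumes — are well defined.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from . import fragmenter
from .fragmenter import FragmentPair, StructuralInfo, TrainingExample, compute_structural_info
from .molgraph import (AtomTypeRegistry, MolecularGraph, check_valence,
                       is_connected, parse_structure)

BOND_LENGTH = 1.5  # A, idealized
TETRAHEDRAL = np.deg2rad(109.47)


def default_vocabulary(registry: AtomTypeRegistry | None = None) -> list[MolecularGraph]:
    """Warhead-like anchored fragments shipped as a plain-text SMILES list."""
    text = (importlib.resources.files("fraglink") / "data" / "fragment_vocab.smi").read_text()
    frags = [parse_structure(line, registry) for line in text.splitlines() if line.strip()]
    for f in frags:
        if len(f.anchors) != 1:
            raise ValueError("vocabulary fragment must have exactly one anchor")
        if check_valence(f):
            raise ValueError("vocabulary fragment violates valence")
    return frags


@dataclass
class FixtureSpec:
    """Parameters of the synthetic library generator."""

    n_molecules: int = 100
    vocabulary: list = field(default_factory=default_vocabulary)
    chain_length: tuple = (3, 8)     # heavy atoms in the backbone chain
    p_ring: float = 0.25             # probability of one in-chain cyclohexane
    p_hetero: float = 0.2            # per-position O/N substitution probability
    seed: int = 0

    def __post_init__(self):
        if not self.vocabulary:
            raise ValueError("fragment vocabulary is empty")
        if self.chain_length[0] < 3:
            raise ValueError("linker chain must have at least 3 heavy atoms")


@dataclass
class LibraryEntry:
    """A synthetic molecule with its planted segmentation (indices into `molecule`)."""

    molecule: MolecularGraph
    fragment_a_atoms: frozenset
    fragment_b_atoms: frozenset
    linker_atoms: frozenset
    anchor_a: int
    anchor_b: int


# ---------------------------------------------------------------------
# Geometry: idealized coordinate walk
# ---------------------------------------------------------------------

def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)

def _perpendicular(v: np.ndarray, rng) -> np.ndarray:
    while True:
        r = _random_unit(rng)
        p = r - np.dot(r, v) * v
        n = np.linalg.norm(p)
        if n > 1e-6:
            return p / n

def _next_direction(prev_dir: np.ndarray, rng) -> np.ndarray:
    """Bend by the tetrahedral supplement around a random (seeded) dihedral axis."""
    axis = _perpendicular(prev_dir, rng)
    bend = np.pi - TETRAHEDRAL
    return np.cos(bend) * prev_dir + np.sin(bend) * axis


def assign_idealized_coordinates(graph: MolecularGraph, rng,
                                 fixed: dict[int, np.ndarray] | None = None,
                                 start_dir: dict[int, np.ndarray] | None = None):
    """BFS placement with fixed bond length and seeded chain dihedrals.

    `fixed` pins atoms to given positions (used to honor a sampled anchor
    distance/angle); `start_dir` biases the first step away from an atom.
    """
    n = graph.n_atoms
    pos = np.full((n, 3), np.nan)
    placed: set[int] = set()
    fixed = fixed or {}
    start_dir = start_dir or {}
    for i, p in fixed.items():
        pos[i] = p
        placed.add(i)

    order = sorted(fixed) or ([0] if n else [])
    if not fixed and n:
        pos[0] = np.zeros(3)
        placed.add(0)
    queue = list(order)
    while len(placed) < n:
        if not queue:  # disconnected remainder: seed a fresh walk far away
            rest = min(i for i in range(n) if i not in placed)
            pos[rest] = rng.uniform(20, 30, size=3)
            placed.add(rest)
            queue.append(rest)
        v = queue.pop(0)
        prev = None
        for u in graph.neighbors(v):
            if u in placed:
                prev = u
        for u in graph.neighbors(v):
            if u in placed:
                continue
            if v in start_dir and len([w for w in graph.neighbors(v) if w in placed]) == 0:
                direction = start_dir[v]
            elif prev is not None:
                direction = _next_direction(
                    (pos[v] - pos[prev]) / max(np.linalg.norm(pos[v] - pos[prev]), 1e-9), rng)
            else:
                direction = _random_unit(rng)
            pos[u] = pos[v] + BOND_LENGTH * direction
            placed.add(u)
            queue.append(u)
            prev = u
    graph.positions = pos


# ---------------------------------------------------------------------
# Linker grammar
# ---------------------------------------------------------------------

def _sample_linker(spec: FixtureSpec, rng) -> tuple[list[str], list[tuple[int, int]], int, int]:
    """Sample linker atoms/bonds; returns (symbols, bonds, entry index, exit index).

    Backbone chain of C with occasional O/N (never adjacent to another
    heteroatom), optionally one backbone carbon expanded into a para-linked
    cyclohexane ring.
    """
    n_chain = int(rng.integers(spec.chain_length[0], spec.chain_length[1] + 1))
    symbols: list[str] = []
    for k in range(n_chain):
        prev_hetero = bool(symbols) and symbols[-1] != "C"
        if not prev_hetero and rng.random() < spec.p_hetero:
            symbols.append("O" if rng.random() < 0.5 else "N")
        else:
            symbols.append("C")
    bonds = [(k, k + 1) for k in range(n_chain - 1)]
    entry, exit_ = 0, n_chain - 1

    if rng.random() < spec.p_ring:
        carbons = [k for k, s in enumerate(symbols) if s == "C"]
        if carbons:
            j = int(rng.choice(carbons))
            # expand chain atom j into a 6-ring: j stays as ring atom r0,
            # five new carbons r1..r5; chain neighbor after j rebonds to r3.
            base = len(symbols)
            symbols.extend(["C"] * 5)
            # reroute the outgoing chain bond to the para ring position r3
            # before adding ring bonds (the ring bond (j, base) would
            # otherwise collide with (j, j+1) when j is the last chain atom)
            bonds = [(base + 2, b) if (a, b) == (j, j + 1) else (a, b)
                     for a, b in bonds]
            ring = [j, base, base + 1, base + 2, base + 3, base + 4]
            for a, b in zip(ring, ring[1:] + [ring[0]]):
                bonds.append((a, b))
            if exit_ == j:
                exit_ = base + 2
    return symbols, bonds, entry, exit_


def _join(frag_a: MolecularGraph, frag_b: MolecularGraph, symbols, linker_bonds,
          entry: int, exit_: int, registry: AtomTypeRegistry) -> LibraryEntry:
    mol = MolecularGraph(registry)
    # fragment A
    for t in frag_a.atoms:
        mol.add_atom(t)
    for i, j, o in frag_a.bond_list():
        mol.add_bond(i, j, o)
    off_l = frag_a.n_atoms
    # linker
    for s in symbols:
        mol.add_atom(registry.resolve(s, 0, 2 if s != "C" else 4))
    for a, b in linker_bonds:
        mol.add_bond(off_l + a, off_l + b, 1)
    off_b = off_l + len(symbols)
    # fragment B
    for t in frag_b.atoms:
        mol.add_atom(t)
    for i, j, o in frag_b.bond_list():
        mol.add_bond(off_b + i, off_b + j, o)
    anchor_a = next(iter(frag_a.anchors))
    anchor_b = off_b + next(iter(frag_b.anchors))
    mol.add_bond(anchor_a, off_l + entry, 1)
    mol.add_bond(off_l + exit_, anchor_b, 1)
    mol.anchors = set()
    return LibraryEntry(
        molecule=mol,
        fragment_a_atoms=frozenset(range(frag_a.n_atoms)),
        fragment_b_atoms=frozenset(range(off_b, off_b + frag_b.n_atoms)),
        linker_atoms=frozenset(range(off_l, off_l + len(symbols))),
        anchor_a=anchor_a,
        anchor_b=anchor_b,
    )


# ---------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------

def make_library(spec: FixtureSpec) -> list[LibraryEntry]:
    """Deterministic (per seed) synthetic library with planted segmentations."""
    rng = np.random.default_rng(spec.seed)
    registry = spec.vocabulary[0].registry
    out = []
    for _ in range(spec.n_molecules):
        ia, ib = rng.integers(0, len(spec.vocabulary), size=2)
        frag_a, frag_b = spec.vocabulary[int(ia)], spec.vocabulary[int(ib)]
        symbols, bonds, entry, exit_ = _sample_linker(spec, rng)
        item = _join(frag_a, frag_b, symbols, bonds, entry, exit_, registry)
        assign_idealized_coordinates(item.molecule, rng)
        if check_valence(item.molecule) or not is_connected(item.molecule):
            raise AssertionError("fixture construction produced an invalid molecule")
        out.append(item)
    return out


def planted_example(entry: LibraryEntry) -> TrainingExample:
    """Build the TrainingExample for a library entry's planted segmentation."""
    mol = entry.molecule
    la = next(n for n in mol.neighbors(entry.anchor_a) if n in entry.linker_atoms)
    lb = next(n for n in mol.neighbors(entry.anchor_b) if n in entry.linker_atoms)
    b1 = tuple(sorted((entry.anchor_a, la)))
    b2 = tuple(sorted((entry.anchor_b, lb)))
    outer = [entry.fragment_a_atoms, entry.fragment_b_atoms]
    return fragmenter._build_example(mol, b1, b2, entry.linker_atoms, outer)


def make_fragment_pair(spec: FixtureSpec, seed: int) -> FragmentPair:
    """Two vocabulary fragments placed at a seeded anchor distance and angle.

    Distance is uniform in [4, 12] A, exit-vector angle uniform in [0, pi];
    the StructuralInfo is computed back from the placed coordinates.
    """
    rng = np.random.default_rng(seed)
    ia, ib = rng.integers(0, len(spec.vocabulary), size=2)
    frag_a = spec.vocabulary[int(ia)].copy()
    frag_b = spec.vocabulary[int(ib)].copy()
    distance = float(rng.uniform(4.0, 12.0))
    angle = float(rng.uniform(0.0, np.pi))

    ua = np.array([1.0, 0.0, 0.0])
    ub = np.array([np.cos(angle), np.sin(angle), 0.0])

    for frag, anchor_pos, u in (
        (frag_a, np.zeros(3), ua),
        (frag_b, np.array([distance, 0.0, 0.0]), ub),
    ):
        anchor = next(iter(frag.anchors))
        fixed = {anchor: anchor_pos}
        nbrs = frag.neighbors(anchor)
        if nbrs:
            fixed[nbrs[0]] = anchor_pos - BOND_LENGTH * u
        assign_idealized_coordinates(frag, rng, fixed=fixed)

    aa, ab = next(iter(frag_a.anchors)), next(iter(frag_b.anchors))
    na, nb = frag_a.neighbors(aa)[0], frag_b.neighbors(ab)[0]
    # joint conformer indexing: fragment B appended after fragment A
    joint = np.vstack([frag_a.positions, frag_b.positions])
    from .molgraph import Conformer

    info = compute_structural_info(Conformer(joint), aa, na,
                                   frag_a.n_atoms + ab, frag_a.n_atoms + nb)
    return FragmentPair(fragment_a=frag_a, fragment_b=frag_b, info=info)
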