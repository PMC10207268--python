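"""Construct fragment-linker-fragment training pairs from whole molecules.

A training molecule Y is segmented by cutting exactly two distinct acyclic
single bonds so that the middle piece (the linker) keeps at least three
heavy atoms and no ring is ever split.  The two outer pieces become the
anchored fragments; each cut site is marked as an anchor.  The anchor
geometry — inter-anchor distance and the angle between the two exit
vectors — is always computed from 3D coordinates, never estimated from
topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.model_selection import KFold

from .molgraph import Conformer, MolecularGraph, is_connected


class DegenerateGeometryError(ValueError):
    """Zero-length exit vector."""


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class StructuralInfo:
    """Relative geometry of the two anchors: distance (A) and exit-vector angle (rad)."""

    distance: float
    angle: float

    def __post_init__(self):
        if self.distance < 0:
            raise ValueError("distance must be non-negative")
        if not (-1e-9 <= self.angle <= np.pi + 1e-9):
            raise ValueError("angle must lie in [0, pi]")

    def as_array(self) -> np.ndarray:
        return np.array([self.distance, self.angle], dtype=float)


@dataclass
class FragmentPair:
    """Two connected fragments, each with exactly one anchor, plus geometry."""

    fragment_a: MolecularGraph
    fragment_b: MolecularGraph
    info: StructuralInfo | None = None

    def __post_init__(self):
        for name, frag in (("fragment_a", self.fragment_a), ("fragment_b", self.fragment_b)):
            if len(frag.anchors) != 1:
                raise ValueError(f"{name} must have exactly one anchor mark")
            if not is_connected(frag):
                raise ValueError(f"{name} must be connected")

    @property
    def anchor_a(self) -> int:
        return next(iter(self.fragment_a.anchors))

    @property
    def anchor_b(self) -> int:
        return next(iter(self.fragment_b.anchors))


@dataclass
class TrainingExample:
    """A segmentation of a whole molecule Y into fragment-linker-fragment.

    Indices refer to Y's atom numbering: `linker_atoms` is the middle
    piece, `anchor_a_y`/`anchor_b_y` are the fragment-side cut atoms and
    `fragment_a_atoms`/`fragment_b_atoms` the two outer pieces.
    """

    pair: FragmentPair
    target: MolecularGraph
    linker_atoms: frozenset
    anchor_a_y: int
    anchor_b_y: int
    fragment_a_atoms: frozenset
    fragment_b_atoms: frozenset

    def __post_init__(self):
        if len(self.linker_atoms) < 3:
            raise ValueError("linker must contain at least 3 heavy atoms")

    def linker_graph(self) -> MolecularGraph:
        sub, _ = self.target.subgraph(sorted(self.linker_atoms))
        sub.anchors = set()
        return sub


# ---------------------------------------------------------------------

def _bridges(mol: MolecularGraph) -> set[frozenset]:
    """Acyclic bonds = bridges of the bond graph."""
    g = mol.to_networkx()
    return {frozenset(e) for e in nx.bridges(g)}


def _component_of(mol: MolecularGraph, start: int, banned: set[frozenset]) -> set[int]:
    """Flood fill from `start`, never crossing bonds in `banned`."""
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for u in mol.neighbors(v):
            if frozenset((v, u)) in banned or u in seen:
                continue
            seen.add(u)
            stack.append(u)
    return seen


def _exit_direction(mol: MolecularGraph, anchor: int, fragment: set[int],
                    cut_partner: int) -> int:
    """Reference atom defining the exit vector at `anchor`.

    Normally a fragment-internal neighbor; for a single-atom fragment the
    only geometric handle is the cut bond itself, so the old linker-side
    partner serves as the (negated) reference.
    """
    internal = [n for n in mol.neighbors(anchor) if n in fragment]
    if internal:
        return min(internal)
    return cut_partner


def compute_structural_info(conf: Conformer, anchor_a: int, neighbor_a: int,
                            anchor_b: int, neighbor_b: int) -> StructuralInfo:
    """Distance between anchors and angle between their exit vectors.

    The exit vector at an anchor points away from its fragment:
    u = normalize(pos[anchor] - pos[neighbor]).
    """
    pos = conf.positions
    n = len(pos)
    for idx in (anchor_a, neighbor_a, anchor_b, neighbor_b):
        if not (0 <= idx < n):
            raise IndexError(f"atom index {idx} outside conformer of size {n}")
    if anchor_a == anchor_b:
        raise ValueError("anchors must be distinct")
    d = float(np.linalg.norm(pos[anchor_a] - pos[anchor_b]))
    ua = pos[anchor_a] - pos[neighbor_a]
    ub = pos[anchor_b] - pos[neighbor_b]
    for v in (ua, ub):
        if np.linalg.norm(v) < 1e-9:
            raise DegenerateGeometryError("zero-length exit vector")
    ua = ua / np.linalg.norm(ua)
    ub = ub / np.linalg.norm(ub)
    angle = float(np.arccos(np.clip(np.dot(ua, ub), -1.0, 1.0)))
    return StructuralInfo(distance=d, angle=angle)


def enumerate_linker_cuts(mol: MolecularGraph, min_linker_atoms: int = 3,
                          min_fragment_atoms: int = 1) -> list[TrainingExample]:
    """All two-cut segmentations of a connected molecule.

    Every returned example cuts two distinct acyclic single bonds; the
    middle piece has >= `min_linker_atoms` heavy atoms, outer pieces have
    >= `min_fragment_atoms`, and no ring bond is ever cut.  An empty list
    (no valid cut pair) is not an error.
    """
    if not is_connected(mol):
        raise ValueError("molecule must be connected")
    mol.validate()

    cuttable = sorted(
        (tuple(sorted(k)) for k, order in mol.bonds.items()
         if order == 1 and k in _bridges(mol)),
    )
    out: list[TrainingExample] = []
    for ai in range(len(cuttable)):
        for bi in range(ai + 1, len(cuttable)):
            b1, b2 = cuttable[ai], cuttable[bi]
            banned = {frozenset(b1), frozenset(b2)}
            comp_cache: dict[int, frozenset] = {}

            def comp(v):
                if v not in comp_cache:
                    c = frozenset(_component_of(mol, v, banned))
                    for x in c:
                        comp_cache[x] = c
                return comp_cache[v]

            # middle piece = the unique component touching both cut bonds
            comps_b1 = {comp(b1[0]), comp(b1[1])}
            comps_b2 = {comp(b2[0]), comp(b2[1])}
            middle_set = comps_b1 & comps_b2
            if len(middle_set) != 1:
                continue
            linker = next(iter(middle_set))
            outer = [c for c in (comps_b1 | comps_b2) if c is not linker and c != linker]
            if len(outer) != 2:
                continue
            if len(linker) < min_linker_atoms:
                continue
            if any(len(c) < min_fragment_atoms for c in outer):
                continue
            out.append(_build_example(mol, b1, b2, linker, outer))
    return out


def _build_example(mol: MolecularGraph, b1, b2, linker: frozenset,
                   outer: list) -> TrainingExample:
    # fragment_a = outer piece containing the lowest original atom index
    outer = sorted(outer, key=lambda c: min(c))
    frag_a_set, frag_b_set = set(outer[0]), set(outer[1])

    def cut_for(frag: set):
        for bond in (b1, b2):
            i, j = bond
            if i in frag:
                return i, j
            if j in frag:
                return j, i
        raise AssertionError("cut bond not adjacent to fragment")

    anchor_a_y, partner_a = cut_for(frag_a_set)
    anchor_b_y, partner_b = cut_for(frag_b_set)

    frag_a, map_a = mol.subgraph(sorted(frag_a_set))
    frag_b, map_b = mol.subgraph(sorted(frag_b_set))
    frag_a.anchors = {map_a[anchor_a_y]}
    frag_b.anchors = {map_b[anchor_b_y]}

    info = None
    if mol.positions is not None:
        ref_a = _exit_direction(mol, anchor_a_y, frag_a_set, partner_a)
        ref_b = _exit_direction(mol, anchor_b_y, frag_b_set, partner_b)
        conf = mol.conformer()
        if ref_a == partner_a or ref_b == partner_b:
            # single-atom fragment: exit vector along the cut bond
            pos = conf.positions
            ua = (pos[partner_a] - pos[anchor_a_y]) if ref_a == partner_a else \
                 (pos[anchor_a_y] - pos[ref_a])
            ub = (pos[partner_b] - pos[anchor_b_y]) if ref_b == partner_b else \
                 (pos[anchor_b_y] - pos[ref_b])
            d = float(np.linalg.norm(pos[anchor_a_y] - pos[anchor_b_y]))
            na, nb = np.linalg.norm(ua), np.linalg.norm(ub)
            if na < 1e-9 or nb < 1e-9:
                raise DegenerateGeometryError("zero-length exit vector")
            angle = float(np.arccos(np.clip(np.dot(ua / na, ub / nb), -1.0, 1.0)))
            info = StructuralInfo(distance=d, angle=angle)
        else:
            info = compute_structural_info(conf, anchor_a_y, ref_a, anchor_b_y, ref_b)

    pair = FragmentPair(fragment_a=frag_a, fragment_b=frag_b, info=info)
    return TrainingExample(
        pair=pair,
        target=mol,
        linker_atoms=frozenset(linker),
        anchor_a_y=anchor_a_y,
        anchor_b_y=anchor_b_y,
        fragment_a_atoms=frozenset(frag_a_set),
        fragment_b_atoms=frozenset(frag_b_set),
    )


def split_dataset(examples: list, train_fraction: float = 0.9, k_folds: int = 10,
                  seed: int = 0) -> list[dict]:
    """Deterministic k-fold assignments (shuffled once by `seed`).

    Returns one dict per fold with 'train' and 'validation' index lists;
    validation folds partition the data into pieces of size floor(n/k) or
    ceil(n/k), consistent with holding out 1/k (= 1 - train_fraction).
    """
    n = len(examples)
    if n == 0:
        raise ConfigurationError("dataset is empty")
    if k_folds > n:
        raise ConfigurationError(f"k_folds={k_folds} exceeds dataset size {n}")
    if abs((1.0 - train_fraction) - 1.0 / k_folds) > 1e-9:
        raise ConfigurationError("train_fraction must equal 1 - 1/k_folds")
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    return [
        {"train": train.tolist(), "validation": val.tolist()}
        for train, val in kf.split(np.arange(n))
    ]


def assemble_dataset(molecules: list[MolecularGraph], min_linker_atoms: int = 3,
                     max_cuts_per_molecule: int = 10,
                     seed: int = 0) -> list[TrainingExample]:
    """Enumerate cuts over a library, capping examples per molecule.

    Molecules admitting many cut pairs are down-sampled (seeded) to
    `max_cuts_per_molecule` to avoid large-molecule bias.
    """
    rng = np.random.default_rng(seed)
    out = []
    for mol in molecules:
        cuts = enumerate_linker_cuts(mol, min_linker_atoms=min_linker_atoms)
        if len(cuts) > max_cuts_per_molecule:
            idx = rng.choice(len(cuts), size=max_cuts_per_molecule, replace=False)
            cuts = [cuts[i] for i in sorted(idx)]
        out.extend(cuts)
    return out


def write_examples_csv(path, examples: list[TrainingExample]):
    """One record per example: anchored fragments, linker, molecule, geometry."""
    import pandas as pd

    from .molgraph import write_canonical

    rows = []
    for ex in examples:
        rows.append({
            "fragment_a": write_canonical(ex.pair.fragment_a, anchor_dummies=True),
            "fragment_b": write_canonical(ex.pair.fragment_b, anchor_dummies=True),
            "linker": write_canonical(ex.linker_graph()),
            "molecule": write_canonical(ex.target),
            "distance": None if ex.pair.info is None else ex.pair.info.distance,
            "angle": None if ex.pair.info is None else ex.pair.info.angle,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
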