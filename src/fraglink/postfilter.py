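"""Post-generation filtering: duplicates, non-linked outputs, unwanted chemistry.

Raw decoder output contains duplicated structures, molecules where the
two fragments never fused into one compound, and chemically unreasonable
linkers.  The pipeline runs two stages:

1. deduplicate by canonical string, then drop molecules that are not a
   single compound with both fragments joined through the designated
   anchors;
2. drop molecules whose linker region carries a reactive or strained
   motif: acid halides, disulfides, peroxides, C=C inside a 3- or
   4-membered ring, or a bridgehead C=C in a small bridged bicyclic
   system (Bredt's rule).

Only the linker atoms and their anchor bonds are inspected in stage 2 —
the warhead fragments are fixed user input, not the generator's doing.
SMARTS-expressible motifs live in an editable plain-text registry
(``data/filter_patterns.smarts``); the two ring-based rules are computed
from ring analysis directly.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import networkx as nx
from networkx.algorithms import isomorphism
from rdkit import Chem

from .fragmenter import FragmentPair
from .molgraph import MolecularGraph, is_connected, write_canonical


@dataclass
class FilterReport:
    """Counts and per-molecule records from the filter pipeline."""

    n_raw: int = 0
    n_after_dedup_nonlinker: int = 0
    n_final: int = 0
    flags: list = field(default_factory=list)          # (canonical, [flag, ...]) kept+dropped at stage 2
    removed: list = field(default_factory=list)        # (stage, canonical, reason)

    def counts(self) -> tuple:
        return (self.n_raw, self.n_after_dedup_nonlinker, self.n_final)

    def summary(self) -> str:
        return (f"raw: {self.n_raw}\n"
                f"after dedup + linkage filter: {self.n_after_dedup_nonlinker}\n"
                f"after substructure filter: {self.n_final}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.removed, columns=["stage", "smiles", "reason"])


def load_pattern_registry(path=None) -> dict[str, Chem.Mol]:
    """Named SMARTS patterns from the plain-text registry file."""
    if path is None:
        text = (importlib.resources.files("fraglink") / "data" /
                "filter_patterns.smarts").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smarts = line.split(None, 1)
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"bad SMARTS for pattern {name!r}: {smarts}")
        out[name] = patt
    return out


_DEFAULT_PATTERNS = None


def _patterns() -> dict:
    global _DEFAULT_PATTERNS
    if _DEFAULT_PATTERNS is None:
        _DEFAULT_PATTERNS = load_pattern_registry()
    return _DEFAULT_PATTERNS


# ---------------------------------------------------------------------
# Stage 1: duplicates and non-linked outputs
# ---------------------------------------------------------------------

def dedup(mols: list[MolecularGraph]) -> list[MolecularGraph]:
    """Keep the first occurrence of each canonical form; order-stable."""
    seen: set[str] = set()
    out = []
    for m in mols:
        key = write_canonical(m)
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out


def _fragment_embeddings(mol_nx: nx.Graph, frag: MolecularGraph):
    """All node-induced embeddings of `frag` into the molecule graph."""
    nm = isomorphism.categorical_node_match(["symbol", "charge"], [None, None])
    em = isomorphism.categorical_edge_match("order", None)
    gm = isomorphism.GraphMatcher(mol_nx, frag.to_networkx(),
                                  node_match=nm, edge_match=em)
    # subgraph_isomorphisms map mol nodes -> frag nodes over induced subgraphs
    return list(gm.subgraph_isomorphisms_iter())


def find_linkage(mol: MolecularGraph, pair: FragmentPair):
    """Locate both fragments inside `mol`, linked through their anchors.

    Returns (frag_a_atoms, frag_b_atoms, linker_atoms) as sets of `mol`
    indices, or None if no valid joint embedding exists.  A valid
    embedding places the two fragments on disjoint atom sets and gives
    each fragment's anchor image at least one bond to an atom outside
    both fragments (a linker atom).
    """
    if mol.n_atoms == 0 or not is_connected(mol):
        return None
    mol_nx = mol.to_networkx()
    embs_a = _fragment_embeddings(mol_nx, pair.fragment_a)
    embs_b = _fragment_embeddings(mol_nx, pair.fragment_b)
    for ea in embs_a:
        inv_a = {v: k for k, v in ea.items()}
        set_a = set(ea.keys())
        for eb in embs_b:
            set_b = set(eb.keys())
            if set_a & set_b:
                continue
            inv_b = {v: k for k, v in eb.items()}
            linker = set(range(mol.n_atoms)) - set_a - set_b
            if not linker:
                continue
            aa = inv_a[pair.anchor_a]
            ab = inv_b[pair.anchor_b]
            if any(n in linker for n in mol.neighbors(aa)) and \
               any(n in linker for n in mol.neighbors(ab)):
                return set_a, set_b, linker
    return None


def is_linked(mol: MolecularGraph, pair: FragmentPair) -> bool:
    """True iff mol is one connected compound with both fragments joined
    to a linker through their designated anchor atoms."""
    return find_linkage(mol, pair) is not None


def extract_linker(mol: MolecularGraph, pair: FragmentPair) -> MolecularGraph | None:
    """The linker subgraph of a linked molecule (fragments stripped)."""
    loc = find_linkage(mol, pair)
    if loc is None:
        return None
    _, _, linker = loc
    sub, _ = mol.subgraph(sorted(linker))
    sub.anchors = set()
    return sub


def _linker_region(mol: MolecularGraph, pair: FragmentPair) -> MolecularGraph:
    """Linker atoms plus the anchor atoms they bond to (anchor bonds kept)."""
    loc = find_linkage(mol, pair)
    if loc is None:
        return mol
    set_a, set_b, linker = loc
    keep = set(linker)
    for i in sorted(set_a | set_b):
        if any(n in linker for n in mol.neighbors(i)):
            keep.add(i)
    region, remap = mol.subgraph(sorted(keep))
    # drop fragment-internal bonds between kept anchor atoms
    frag_kept = {remap[i] for i in keep - linker}
    for key in [k for k in region.bonds if k <= frag_kept]:
        del region.bonds[key]
    region.anchors = set()
    return region


# ---------------------------------------------------------------------
# Stage 2: unwanted substructures
# ---------------------------------------------------------------------

def _ring_info(mol: Chem.Mol):
    return [list(r) for r in Chem.GetSymmSSSR(Chem.Mol(mol))]


def _strained_ring_alkene(rdmol: Chem.Mol) -> bool:
    """C=C inside a 3- or 4-membered ring (cyclopropene/cyclobutene class)."""
    for ring in _ring_info(rdmol):
        if len(ring) not in (3, 4):
            continue
        rset = set(ring)
        for b in rdmol.GetBonds():
            if (b.GetBondType() == Chem.BondType.DOUBLE
                    and b.GetBeginAtomIdx() in rset and b.GetEndAtomIdx() in rset
                    and b.GetBeginAtom().GetSymbol() == "C"
                    and b.GetEndAtom().GetSymbol() == "C"
                    and b.IsInRing()):
                return True
    return False


def _bredt_violation(rdmol: Chem.Mol) -> bool:
    """Bridgehead C=C in a small bridged (not merely fused) bicyclic system.

    Ring pairs sharing >= 3 atoms form a bridged system; the bridgeheads
    are the shared atoms with a neighbor outside the shared path.  A
    double bond at such a bridgehead is flagged when every ring through
    the atom is small (size <= 7) — large bridged rings can accommodate
    the planar center.
    """
    rings = [set(r) for r in _ring_info(rdmol)]
    ri = rdmol.GetRingInfo()
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            shared = rings[i] & rings[j]
            if len(shared) < 3:
                continue
            union = rings[i] | rings[j]
            for a in shared:
                atom = rdmol.GetAtomWithIdx(a)
                nbrs = {n.GetIdx() for n in atom.GetNeighbors()}
                if not (nbrs & (union - shared)):
                    continue  # interior of the shared path, not a bridgehead
                if max((s for s in ri.AtomRingSizes(a)), default=0) > 7:
                    continue
                for b in atom.GetBonds():
                    other = b.GetOtherAtom(atom)
                    if (b.GetBondType() == Chem.BondType.DOUBLE
                            and atom.GetSymbol() == "C" and other.GetSymbol() == "C"):
                        return True
    return False


def flag_unwanted(mol: MolecularGraph, patterns: dict | None = None) -> list[str]:
    """Every unwanted-substructure flag raised by `mol`.

    SMARTS flags (acid_halide, disulfide, peroxide) come from the pattern
    registry; strained_ring_alkene and bredt_violation from ring analysis.
    """
    rdmol = mol.to_rdkit()
    flags = []
    for name, patt in (patterns or _patterns()).items():
        if rdmol.HasSubstructMatch(patt):
            flags.append(name)
    if _strained_ring_alkene(rdmol):
        flags.append("strained_ring_alkene")
    if _bredt_violation(rdmol):
        flags.append("bredt_violation")
    return flags


# ---------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------

def run_pipeline(mols: list[MolecularGraph], pair: FragmentPair | None = None,
                 patterns: dict | None = None):
    """Dedup -> linkage filter -> substructure filter.

    With `pair` given, stage 2 inspects only the linker region (linker
    atoms plus anchor bonds); without it, whole molecules are inspected.
    Returns (kept molecules, FilterReport).
    """
    report = FilterReport(n_raw=len(mols))

    unique = dedup(mols)
    dropped_dup = len(mols) - len(unique)
    if dropped_dup:
        report.removed.append(("dedup", f"{dropped_dup} duplicates", "duplicate"))

    if pair is not None:
        stage1 = []
        for m in unique:
            if is_linked(m, pair):
                stage1.append(m)
            else:
                report.removed.append(("nonlinker", write_canonical(m), "not linked at anchors"))
    else:
        stage1 = unique
    report.n_after_dedup_nonlinker = len(stage1)

    kept = []
    for m in stage1:
        region = _linker_region(m, pair) if pair is not None else m
        flags = flag_unwanted(region, patterns)
        report.flags.append((write_canonical(m), flags))
        if flags:
            report.removed.append(("substructure", write_canonical(m), ",".join(flags)))
        else:
            kept.append(m)
    report.n_final = len(kept)
    return kept, report
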