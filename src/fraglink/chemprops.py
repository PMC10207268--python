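"""Fragment-likeness profiling and generation-quality metrics.

The Rule of Three is the classic fragment screen: molecular weight
< 300 Da, cLogP <= 3, hydrogen-bond donors <= 3, acceptors <= 3, here
extended with topological polar surface area <= 60 A^2.  It is applied to
the extracted linker (attachment points hydrogen-capped), not to the full
PROTAC — the generator only authors the linker region.

Descriptors use the standard published schemes as implemented in RDKit:
Wildman-Crippen atom contributions for cLogP, Ertl's fragment table for
TPSA, Lipinski N/O counting for donors/acceptors.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit import Chem

from .fragmenter import FragmentPair
from .molgraph import MolecularGraph, check_valence, write_canonical
from .postfilter import extract_linker, is_linked

RULE_OF_THREE = {"mw": 300.0, "clogp": 3.0, "hbd": 3, "hba": 3, "psa": 60.0}


@dataclass(frozen=True)
class PropertyProfile:
    """Rule-of-Three descriptor set for one linker, with pass flags."""

    mw: float
    clogp: float
    hbd: int
    hba: int
    psa: float

    @property
    def passes(self) -> dict[str, bool]:
        return {
            "mw": self.mw < RULE_OF_THREE["mw"],
            "clogp": self.clogp <= RULE_OF_THREE["clogp"],
            "hbd": self.hbd <= RULE_OF_THREE["hbd"],
            "hba": self.hba <= RULE_OF_THREE["hba"],
            "psa": self.psa <= RULE_OF_THREE["psa"],
        }

    @property
    def passes_all(self) -> bool:
        return all(self.passes.values())


def property_profile(linker: MolecularGraph) -> PropertyProfile:
    """MW, cLogP, HBD, HBA and TPSA of a linker (implicit-H capped)."""
    if linker.n_atoms == 0:
        raise ValueError("empty molecule")
    if check_valence(linker):
        raise ValueError("linker violates valence")
    mol = linker.to_rdkit()
    return PropertyProfile(
        mw=float(Descriptors.MolWt(mol)),
        clogp=float(Crippen.MolLogP(mol)),
        hbd=int(Lipinski.NHOHCount(mol)),
        hba=int(Lipinski.NOCount(mol)),
        psa=float(rdMolDescriptors.CalcTPSA(mol)),
    )


def rule_of_three_report(linkers: list[MolecularGraph]) -> dict[str, int]:
    """Per-metric pass percentage (rounded to integer percent)."""
    if not linkers:
        raise ValueError("linker list is empty")
    profiles = [property_profile(lk) for lk in linkers]
    out = {}
    for key in RULE_OF_THREE:
        n_pass = sum(1 for p in profiles if p.passes[key])
        out[key] = int(round(100.0 * n_pass / len(profiles)))
    return out


def ring_statistics(linkers: list[MolecularGraph]) -> dict:
    """Ring-structure statistics over a linker pool.

    Counts molecules with at least one ring, incidence of ring sizes
    (3/4/5/6/>6, one incidence per molecule per size bucket, smallest-
    set-of-smallest-rings basis) and bicyclic/tricyclic linkers.
    """
    stats = {
        "n_linkers": len(linkers), "n_with_ring": 0,
        "ring_size_3": 0, "ring_size_4": 0, "ring_size_5": 0,
        "ring_size_6": 0, "ring_size_above_6": 0,
        "bicyclic": 0, "tricyclic": 0,
    }
    for lk in linkers:
        mol = lk.to_rdkit()
        sizes = [len(r) for r in Chem.GetSymmSSSR(mol)]
        if not sizes:
            continue
        stats["n_with_ring"] += 1
        present = set(sizes)
        for s in (3, 4, 5, 6):
            if s in present:
                stats[f"ring_size_{s}"] += 1
        if any(s > 6 for s in present):
            stats["ring_size_above_6"] += 1
        if len(sizes) >= 2:
            stats["bicyclic"] += 1
        if len(sizes) >= 3:
            stats["tricyclic"] += 1
    return stats


def generation_metrics(generated: list[MolecularGraph], training_linkers: set,
                       pair: FragmentPair) -> dict[str, float]:
    """Validity / uniqueness / novelty / anchor-correctness percentages.

    valid: valence-legal and linked at the designated anchors;
    unique: distinct canonical forms among the valid molecules;
    novel: unique valid molecules whose extracted linker's canonical form
    is absent from the training linker set;
    linked_correct: valid molecules linked at the designated anchors.
    """
    if not generated:
        raise ValueError("generated list is empty")
    n = len(generated)
    valid = [m for m in generated if not check_valence(m) and is_linked(m, pair)]
    if not valid:
        return {"valid": 0.0, "unique": 0.0, "novel": 0.0, "linked_correct": 0.0}
    canon_seen = {}
    for m in valid:
        canon_seen.setdefault(write_canonical(m), m)
    unique_mols = list(canon_seen.values())
    novel = 0
    for m in unique_mols:
        lk = extract_linker(m, pair)
        if lk is None or write_canonical(lk) not in training_linkers:
            novel += 1
    linked = sum(1 for m in valid if is_linked(m, pair))
    return {
        "valid": 100.0 * len(valid) / n,
        "unique": 100.0 * len(unique_mols) / len(valid),
        "novel": 100.0 * novel / len(unique_mols),
        "linked_correct": 100.0 * linked / len(valid),
    }


def properties_table(linkers: list[MolecularGraph]):
    """Tidy per-linker descriptor table (rows: linkers, columns: metrics)."""
    import pandas as pd

    rows = []
    for lk in linkers:
        p = property_profile(lk)
        rows.append({"smiles": write_canonical(lk), "mw": p.mw, "clogp": p.clogp,
                     "hbd": p.hbd, "hba": p.hba, "psa": p.psa,
                     "passes_all": p.passes_all})
    return pd.DataFrame(rows)
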