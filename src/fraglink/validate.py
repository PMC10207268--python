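"""Structural and energetic comparison arithmetic.

Pose similarity is the root-mean-square deviation over index-matched
atoms, optionally after least-squares rigid superposition (proper
rotations only).  Binding energetics are simple differences consumed
from external MM-PBSA / FEP evaluations:

    dG_binding  = G_complex - G_protein - G_ligand
    ddG_binding = dG_pose - dG_reference           (pose minus crystal)
    ddG_FEP     = dG_complex(L0->L1) - dG_ligand(L0->L1)

with mean +/- sample standard deviation aggregation across repeat runs.
This module never runs docking, MD or FEP itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molgraph import Conformer


@dataclass(frozen=True)
class EnergyRecord:
    """A binding free energy, optionally with its decomposition (kcal/mol)."""

    dg_binding: float
    g_complex: float | None = None
    g_protein: float | None = None
    g_ligand: float | None = None

    def __post_init__(self):
        comps = (self.g_complex, self.g_protein, self.g_ligand)
        if all(c is not None for c in comps):
            expected = self.g_complex - self.g_protein - self.g_ligand
            if abs(self.dg_binding - expected) > 1e-6:
                raise ValueError(
                    f"dg_binding={self.dg_binding} inconsistent with components "
                    f"({expected})")


@dataclass(frozen=True)
class FepRunRecord:
    """One FEP run: alchemical dG in the complex and in solution (kcal/mol)."""

    dg_complex: float
    dg_ligand: float

    def __post_init__(self):
        if not (np.isfinite(self.dg_complex) and np.isfinite(self.dg_ligand)):
            raise ValueError("FEP energies must be finite")


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Proper rotation minimizing ||p - q R|| for centered coordinate sets."""
    h = q.T @ p
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, 1.0, sign])
    return u @ d @ vt


def rmsd(a: Conformer, b: Conformer, superimpose: bool = False) -> float:
    """RMSD in Angstrom between index-corresponding atoms.

    rmsd = sqrt( (1/N) * sum_i d_i^2 ) with d_i the Euclidean distance of
    the i-th atom pair.  With `superimpose`, b is first aligned to a by
    the optimal rigid rotation+translation (reflections disallowed).
    """
    pa, pb = a.positions, b.positions
    if len(pa) != len(pb):
        raise ValueError(f"atom count mismatch: {len(pa)} vs {len(pb)}")
    if len(pa) == 0:
        raise ValueError("empty conformers")
    if superimpose:
        ca, cb = pa.mean(axis=0), pb.mean(axis=0)
        rot = kabsch_rotation(pa - ca, pb - cb)
        pb = (pb - cb) @ rot + ca
    d2 = np.sum((pa - pb) ** 2, axis=1)
    return float(np.sqrt(d2.mean()))


def relative_binding(dg_pose: float, dg_reference: float) -> float:
    """ddG_binding = dG(pose) - dG(reference crystal pose), kcal/mol."""
    return float(dg_pose) - float(dg_reference)


def fep_ddg(run: FepRunRecord) -> float:
    """Relative binding free energy of one FEP run: dG_complex - dG_ligand."""
    return run.dg_complex - run.dg_ligand


def aggregate(values: list[float]) -> tuple[float, float]:
    """(mean, sample SD with n-1 denominator); rounding is left to report time."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 values for a sample SD")
    return float(vals.mean()), float(vals.std(ddof=1))


# ---------------------------------------------------------------------
# CSV report shaping
# ---------------------------------------------------------------------

def binding_summary(df, reference_id: str):
    """Pose-energy table -> ddG column against a reference pose.

    `df` needs columns id, dg_binding; returns the frame plus a
    'ddg_binding' column (reference row left empty).
    """
    import pandas as pd

    if reference_id not in set(df["id"]):
        raise ValueError(f"reference id {reference_id!r} not in table")
    ref = float(df.loc[df["id"] == reference_id, "dg_binding"].iloc[0])
    out = df.copy()
    out["ddg_binding"] = [
        None if i == reference_id else round(relative_binding(g, ref), 2)
        for i, g in zip(out["id"], out["dg_binding"])
    ]
    return out


def fep_summary(df):
    """Per-run FEP table -> per-pair ddG rows plus mean +/- SD.

    `df` needs columns pair, run, dg_complex, dg_ligand.
    """
    import pandas as pd

    rows = []
    for pair_name, grp in df.groupby("pair", sort=False):
        ddgs = [fep_ddg(FepRunRecord(float(r.dg_complex), float(r.dg_ligand)))
                for r in grp.itertuples()]
        for run_id, v in zip(grp["run"], ddgs):
            rows.append({"pair": pair_name, "run": run_id, "ddg": round(v, 2)})
        mean, sd = aggregate(ddgs)
        rows.append({"pair": pair_name, "run": "average",
                     "ddg": round(mean, 2), "sd": round(sd, 2)})
    return pd.DataFrame(rows)
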