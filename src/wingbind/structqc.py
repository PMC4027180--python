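"""NMR ensemble coordinate analysis.

Precision of a multi-model NMR ensemble is quantified as the average RMSD of
the models to their mean structure after iterative least-squares
superposition (Kabsch algorithm, proper rotations only), over a chosen
residue window and atom set.  Backbone phi/psi torsions are computed for
descriptive Ramachandran statistics with a deliberately simplified
favored-region label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

BACKBONE_ATOMS = ("N", "CA", "C", "O")

MODEL_COLUMNS = ["residue", "resname", "atom", "x", "y", "z"]


@dataclass
class StructureEnsemble:
    """Ordered models, each a DataFrame of atoms (residue, resname, atom, xyz)."""

    models: list    # list[pd.DataFrame]

    def __post_init__(self):
        if not self.models:
            raise ValueError("empty ensemble")
        for m in self.models:
            missing = set(MODEL_COLUMNS) - set(m.columns)
            if missing:
                raise ValueError(f"model missing columns {sorted(missing)}")
            if not np.all(np.isfinite(m[["x", "y", "z"]].to_numpy(float))):
                raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.models)

    def select(self, residue_range: Optional[tuple[int, int]] = None,
               atoms: str = "backbone") -> list[np.ndarray]:
        """Matching coordinate arrays (one per model) for a residue window
        and atom set ('backbone' = N, CA, C, O; 'heavy' = non-hydrogen)."""
        coords = []
        roster = None
        for m in self.models:
            sub = m
            if residue_range is not None:
                lo, hi = residue_range
                sub = sub[(sub["residue"] >= lo) & (sub["residue"] <= hi)]
            if atoms == "backbone":
                sub = sub[sub["atom"].isin(BACKBONE_ATOMS)]
            elif atoms == "heavy":
                sub = sub[~sub["atom"].str.startswith(("H", "1H", "2H", "3H"))]
            else:
                raise ValueError(f"unknown atom set {atoms!r}")
            sub = sub.sort_values(["residue", "atom"], kind="stable")
            key = list(zip(sub["residue"], sub["atom"]))
            if roster is None:
                roster = key
            elif key != roster:
                raise ValueError("models do not share the same atom roster "
                                 "over the selection")
            coords.append(sub[["x", "y", "z"]].to_numpy(float))
        return coords


def read_pdb_ensemble(path: str) -> StructureEnsemble:
    """Read a multi-MODEL PDB file (first chain of each model) via gemmi."""
    import gemmi

    st = gemmi.read_structure(str(path))
    models = []
    for model in st:
        rows = []
        chain = model[0]
        for res in chain:
            for atom in res:
                rows.append({
                    "residue": res.seqid.num, "resname": res.name,
                    "atom": atom.name,
                    "x": atom.pos.x, "y": atom.pos.y, "z": atom.pos.z,
                })
        models.append(pd.DataFrame(rows))
    return StructureEnsemble(models=models)


@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray        # 3x3, det = +1
    translation: np.ndarray     # applied after rotation
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(ref: np.ndarray, mov: np.ndarray) -> Superposition:
    """Optimal proper rigid superposition of ``mov`` onto ``ref``.

    Reflections are rejected by the determinant correction; degenerate
    (collinear or < 3 point) sets raise.
    """
    ref = np.asarray(ref, float)
    mov = np.asarray(mov, float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate sets must both be N x 3")
    n = len(ref)
    if n < 3:
        raise ValueError("need at least 3 points")
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-9) < 2 or \
            np.linalg.matrix_rank(mov_c, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) coordinate set")
    h = mov_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = ref.mean(axis=0) - mov.mean(axis=0) @ rot.T
    moved = mov @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


@dataclass
class EnsembleRmsd:
    mean_coords: np.ndarray
    mean_rmsd: float            # average over models of RMSD to the mean
    per_model: np.ndarray
    n_iterations: int

    def summary(self) -> str:
        return (
            f"ensemble of {len(self.per_model)} models: "
            f"mean RMSD to mean structure {self.mean_rmsd:.3f} A "
            f"(converged in {self.n_iterations} iterations)"
        )


def ensemble_rmsd(ens: StructureEnsemble,
                  residue_range: Optional[tuple[int, int]] = None,
                  atoms: str = "backbone",
                  tol: float = 1e-6, max_iter: int = 100) -> EnsembleRmsd:
    """Iterative superposition onto the evolving mean structure.

    All models are superposed on the current mean, the mean is recomputed,
    and the cycle repeats until the average RMSD changes by < ``tol`` A.
    """
    coords = ens.select(residue_range=residue_range, atoms=atoms)
    if len(coords) < 2:
        raise ValueError("need at least 2 models")
    arr = [c.copy() for c in coords]
    mean = arr[0].copy()
    prev = math.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        sups = [kabsch(mean, c) for c in arr]
        arr = [s.apply(c) for s, c in zip(sups, arr)]
        mean = np.mean(arr, axis=0)
        rmsds = np.array([
            math.sqrt(np.mean(np.sum((c - mean) ** 2, axis=1))) for c in arr])
        cur = float(rmsds.mean())
        if abs(prev - cur) < tol:
            break
        prev = cur
    return EnsembleRmsd(mean_coords=mean, mean_rmsd=cur,
                        per_model=rmsds, n_iterations=n_iter)


def _dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def dihedrals(model: pd.DataFrame, residue: int
              ) -> tuple[Optional[float], Optional[float]]:
    """Backbone (phi, psi) for one residue; None at chain termini or when
    flanking atoms are missing."""

    def atom(res: int, name: str) -> Optional[np.ndarray]:
        sub = model[(model["residue"] == res) & (model["atom"] == name)]
        if len(sub) != 1:
            return None
        return sub[["x", "y", "z"]].to_numpy(float)[0]

    c_prev = atom(residue - 1, "C")
    n = atom(residue, "N")
    ca = atom(residue, "CA")
    c = atom(residue, "C")
    n_next = atom(residue + 1, "N")
    phi = None
    psi = None
    if all(a is not None for a in (c_prev, n, ca, c)):
        phi = _dihedral(c_prev, n, ca, c)
    if all(a is not None for a in (n, ca, c, n_next)):
        psi = _dihedral(n, ca, c, n_next)
    return phi, psi


def rama_label(phi: Optional[float], psi: Optional[float]) -> str:
    """Simplified Ramachandran region label in {'favored-like', 'other'}.

    Uses generous rectangular windows around the alpha and beta basins; it
    is a descriptive aid, not a PROCHECK replacement.
    """
    if phi is None or psi is None:
        return "other"
    alpha = -160 <= phi <= -20 and -120 <= psi <= 45
    beta = -180 <= phi <= -45 and (90 <= psi <= 180 or -180 <= psi <= -150)
    return "favored-like" if alpha or beta else "other"
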