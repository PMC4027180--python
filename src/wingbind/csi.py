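"""Secondary-structure calling from backbone chemical shifts (CSI).

Deviations of Calpha and Halpha shifts from residue-specific random-coil
values carry a robust secondary-structure signal: helices shift Calpha
downfield (positive delta) and Halpha upfield (negative delta); strands do
the opposite.  Thresholding these deltas gives a per-residue index in
{-1, 0, +1}, and consensus over short windows plus minimum segment lengths
yields helix/strand segments and a Greek-letter topology string.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._random_coil import RANDOM_COIL, random_coil_table

# CSI thresholds (ppm) and minimum segment lengths, following the classic
# chemical-shift-index convention.
CA_THRESHOLD = 0.7
HA_THRESHOLD = 0.1
MIN_HELIX = 4
MIN_STRAND = 3

SHIFT_WINDOWS = {"ca": (40.0, 75.0), "ha": (2.0, 7.0),
                 "n": (100.0, 135.0), "hn": (5.0, 12.0)}


def validate_shift_table(shifts: pd.DataFrame) -> pd.DataFrame:
    """Check a shift table (columns: residue, aa, and any of ca/ha/n/hn).

    Residue indices must be strictly increasing; shifts outside loose
    physical windows are flagged in a boolean ``flagged`` column rather than
    rejected.
    """
    required = {"residue", "aa"}
    if not required <= set(shifts.columns):
        raise ValueError("shift table needs 'residue' and 'aa' columns")
    res = shifts["residue"].to_numpy()
    if len(res) and not np.all(np.diff(res) > 0):
        raise ValueError("residue indices must be strictly increasing")
    out = shifts.copy()
    flagged = np.zeros(len(out), dtype=bool)
    for col, (lo, hi) in SHIFT_WINDOWS.items():
        if col in out.columns:
            vals = out[col].to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                flagged |= (vals < lo) | (vals > hi)
    out["flagged"] = flagged
    return out


def compute_deltas(shifts: pd.DataFrame) -> pd.DataFrame:
    """Secondary chemical shifts Delta = observed - random_coil(aa).

    Returns a DataFrame with residue, aa, d_ca, d_ha; missing shifts
    propagate as NaN.
    """
    shifts = validate_shift_table(shifts)
    unknown = set(shifts["aa"]) - set(RANDOM_COIL)
    if unknown:
        raise ValueError(f"unknown amino-acid codes: {sorted(unknown)}")
    rc = random_coil_table()
    rc_ca = shifts["aa"].map(rc["ca"]).to_numpy()
    rc_ha = shifts["aa"].map(rc["ha"]).to_numpy()
    out = shifts[["residue", "aa"]].copy()
    out["d_ca"] = (shifts["ca"].to_numpy(dtype=float) - rc_ca
                   if "ca" in shifts.columns else np.nan)
    out["d_ha"] = (shifts["ha"].to_numpy(dtype=float) - rc_ha
                   if "ha" in shifts.columns else np.nan)
    return out


def csi_index(deltas: pd.DataFrame) -> pd.DataFrame:
    """Per-residue CSI per nucleus: values in {-1, 0, +1}.

    Calpha: +1 above +0.7 ppm, -1 below -0.7 ppm.  Halpha: -1 below
    -0.1 ppm, +1 above +0.1 ppm.  NaN deltas index as 0.
    """
    d_ca = deltas["d_ca"].to_numpy(dtype=float)
    d_ha = deltas["d_ha"].to_numpy(dtype=float)
    idx_ca = np.zeros(len(deltas), dtype=int)
    idx_ca[d_ca > CA_THRESHOLD] = 1
    idx_ca[d_ca < -CA_THRESHOLD] = -1
    idx_ha = np.zeros(len(deltas), dtype=int)
    idx_ha[d_ha > HA_THRESHOLD] = 1
    idx_ha[d_ha < -HA_THRESHOLD] = -1
    out = deltas[["residue", "aa"]].copy()
    out["idx_ca"] = idx_ca
    out["idx_ha"] = idx_ha
    return out


@dataclass(frozen=True)
class SecondaryStructure:
    """Per-residue labels plus segments and a topology string."""

    residues: np.ndarray          # residue numbers
    labels: np.ndarray            # 'H' / 'E' / 'C' per residue
    segments: tuple               # ((label, start_res, end_res), ...)
    topology: str                 # e.g. "αβααββα"

    @property
    def n_helices(self) -> int:
        return sum(1 for s in self.segments if s[0] == "H")

    @property
    def n_strands(self) -> int:
        return sum(1 for s in self.segments if s[0] == "E")


def _raw_pattern(idx_ca: np.ndarray, idx_ha: np.ndarray) -> np.ndarray:
    raw = np.full(len(idx_ca), "C", dtype="<U1")
    raw[(idx_ca == 1) & (idx_ha == -1)] = "H"
    raw[(idx_ca == -1) & (idx_ha == 1)] = "E"
    return raw


def call_secondary_structure(indices: pd.DataFrame, mode: str = "window",
                             min_helix: int = MIN_HELIX,
                             min_strand: int = MIN_STRAND) -> SecondaryStructure:
    """Consensus secondary-structure calls from per-nucleus CSI indices.

    mode='window' (default): a residue is helix/strand if that pattern holds
    for the majority of a 3-residue window centered on it (ties -> coil).
    mode='strict': per-residue AND of the two nuclei with no smoothing.
    Helix runs shorter than ``min_helix`` and strand runs shorter than
    ``min_strand`` revert to coil.
    """
    if len(indices) < 1:
        raise ValueError("need at least one indexed residue")
    residues = indices["residue"].to_numpy()
    raw = _raw_pattern(indices["idx_ca"].to_numpy(), indices["idx_ha"].to_numpy())

    if mode == "strict":
        labels = raw.copy()
    elif mode == "window":
        labels = np.full(len(raw), "C", dtype="<U1")
        n = len(raw)
        for i in range(n):
            window = raw[max(0, i - 1):min(n, i + 2)]
            for lab in ("H", "E"):
                if np.sum(window == lab) * 2 > len(window):
                    labels[i] = lab
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # enforce minimum run lengths
    segments = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i] and \
                (j == i or residues[j] == residues[j - 1] + 1):
            j += 1
        lab, run = labels[i], j - i
        if lab == "H" and run < min_helix:
            labels[i:j] = "C"
        elif lab == "E" and run < min_strand:
            labels[i:j] = "C"
        i = j

    segments = []
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i] and \
                (j == i or residues[j] == residues[j - 1] + 1):
            j += 1
        if labels[i] in ("H", "E"):
            segments.append((labels[i], int(residues[i]), int(residues[j - 1])))
        i = j

    topology = "".join("α" if s[0] == "H" else "β" for s in segments)
    return SecondaryStructure(residues=residues, labels=labels,
                              segments=tuple(segments), topology=topology)


def analyze_shifts(shifts: pd.DataFrame, mode: str = "window") -> SecondaryStructure:
    """Convenience: shift table -> deltas -> indices -> structure call."""
    return call_secondary_structure(csi_index(compute_deltas(shifts)), mode=mode)
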