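"""Chemical shift perturbation (CSP) mapping of a binding interface.

Amide cross-peaks of a 15N-labeled protein move and/or lose intensity when a
ligand binds.  The combined amide perturbation

    dHNav = sqrt[ (dH^2 + (dN/5)^2) / 2 ]

down-weights nitrogen by its larger shift dispersion.  Residues whose
combined shift exceeds the ensemble mean plus one standard deviation, whose
relative intensity loss exceeds the mean loss plus one standard deviation,
or whose bound-state peak disappears entirely (broadened away) are assigned
to the interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

PEAK_COLUMNS = ["residue", "aa", "h_ppm", "n_ppm", "intensity"]

CLASS_NONE = "none"
CLASS_ABOVE_MEAN = "above_mean"
CLASS_ABOVE_MEAN_SD = "above_mean_plus_sd"
FLAG_INTENSITY = "intensity_flagged"


def validate_peaklist(peaks: pd.DataFrame) -> pd.DataFrame:
    missing = set(PEAK_COLUMNS) - set(peaks.columns)
    if missing:
        raise ValueError(f"peak list missing columns {sorted(missing)}")
    if peaks["residue"].duplicated().any():
        raise ValueError("duplicate residue index in peak list")
    if (peaks["intensity"] <= 0).any():
        raise ValueError("intensities must be positive")
    return peaks


@dataclass
class MatchedPeaks:
    """Free/bound peaks paired by residue index."""

    pairs: pd.DataFrame         # residue, aa, free/bound shifts + intensities
    lost: frozenset             # residues present free-only (broadened away)
    gained: frozenset           # residues present bound-only


def match_peaks(free: pd.DataFrame, bound: pd.DataFrame) -> MatchedPeaks:
    """Pair two assigned peak lists by residue index."""
    free = validate_peaklist(free)
    bound = validate_peaklist(bound)
    merged = free.merge(bound, on="residue", suffixes=("_free", "_bound"),
                        how="inner").sort_values("residue", ignore_index=True)
    merged = merged.rename(columns={"aa_free": "aa"}).drop(
        columns=["aa_bound"], errors="ignore")
    lost = frozenset(set(free["residue"]) - set(bound["residue"]))
    gained = frozenset(set(bound["residue"]) - set(free["residue"]))
    return MatchedPeaks(pairs=merged, lost=lost, gained=gained)


def combined_csp(d_h, d_n):
    """Combined amide shift change, ppm: sqrt[(dH^2 + (dN/5)^2)/2]."""
    d_h = np.asarray(d_h, dtype=float)
    d_n = np.asarray(d_n, dtype=float)
    return np.sqrt((d_h ** 2 + (d_n / 5.0) ** 2) / 2.0)


def compute_profile(matched: MatchedPeaks) -> pd.DataFrame:
    """Per-residue CSP profile: d_h, d_n, csp, intensity ratio bound/free."""
    p = matched.pairs
    out = p[["residue", "aa"]].copy()
    out["d_h"] = p["h_ppm_bound"] - p["h_ppm_free"]
    out["d_n"] = p["n_ppm_bound"] - p["n_ppm_free"]
    out["csp"] = combined_csp(out["d_h"], out["d_n"])
    out["intensity_ratio"] = p["intensity_bound"] / p["intensity_free"]
    return out


@dataclass
class InterfaceClassification:
    """Interface call from a CSP profile plus lost peaks."""

    profile: pd.DataFrame       # adds 'class' and 'intensity_flagged' columns
    csp_mean: float
    csp_sd: float
    reduction_mean: float
    reduction_sd: float
    interface: frozenset        # residues called as the binding interface
    lost: frozenset
    degenerate: bool = False


def classify_interface(profile: pd.DataFrame,
                       lost: frozenset = frozenset(),
                       min_residues: int = 5) -> InterfaceClassification:
    """Classify residues against global mean / mean+SD thresholds.

    The interface set is the union of residues with csp > mean + SD, residues
    whose relative intensity reduction (1 - I_bound/I_free) exceeds the mean
    reduction plus one SD, and peaks lost on binding.  Statistics are taken
    over all matched residues with no trimming.
    """
    if len(profile) < min_residues:
        raise ValueError(f"need at least {min_residues} matched residues")
    csp = profile["csp"].to_numpy(dtype=float)
    mean, sd = float(np.mean(csp)), float(np.std(csp, ddof=0))
    # identical shifts differ only by float rounding; compare SD to the mean
    degenerate = sd <= 1e-9 * max(abs(mean), 1e-30)
    if degenerate:
        warnings.warn("all combined shifts identical; SD threshold degenerate,"
                      " using mean-only classes", stacklevel=2)

    classes = np.full(len(profile), CLASS_NONE, dtype=object)
    classes[csp > mean] = CLASS_ABOVE_MEAN
    if not degenerate:
        classes[csp > mean + sd] = CLASS_ABOVE_MEAN_SD

    reduction = 1.0 - profile["intensity_ratio"].to_numpy(dtype=float)
    red_mean, red_sd = float(np.mean(reduction)), float(np.std(reduction, ddof=0))
    red_degenerate = red_sd <= 1e-9 * max(abs(red_mean), 1e-30)
    flagged = np.zeros(len(profile), dtype=bool) if red_degenerate else \
        reduction > red_mean + red_sd

    out = profile.copy()
    out["class"] = classes
    out["intensity_flagged"] = flagged

    residues = profile["residue"].to_numpy()
    interface = set(residues[classes == CLASS_ABOVE_MEAN_SD])
    interface |= set(residues[flagged])
    interface |= set(lost)
    return InterfaceClassification(
        profile=out, csp_mean=mean, csp_sd=sd,
        reduction_mean=red_mean, reduction_sd=red_sd,
        interface=frozenset(int(r) for r in interface),
        lost=frozenset(int(r) for r in lost), degenerate=degenerate,
    )


def analyze_pair(free: pd.DataFrame, bound: pd.DataFrame) -> InterfaceClassification:
    """Convenience: free/bound peak lists -> interface classification."""
    matched = match_peaks(free, bound)
    return classify_interface(compute_profile(matched), lost=matched.lost)
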