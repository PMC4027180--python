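"""Synthetic data generators for every input type of the analysis pipeline.

Each generator emits data with exactly the statistical structure its partner
analysis assumes — random-coil-referenced shift tables with helix/strand
offsets, free/bound amide peak lists with a planted interface, rigid
isotropic-rotor relaxation decays, sequential-model ITC thermograms,
two-segment titration curves, paired melting sigmoids, Hill-shaped EMSA
binding curves, and promoter sequences with two planted TTAA-N7-TTAA
operators.  Defaults reproduce the study conditions of the system the
package models: tau_c = 8.4 ns at 600 MHz, site-1 Kd = 40 nM with
dH1 = +10 kcal/mol, a 2:1 protein:DNA breakpoint, a 10 degC duplex
stabilization, and a Hill coefficient of 4.5.

Determinism: a single integer seed in the spec governs independent
per-data-type sub-streams, so identical (spec, seed) gives bit-identical
outputs across generators and generator order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import itcseq, relaxhydro
from ._random_coil import RANDOM_COIL
from .motifs import DnaSequence
from .structqc import StructureEnsemble
from .titrate import hill_curve

# secondary chemical-shift offsets (ppm) added to random-coil values
HELIX_OFFSET = {"ca": +2.5, "ha": -0.25}
STRAND_OFFSET = {"ca": -2.0, "ha": +0.35}

#: protein concentrations (uM) used in the EMSA titration
EMSA_CONCENTRATIONS_UM = (3.2, 6.4, 9.6, 12.8, 16.0, 19.2, 22.4, 25.8, 32.4)

DEFAULT_TOPOLOGY = (
    ("H", 8, 18), ("E", 21, 23), ("H", 24, 31), ("H", 35, 48),
    ("E", 51, 58), ("E", 61, 68), ("H", 71, 76),
)

#: interface residues perturbed on DNA binding (recognition helix + wing)
DEFAULT_INTERFACE = frozenset({
    9, 10, 11, 24, 25, 26, 28, 29, 33, 34, 35, 44, 46, 47,
    51, 52, 53, 55, 56, 57, 58, 60, 62, 63,
})

DEFAULT_NOISE = {
    "shift_ca": 0.10,   # ppm
    "shift_ha": 0.02,   # ppm
    "hsqc_h": 0.003,    # ppm positional jitter
    "hsqc_n": 0.015,    # ppm
    "hsqc_intensity": 0.05,   # fractional
    "relax": 0.03,      # fractional intensity noise
    "itc": 0.02,        # fraction of the largest |heat|
    "titration": 0.01,  # fraction of signal range
    "melt": 0.01,       # fraction of absorbance range
    "emsa": 0.02,       # absolute on fraction bound
    "spectrum": 0.005,  # fraction of peak intensity
    "ensemble": 0.30,   # A coordinate jitter
}

_STREAMS = {
    "sequence": 1, "shifts": 2, "hsqc": 3, "relax": 4, "itc": 5,
    "titration": 6, "melt": 7, "emsa": 8, "promoter": 9, "ensemble": 10,
    "spectrum": 11,
}

_SITE_A_CORE = "TTAATAAAGTGTTAA"          # 15 nt, TTAA-N7-TTAA
_SITE_A_FLANK5 = "AGTA"                    # direct-repeat context
_SITE_A_FLANK3 = "T"


@dataclass(frozen=True)
class SynthSpec:
    """Ground-truth parameters shared by all generators."""

    seed: int = 0
    n_residues: int = 76
    topology: tuple = DEFAULT_TOPOLOGY
    interface_residues: frozenset = DEFAULT_INTERFACE
    flexible_termini: frozenset = frozenset(range(1, 6))
    tau_c_ns: float = 8.4
    field_1h_mhz: float = 600.0
    kd1_m: float = 40e-9
    kd2_m: float = 5e-6
    dh1_kcal: float = 10.0
    dh2_kcal: float = -5.0
    stoichiometry_break: float = 2.0
    tm_free_c: float = 55.0
    tm_bound_c: float = 65.0
    hill_n: float = 4.5
    hill_k_um: float = 12.0
    lambda_max_free_nm: float = 355.0
    lambda_max_bound_nm: float = 350.0
    perturb_scale_ppm: float = 0.2   # combined CSP planted at the interface
    noise: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))

    def __post_init__(self):
        if self.n_residues < 1:
            raise ValueError("n_residues must be positive")
        prev_end = 0
        for label, start, end in self.topology:
            if label not in ("H", "E", "C"):
                raise ValueError(f"bad topology label {label!r}")
            if start <= prev_end or end < start or end > self.n_residues:
                raise ValueError("topology segments must be ordered, "
                                 "non-overlapping and within the chain")
            prev_end = end
        if not set(self.interface_residues) <= set(range(1, self.n_residues + 1)):
            raise ValueError("interface residues outside [1, n_residues]")
        for name in ("tau_c_ns", "field_1h_mhz", "kd1_m", "kd2_m",
                     "stoichiometry_break", "tm_free_c", "tm_bound_c",
                     "hill_n", "hill_k_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if any(v < 0 for v in self.noise.values()):
            raise ValueError("noise levels must be non-negative")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def noiseless(self) -> "SynthSpec":
        return replace(self, noise={k: 0.0 for k in self.noise})

    def ground_truth(self) -> dict:
        return {
            "tau_c_ns": self.tau_c_ns, "kd1_m": self.kd1_m,
            "kd2_m": self.kd2_m, "dh1_kcal": self.dh1_kcal,
            "dh2_kcal": self.dh2_kcal,
            "stoichiometry_break": self.stoichiometry_break,
            "delta_tm_c": self.tm_bound_c - self.tm_free_c,
            "hill_n": self.hill_n, "hill_k_um": self.hill_k_um,
            "interface_residues": sorted(self.interface_residues),
            "topology": ["".join(map(str, seg)) for seg in self.topology],
        }


def residue_labels(spec: SynthSpec) -> np.ndarray:
    """Per-residue H/E/C labels implied by the topology segments."""
    labels = np.full(spec.n_residues, "C", dtype="<U1")
    for label, start, end in spec.topology:
        labels[start - 1:end] = label
    return labels


def gen_sequence(spec: SynthSpec) -> str:
    """Deterministic random amino-acid sequence (prolines excluded so every
    residue carries an amide peak)."""
    rng = spec.rng("sequence")
    alphabet = np.array(sorted(set(RANDOM_COIL) - {"P"}))
    return "".join(rng.choice(alphabet, size=spec.n_residues))


# ------------------------------------------------------------- shift tables

def gen_shift_table(spec: SynthSpec) -> pd.DataFrame:
    """Backbone shift table with helix/strand secondary-shift offsets."""
    seq = gen_sequence(spec)
    labels = residue_labels(spec)
    rng = spec.rng("shifts")
    rows = []
    for i, (aa, lab) in enumerate(zip(seq, labels), 1):
        rc = dict(zip(("ca", "ha", "n", "hn"), RANDOM_COIL[aa]))
        off = HELIX_OFFSET if lab == "H" else STRAND_OFFSET if lab == "E" \
            else {"ca": 0.0, "ha": 0.0}
        rows.append({
            "residue": i, "aa": aa,
            "ca": rc["ca"] + off["ca"] + rng.normal(0, spec.noise["shift_ca"]),
            "ha": rc["ha"] + off["ha"] + rng.normal(0, spec.noise["shift_ha"]),
            "n": rc["n"] + rng.normal(0, 0.5),
            "hn": rc["hn"] + rng.normal(0, 0.05),
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------- HSQC pairs

def gen_hsqc_pair(spec: SynthSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Free/bound amide peak lists with the interface displaced/attenuated.

    Interface residues move by a combined amide shift equal to
    ``perturb_scale_ppm`` (random direction in the weighted H/N plane) and
    lose intensity; all other residues stay put up to the noise level.
    """
    seq = gen_sequence(spec)
    rng = spec.rng("hsqc")
    n = spec.n_residues
    free_rows, bound_rows = [], []
    for i, aa in enumerate(seq, 1):
        rc = dict(zip(("ca", "ha", "n", "hn"), RANDOM_COIL[aa]))
        h = rc["hn"] + rng.normal(0, 0.25)
        nn = rc["n"] + rng.normal(0, 2.0)
        inten = 100.0 * (1.0 + rng.normal(0, 0.02))
        free_rows.append({"residue": i, "aa": aa, "h_ppm": h, "n_ppm": nn,
                          "intensity": inten})
        if i in spec.interface_residues:
            theta = rng.uniform(0, 2 * np.pi)
            c = spec.perturb_scale_ppm
            dh = c * np.sqrt(2.0) * np.cos(theta)
            dn = 5.0 * c * np.sqrt(2.0) * np.sin(theta)
            ratio = 0.45
        else:
            dh = dn = 0.0
            ratio = 1.0
        bound_rows.append({
            "residue": i, "aa": aa,
            "h_ppm": h + dh + rng.normal(0, spec.noise["hsqc_h"]),
            "n_ppm": nn + dn + rng.normal(0, spec.noise["hsqc_n"]),
            "intensity": inten * ratio *
            (1.0 + rng.normal(0, spec.noise["hsqc_intensity"])),
        })
    return pd.DataFrame(free_rows), pd.DataFrame(bound_rows)


# ---------------------------------------------------------------- relaxation

R1_DELAYS_S = (0.01, 0.05, 0.10, 0.20, 0.35, 0.50, 0.75, 1.00)
R2_DELAYS_S = (0.004, 0.010, 0.017, 0.030, 0.050, 0.070, 0.100, 0.130)


def gen_relaxation_series(
    spec: SynthSpec,
    r1_delays: Sequence[float] = R1_DELAYS_S,
    r2_delays: Sequence[float] = R2_DELAYS_S,
) -> tuple[relaxhydro.RelaxationSeries, relaxhydro.RelaxationSeries]:
    """R1 and R2 decay series for a rigid rotor at the spec's tau_c/field.

    Residues in ``flexible_termini`` tumble with an apparent tau_c of a
    quarter of the global value, emulating fast local motion of the tails.
    """
    for name, delays in (("R1", r1_delays), ("R2", r2_delays)):
        if len(set(delays)) < 4:
            raise ValueError(f"{name} delay list must contain at least 4 "
                             "distinct delays (degenerate design)")
    rng = spec.rng("relax")
    r1_rigid, r2_rigid = relaxhydro.predict_rates(spec.tau_c_ns,
                                                  spec.field_1h_mhz)
    r1_flex, r2_flex = relaxhydro.predict_rates(0.25 * spec.tau_c_ns,
                                                spec.field_1h_mhz)
    frames = {}
    for name, delays, rigid, flex in (
            ("R1", r1_delays, r1_rigid, r1_flex),
            ("R2", r2_delays, r2_rigid, r2_flex)):
        rows = []
        for res in range(1, spec.n_residues + 1):
            rate = flex if res in spec.flexible_termini else rigid
            for t in delays:
                ideal = 100.0 * np.exp(-rate * t)
                rows.append({
                    "residue": res, "delay_s": t,
                    "intensity": ideal *
                    (1.0 + rng.normal(0, spec.noise["relax"])),
                })
        frames[name] = relaxhydro.RelaxationSeries(
            experiment=name, field_1h_mhz=spec.field_1h_mhz,
            data=pd.DataFrame(rows))
    return frames["R1"], frames["R2"]


# ----------------------------------------------------------------------- ITC

def gen_itc_thermogram(spec: SynthSpec,
                       cell_conc_m: float = 10e-6,
                       syringe_conc_m: float = 100e-6,
                       n_injections: int = 20,
                       injection_vol_l: float = 5e-6,
                       cell_volume_l: float = 200e-6,
                       temperature_k: float = 295.15) -> itcseq.Thermogram:
    """Sequential-model thermogram at the spec's Kd/dH parameters.

    With dH1 > 0 > dH2 and Kd1 << Kd2 the heats are endothermic for early
    injections and exothermic later.
    """
    if min(cell_conc_m, syringe_conc_m) < 0 or n_injections < 10:
        raise ValueError("need non-negative concentrations, >= 10 injections")
    design = itcseq.Thermogram(
        cell_volume_l=cell_volume_l, cell_conc_m=cell_conc_m,
        syringe_conc_m=syringe_conc_m,
        injection_volumes_l=np.full(n_injections, injection_vol_l),
        temperature_k=temperature_k)
    params = itcseq.SeqBindParams(k1=1.0 / spec.kd1_m, k2=1.0 / spec.kd2_m,
                                  dh1=spec.dh1_kcal, dh2=spec.dh2_kcal)
    heats = itcseq.simulate_heats(params, design)
    if spec.noise["itc"] > 0:
        # fractional noise, consistent with the other generators
        heats = heats * (1.0 + spec.rng("itc").normal(
            0, spec.noise["itc"], size=len(heats)))
    design.heats_cal = heats
    return design


# ------------------------------------------------------------------- curves

def gen_titration_curve(spec: SynthSpec, n_points: int = 12,
                        max_ratio: float = 4.0,
                        slope_before: float = 1.0,
                        slope_after: float = 0.1) -> pd.DataFrame:
    """Two-segment titration signal breaking at ``stoichiometry_break``."""
    ratios = np.linspace(0.0, max_ratio, n_points)
    x0 = spec.stoichiometry_break
    signal = slope_before * ratios + \
        (slope_after - slope_before) * np.maximum(ratios - x0, 0.0)
    sigma = spec.noise["titration"] * np.ptp(signal)
    if sigma > 0:
        signal = signal + spec.rng("titration").normal(0, sigma, n_points)
    return pd.DataFrame({"ratio": ratios, "signal": signal})


def gen_melting_pair(spec: SynthSpec, t_min: float = 20.0,
                     t_max: float = 80.0, step: float = 0.5,
                     width: float = 2.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired free/bound A260 melting sigmoids centered at tm_free/tm_bound."""
    temps = np.arange(t_min, t_max + step / 2, step)
    rng = spec.rng("melt")
    out = []
    for tm in (spec.tm_free_c, spec.tm_bound_c):
        a260 = 0.55 + 0.45 / (1.0 + np.exp(-(temps - tm) / width))
        sigma = spec.noise["melt"] * np.ptp(a260)
        if sigma > 0:
            a260 = a260 + rng.normal(0, sigma, len(temps))
        out.append(pd.DataFrame({"temperature_c": temps, "a260": a260}))
    return out[0], out[1]


def gen_emission_pair(spec: SynthSpec, wl_min: float = 310.0,
                      wl_max: float = 420.0, step: float = 1.0,
                      width_nm: float = 28.0, quench: float = 0.6
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Free/bound tryptophan emission spectra.

    Gaussian bands centered at ``lambda_max_free_nm``/``lambda_max_bound_nm``;
    the bound spectrum is quenched to ``quench`` of the free amplitude,
    emulating fluorescence loss on complex formation.
    """
    wl = np.arange(wl_min, wl_max + step / 2, step)
    rng = spec.rng("spectrum")
    out = []
    for center, amp in ((spec.lambda_max_free_nm, 1.0),
                        (spec.lambda_max_bound_nm, quench)):
        inten = amp * np.exp(-0.5 * ((wl - center) / width_nm) ** 2)
        sigma = spec.noise["spectrum"] * amp
        if sigma > 0:
            inten = inten + rng.normal(0, sigma, len(wl))
        out.append(pd.DataFrame({"wavelength_nm": wl, "intensity": inten}))
    return out[0], out[1]


def gen_emsa_curve(spec: SynthSpec,
                   concentrations_um: Sequence[float] = EMSA_CONCENTRATIONS_UM
                   ) -> pd.DataFrame:
    """Hill-shaped fraction-bound data at the EMSA protein concentrations."""
    conc = np.asarray(concentrations_um, float)
    frac = hill_curve(conc, spec.hill_n, spec.hill_k_um)
    sigma = spec.noise["emsa"]
    if sigma > 0:
        frac = np.clip(frac + spec.rng("emsa").normal(0, sigma, len(conc)),
                       0.0, 1.0)
    return pd.DataFrame({"conc_um": conc, "fraction_bound": frac})


# ----------------------------------------------------------------- promoter

def _tss_to_index(pos: int, tss_offset: int) -> int:
    """1-based sequence index of a TSS-relative coordinate (no zero)."""
    idx = pos - tss_offset + 1
    if tss_offset < 0 < pos:
        idx -= 1
    return idx


def gen_promoter(spec: SynthSpec, start_tss: int = -120, end_tss: int = 20,
                 with_sites: bool = True) -> tuple[DnaSequence, dict]:
    """Random promoter with two planted TTAA-N7-TTAA operators.

    Site A (with its direct-repeat context) occupies TSS coordinates -92..-78
    and site B -28..-14; the background is screened free of any other TTAA
    so the only paired sites are the planted ones.  With ``with_sites=False``
    a screened background with no operator at all is returned.
    """
    rng = spec.rng("promoter")
    length = end_tss - start_tss + (0 if start_tss > 0 or end_tss < 0 else -1) + 1
    bases = list(rng.choice(list("ACGT"), size=length))

    planted = {}
    protected: list[tuple[int, int]] = []   # 0-based [start, end) windows
    allowed_box_starts: set[int] = set()    # 0-based TTAA starts to keep
    if with_sites:
        site_b_core = "TTAA" + "".join(rng.choice(list("ACG"), size=7)) + "TTAA"
        a_start = _tss_to_index(-92, start_tss)
        b_start = _tss_to_index(-28, start_tss)
        full_a = _SITE_A_FLANK5 + _SITE_A_CORE + _SITE_A_FLANK3
        fa0 = a_start - 1 - len(_SITE_A_FLANK5)
        bases[fa0:fa0 + len(full_a)] = list(full_a)
        bases[b_start - 1:b_start - 1 + len(site_b_core)] = list(site_b_core)
        planted = {
            "site_a": {"tss_span": (-92, -78),
                       "index_span": (a_start, a_start + 14)},
            "site_b": {"tss_span": (-28, -14),
                       "index_span": (b_start, b_start + 14)},
        }
        protected = [(fa0, fa0 + len(full_a)),
                     (b_start - 1, b_start - 1 + 15)]
        allowed_box_starts = {a_start - 1, a_start + 10,
                              b_start - 1, b_start + 10}

    # Scrub every non-planted TTAA: mutate one unprotected base of each
    # occurrence to C/G (which can never rejoin a TTAA), until clean.
    for _ in range(100):
        text = "".join(bases)
        extraneous = []
        start = text.find("TTAA")
        while start != -1:
            if start not in allowed_box_starts:
                extraneous.append(start)
            start = text.find("TTAA", start + 1)
        if not extraneous:
            break
        for pos in extraneous:
            for k in range(4):
                inside = any(lo <= pos + k < hi for lo, hi in protected)
                if not inside:
                    bases[pos + k] = str(rng.choice(list("CG")))
                    break

    seq = DnaSequence(name="synthetic_promoter", bases="".join(bases),
                      tss_offset=start_tss)
    return seq, planted


# ----------------------------------------------------------------- ensembles

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.5}


def _place_atom(a, b, c, bond: float, angle_deg: float,
                torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of the next atom."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.sin(angle) * np.cos(torsion),
                  -bond * np.sin(angle) * np.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(phi_psi: Sequence[tuple[float, float]]) -> pd.DataFrame:
    """Ideal peptide backbone (N, CA, C, O per residue) from phi/psi lists.

    phi of the first residue and psi of the last are ignored (undefined at
    chain termini); omega is fixed trans (180 deg).
    """
    n_res = len(phi_psi)
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    coords = {}
    coords[(1, "N")] = np.array([0.0, 0.0, 0.0])
    coords[(1, "CA")] = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = np.radians(_ANGLE["N-CA-C"])
    coords[(1, "C")] = coords[(1, "CA")] + _BOND["CA-C"] * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        phi_next, _ = phi_psi[i]
        _, psi = phi_psi[i - 1]
        coords[(i + 1, "N")] = _place_atom(
            coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")],
            _BOND["C-N"], _ANGLE["CA-C-N"], psi)
        coords[(i + 1, "CA")] = _place_atom(
            coords[(i, "CA")], coords[(i, "C")], coords[(i + 1, "N")],
            _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)
        coords[(i + 1, "C")] = _place_atom(
            coords[(i, "C")], coords[(i + 1, "N")], coords[(i + 1, "CA")],
            _BOND["CA-C"], _ANGLE["N-CA-C"], phi_next)
    for i in range(1, n_res):
        _, psi = phi_psi[i - 1]
        coords[(i, "O")] = _place_atom(
            coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")],
            _BOND["C-O"], _ANGLE["CA-C-O"], psi - 180.0)
    # last O: use psi = 180 by convention
    coords[(n_res, "O")] = _place_atom(
        coords[(n_res, "N")], coords[(n_res, "CA")], coords[(n_res, "C")],
        _BOND["C-O"], _ANGLE["CA-C-O"], 0.0)
    rows = []
    for (res, atom), xyz in sorted(coords.items()):
        rows.append({"residue": res, "resname": "ALA", "atom": atom,
                     "x": xyz[0], "y": xyz[1], "z": xyz[2]})
    return pd.DataFrame(rows)


def gen_ensemble(spec: SynthSpec, n_models: int = 10, n_residues: int = 20,
                 phi: float = -57.0, psi: float = -47.0) -> StructureEnsemble:
    """Synthetic NMR-style ensemble: jittered, randomly oriented copies of an
    ideal helical backbone."""
    rng = spec.rng("ensemble")
    base = build_backbone([(phi, psi)] * n_residues)
    xyz0 = base[["x", "y", "z"]].to_numpy(float)
    sigma = spec.noise["ensemble"]
    models = []
    for _ in range(n_models):
        xyz = xyz0 + rng.normal(0, sigma, xyz0.shape) if sigma > 0 else xyz0.copy()
        # random proper rotation + translation
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ])
        xyz = xyz @ rot.T + rng.normal(0, 5.0, 3)
        m = base.copy()
        m[["x", "y", "z"]] = xyz
        models.append(m)
    return StructureEnsemble(models=models)


# ------------------------------------------------------------------- bundle

def write_bundle(spec: SynthSpec, outdir) -> dict:
    """Write every synthetic data type plus a ground-truth JSON sidecar."""
    from . import nmrstar

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    shifts = gen_shift_table(spec)
    shifts.to_csv(outdir / "shifts.csv", index=False)
    nmrstar.write_shift_loop(shifts, outdir / "shifts.str")

    free, bound = gen_hsqc_pair(spec)
    free.to_csv(outdir / "hsqc_free.csv", index=False)
    bound.to_csv(outdir / "hsqc_bound.csv", index=False)

    r1, r2 = gen_relaxation_series(spec)
    r1.data.to_csv(outdir / "relax_r1.csv", index=False)
    r2.data.to_csv(outdir / "relax_r2.csv", index=False)

    tg = gen_itc_thermogram(spec)
    pd.DataFrame({
        "inj_vol_ul": tg.injection_volumes_l * 1e6,
        "heat_ucal": tg.heats_cal * 1e6,
    }).to_csv(outdir / "itc.csv", index=False)
    (outdir / "itc_design.json").write_text(json.dumps({
        "cell_volume_l": tg.cell_volume_l, "cell_conc_m": tg.cell_conc_m,
        "syringe_conc_m": tg.syringe_conc_m,
        "temperature_k": tg.temperature_k,
    }, indent=1))

    gen_titration_curve(spec).to_csv(outdir / "titration.csv", index=False)
    melt_free, melt_bound = gen_melting_pair(spec)
    melt_free.to_csv(outdir / "melt_free.csv", index=False)
    melt_bound.to_csv(outdir / "melt_bound.csv", index=False)
    gen_emsa_curve(spec).to_csv(outdir / "emsa.csv", index=False)
    em_free, em_bound = gen_emission_pair(spec)
    em_free.to_csv(outdir / "emission_free.csv", index=False)
    em_bound.to_csv(outdir / "emission_bound.csv", index=False)

    promoter, planted = gen_promoter(spec)
    (outdir / "promoter.fasta").write_text(
        f">{promoter.name} tss_offset={promoter.tss_offset}\n"
        + "\n".join(promoter.bases[i:i + 70]
                    for i in range(0, len(promoter.bases), 70)) + "\n")

    truth = spec.ground_truth()
    truth["promoter_sites"] = {
        k: {kk: list(vv) for kk, vv in v.items()} for k, v in planted.items()}
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return truth
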