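"""15N relaxation analysis and hydrodynamics.

Backbone 15N longitudinal (R1) and transverse (R2) relaxation rates of a
rigid, isotropically tumbling protein depend on the rotational correlation
time tau_c through the standard dipolar + CSA expressions with the rigid
isotropic-rotor spectral density J(w) = (2/5) tau_c / (1 + (w tau_c)^2).
After exponential fitting of decay series and filtering of flexible or
exchange-broadened residues, the R2/R1 ratio inverts to tau_c via

    tau_c = (1 / (4 pi nu_N)) sqrt(6 R2/R1 - 7)

and tau_c converts to a hydrodynamic radius by the Stokes-Einstein-Debye
relation r_H = (3 kB T tau_c / (4 pi eta))^(1/3).

All public interfaces use ns for tau_c, nm for r_H, s^-1 for rates and MHz
for the 1H field.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

# Physical constants (CODATA) and frozen model parameters.
MU0 = 4e-7 * math.pi            # vacuum permeability, T m / A
HBAR = 1.054571817e-34          # J s
GAMMA_H = 2.6752218744e8        # 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_N = -2.7126189e7          # 15N gyromagnetic ratio, rad s^-1 T^-1
R_NH = 1.02e-10                 # N-H bond length, m
CSA_N = -160e-6                 # 15N chemical shift anisotropy
KB = 1.380649e-23               # J / K

WATER_VISCOSITY_25C = 8.90e-4   # Pa s

#: 15N/1H resonance frequency ratio |gamma_N / gamma_H|
N15_FREQ_RATIO = abs(GAMMA_N / GAMMA_H)


def spectral_density(omega: float, tau_c_s: float) -> float:
    """Rigid isotropic-rotor spectral density, s/rad."""
    return 0.4 * tau_c_s / (1.0 + (omega * tau_c_s) ** 2)


def predict_rates(tau_c_ns: float, field_1h_mhz: float) -> tuple[float, float]:
    """R1 and R2 (s^-1) for a rigid isotropic rotor at a given 1H field."""
    if tau_c_ns <= 0:
        raise ValueError("tau_c must be positive")
    tc = tau_c_ns * 1e-9
    w_h = 2 * math.pi * field_1h_mhz * 1e6
    w_n = w_h * GAMMA_N / GAMMA_H
    d = MU0 * HBAR * GAMMA_H * GAMMA_N / (4 * math.pi * R_NH ** 3)
    c = w_n * CSA_N / math.sqrt(3)
    d2, c2 = d * d, c * c
    J = spectral_density
    r1 = (d2 / 4) * (J(w_h - w_n, tc) + 3 * J(w_n, tc) + 6 * J(w_h + w_n, tc)) \
        + c2 * J(w_n, tc)
    r2 = (d2 / 8) * (4 * J(0.0, tc) + J(w_h - w_n, tc) + 3 * J(w_n, tc)
                     + 6 * J(w_h, tc) + 6 * J(w_h + w_n, tc)) \
        + (c2 / 6) * (4 * J(0.0, tc) + 3 * J(w_n, tc))
    return r1, r2


@dataclass
class RelaxationSeries:
    """Per-residue decay curves for one experiment (R1 or R2)."""

    experiment: str                 # 'R1' or 'R2'
    field_1h_mhz: float
    data: pd.DataFrame              # columns: residue, delay_s, intensity

    def __post_init__(self):
        if self.experiment not in ("R1", "R2"):
            raise ValueError("experiment must be 'R1' or 'R2'")
        need = {"residue", "delay_s", "intensity"}
        if not need <= set(self.data.columns):
            raise ValueError(f"series needs columns {sorted(need)}")

    def residues(self) -> list[int]:
        return sorted(set(int(r) for r in self.data["residue"]))


@dataclass
class DecayFit:
    rate: float                     # s^-1
    i0: float
    rate_err: float
    ok: bool


def fit_decay(delays: Iterable[float], intensities: Iterable[float]) -> DecayFit:
    """Nonlinear least-squares fit of I(t) = I0 exp(-R t).

    Requires >= 4 points over >= 3 distinct delays.  Non-decaying data
    (best-fit R <= 0) returns ok=False rather than raising.
    """
    t = np.asarray(list(delays), dtype=float)
    y = np.asarray(list(intensities), dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 points")
    if len(np.unique(t)) < 3:
        raise ValueError("need at least 3 distinct delays")
    # log-linear starting values (guard non-positive intensities)
    ypos = np.clip(y, 1e-30, None)
    slope, intercept = np.polyfit(t, np.log(ypos), 1)
    p0 = (math.exp(intercept), max(-slope, 1e-6))
    try:
        popt, pcov = curve_fit(lambda t, i0, r: i0 * np.exp(-r * t),
                               t, y, p0=p0, maxfev=10000)
    except RuntimeError:
        return DecayFit(rate=float("nan"), i0=float("nan"),
                        rate_err=float("nan"), ok=False)
    i0, r = popt
    err = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("inf")
    if r <= 0:
        return DecayFit(rate=r, i0=i0, rate_err=err, ok=False)
    return DecayFit(rate=float(r), i0=float(i0), rate_err=err, ok=True)


def fit_rate_table(r1_series: RelaxationSeries,
                   r2_series: RelaxationSeries) -> pd.DataFrame:
    """Fit every residue's R1 and R2 decay; returns the joint rate table."""
    if r1_series.field_1h_mhz != r2_series.field_1h_mhz:
        raise ValueError("R1 and R2 series were recorded at different fields")
    rows = []
    common = sorted(set(r1_series.residues()) & set(r2_series.residues()))
    for res in common:
        row = {"residue": res}
        for name, series in (("r1", r1_series), ("r2", r2_series)):
            sub = series.data[series.data["residue"] == res]
            fit = fit_decay(sub["delay_s"], sub["intensity"])
            row[name] = fit.rate
            row[f"{name}_err"] = fit.rate_err
            row[f"{name}_ok"] = fit.ok
        rows.append(row)
    return pd.DataFrame(rows)


def filter_residues(rates: pd.DataFrame,
                    flexible: Iterable[int] = (),
                    max_rel_err: float = 0.20,
                    min_survivors: int = 5,
                    max_iter: int = 50) -> pd.DataFrame:
    """Coarse and fine filtering of the rate table before tau_c estimation.

    Coarse: drop fit failures, residues with relative rate error above
    ``max_rel_err``, and user-marked flexible termini.  Fine: iteratively
    drop residues whose R2/R1 deviates from the current mean by more than
    one standard deviation, until the passing set is stable.
    """
    if len(rates) < 10:
        raise ValueError("need at least 10 residues to filter")
    out = rates.copy()
    flexible = set(int(r) for r in flexible)
    ok = out["r1_ok"] & out["r2_ok"] & (out["r1"] > 0) & (out["r2"] > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel1 = out["r1_err"] / out["r1"]
        rel2 = out["r2_err"] / out["r2"]
    ok &= (rel1 <= max_rel_err) & (rel2 <= max_rel_err)
    ok &= ~out["residue"].isin(flexible)
    out["pass_coarse"] = ok.fillna(False)

    passing = out["pass_coarse"].to_numpy().copy()
    ratio = (out["r2"] / out["r1"]).to_numpy()
    # Iterate the 1-SD trim until the mean R2/R1 is stable (relative change
    # below 1%): outliers (flexible tails, exchange-broadened residues) go
    # in the first rounds without letting the trim eat into the rigid core.
    prev_mean = None
    for _ in range(max_iter):
        idx = np.flatnonzero(passing)
        if len(idx) < min_survivors:
            break
        mean = ratio[idx].mean()
        if prev_mean is not None and abs(mean - prev_mean) <= 0.01 * abs(prev_mean):
            break
        prev_mean = mean
        sd = ratio[idx].std(ddof=0)
        drop = idx[np.abs(ratio[idx] - mean) > sd] if sd > 0 else np.array([], int)
        if len(drop) == 0 or len(idx) - len(drop) < min_survivors:
            break
        passing[drop] = False
    out["pass_fine"] = passing
    if passing.sum() < min_survivors:
        raise ValueError(
            f"fewer than {min_survivors} residues survive filtering")
    return out


@dataclass
class TumblingEstimate:
    """Rotational correlation time and derived hydrodynamic radius."""

    tau_c_ns: float
    tau_c_sd_ns: float
    n_residues: int
    field_1h_mhz: float
    r_h_nm: Optional[float] = None
    temperature_k: Optional[float] = None
    viscosity_pa_s: Optional[float] = None

    def summary(self) -> str:
        lines = [
            "Rotational tumbling estimate",
            "-" * 32,
            f"tau_c            {self.tau_c_ns:7.2f} +/- {self.tau_c_sd_ns:.2f} ns",
            f"residues used    {self.n_residues:d}",
            f"1H field         {self.field_1h_mhz:.1f} MHz",
        ]
        if self.r_h_nm is not None:
            lines.append(f"r_H (SED)        {self.r_h_nm:7.3f} nm "
                         f"(T = {self.temperature_k} K, "
                         f"eta = {self.viscosity_pa_s} Pa s)")
        return "\n".join(lines)


def tauc_from_ratio(ratio: float, field_1h_mhz: float) -> float:
    """Invert an R2/R1 ratio to tau_c (ns); valid for ratio >= 7/6."""
    nu_n = field_1h_mhz * 1e6 * N15_FREQ_RATIO
    radicand = 6.0 * ratio - 7.0
    if radicand < 0:
        raise ValueError("R2/R1 below the 7/6 fast-tumbling limit")
    return math.sqrt(radicand) / (4 * math.pi * nu_n) * 1e9


def estimate_tauc(rates: pd.DataFrame, field_1h_mhz: float,
                  temperature_k: Optional[float] = None,
                  viscosity_pa_s: Optional[float] = None) -> TumblingEstimate:
    """Mean +/- SD tau_c over residues passing both filters.

    Residues whose R2/R1 falls below the theoretical minimum of 7/6 are
    skipped with a warning.  If temperature and viscosity are supplied the
    Stokes-Einstein-Debye radius is attached.
    """
    passing = rates[rates["pass_fine"]] if "pass_fine" in rates.columns else rates
    if len(passing) < 5:
        raise ValueError("need at least 5 passing residues")
    taus = []
    for _, row in passing.iterrows():
        ratio = row["r2"] / row["r1"]
        if 6.0 * ratio - 7.0 < 0:
            warnings.warn(f"residue {int(row['residue'])}: R2/R1 below 7/6, "
                          "skipped", stacklevel=2)
            continue
        taus.append(tauc_from_ratio(ratio, field_1h_mhz))
    taus = np.asarray(taus)
    if len(taus) < 5:
        raise ValueError("fewer than 5 residues with invertible R2/R1")
    est = TumblingEstimate(
        tau_c_ns=float(taus.mean()), tau_c_sd_ns=float(taus.std(ddof=0)),
        n_residues=len(taus), field_1h_mhz=field_1h_mhz,
    )
    if temperature_k is not None and viscosity_pa_s is not None:
        est.r_h_nm = rh_from_tauc(est.tau_c_ns, temperature_k, viscosity_pa_s)
        est.temperature_k = temperature_k
        est.viscosity_pa_s = viscosity_pa_s
    return est


def rh_from_tauc(tau_c_ns: float, temperature_k: float = 298.15,
                 viscosity_pa_s: float = WATER_VISCOSITY_25C) -> float:
    """Stokes-Einstein-Debye hydrodynamic radius, nm.

    r_H = (3 kB T tau_c / (4 pi eta))^(1/3) for an equivalent sphere.
    """
    if min(tau_c_ns, temperature_k, viscosity_pa_s) <= 0:
        raise ValueError("tau_c, T and eta must be positive")
    tc = tau_c_ns * 1e-9
    r_m = (3 * KB * temperature_k * tc / (4 * math.pi * viscosity_pa_s)) ** (1 / 3)
    return r_m * 1e9


def analyze_relaxation(r1_series: RelaxationSeries,
                       r2_series: RelaxationSeries,
                       flexible: Iterable[int] = (),
                       temperature_k: float = 298.15,
                       viscosity_pa_s: float = WATER_VISCOSITY_25C,
                       ) -> tuple[pd.DataFrame, TumblingEstimate]:
    """Full pipeline: decay fits -> filters -> tau_c -> r_H."""
    rates = fit_rate_table(r1_series, r2_series)
    rates = filter_residues(rates, flexible=flexible)
    est = estimate_tauc(rates, r1_series.field_1h_mhz,
                        temperature_k=temperature_k,
                        viscosity_pa_s=viscosity_pa_s)
    return rates, est
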