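"""Sequential two-site binding model for isothermal titration calorimetry.

A double-stranded operator DNA (the cell macromolecule, D) binds two protein
molecules (the syringe titrant, P) stepwise:

    D  + P <-> PD    (site constant K1, enthalpy dH1)
    PD + P <-> P2D   (site constant K2, enthalpy dH2)

Free-ligand concentration at each injection is obtained by bracketed root
finding on the coupled mass balances; injection heats follow from the change
in cumulative binding enthalpy with the standard displaced-volume correction
of perfusion-cell instruments.  With dH1 > 0 > dH2 and K1 >> K2 the
simulated isotherm is endothermic for early injections and exothermic later,
crossing zero once - the biphasic signature of sequential binding.

Fitting is done in log10-K space (which keeps the constants positive) by
multi-start nonlinear least squares; results are returned in a statsmodels-
style Results object with parameter estimates, asymptotic errors and a
summary table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

R_GAS_CAL = 1.98720  # cal / (mol K)


@dataclass(frozen=True)
class SeqBindParams:
    """Stepwise site constants (M^-1) and enthalpies (kcal/mol)."""

    k1: float                   # association constant, site 1
    k2: float
    dh1: float                  # kcal/mol
    dh2: float
    baseline: float = 0.0       # heat per injection, cal

    def __post_init__(self):
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("association constants must be positive")

    @property
    def kd1(self) -> float:
        """Site-1 dissociation constant, M."""
        return 1.0 / self.k1

    @property
    def kd2(self) -> float:
        return 1.0 / self.k2


@dataclass
class Thermogram:
    """An ITC experiment: cell geometry, concentrations, injection heats."""

    cell_volume_l: float
    cell_conc_m: float          # macromolecule (DNA) in the cell
    syringe_conc_m: float       # titrant (protein) in the syringe
    injection_volumes_l: np.ndarray
    heats_cal: Optional[np.ndarray] = None
    temperature_k: float = 295.15   # 22 C

    def __post_init__(self):
        self.injection_volumes_l = np.asarray(self.injection_volumes_l, float)
        if self.heats_cal is not None:
            self.heats_cal = np.asarray(self.heats_cal, float)
            if len(self.heats_cal) != len(self.injection_volumes_l):
                raise ValueError("heats and injection volumes differ in length")
        if self.cell_volume_l <= 0 or self.cell_conc_m < 0 \
                or self.syringe_conc_m < 0:
            raise ValueError("volumes and concentrations must be non-negative"
                             " (cell volume positive)")
        if len(self.injection_volumes_l) < 5:
            raise ValueError("need at least 5 injections")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_l)


def species_fractions(p_tot: float, d_tot: float,
                      k1: float, k2: float) -> tuple[float, float, float, float]:
    """Equilibrium species for the sequential model.

    Returns ([D], [PD], [P2D], [P]free) in M, solving

        Dtot = [D] (1 + K1 [P] + K1 K2 [P]^2)
        Ptot = [P] + [D] (K1 [P] + 2 K1 K2 [P]^2)

    for free [P] in [0, Ptot] by Brent's method at 1e-12 relative tolerance.
    """
    if min(p_tot, d_tot) < 0 or k1 < 0 or k2 < 0:
        raise ValueError("concentrations and constants must be non-negative")
    if p_tot == 0 or d_tot == 0:
        return d_tot, 0.0, 0.0, p_tot

    def residual(p_free: float) -> float:
        denom = 1.0 + k1 * p_free + k1 * k2 * p_free ** 2
        d_free = d_tot / denom
        bound = d_free * (k1 * p_free + 2 * k1 * k2 * p_free ** 2)
        return p_free + bound - p_tot

    lo, hi = 0.0, p_tot
    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo > 0 or f_hi < 0:
        raise ArithmeticError("no sign change in the [P]free bracket")
    p_free = brentq(residual, lo, hi, xtol=1e-30, rtol=1e-14, maxiter=200)
    denom = 1.0 + k1 * p_free + k1 * k2 * p_free ** 2
    d_free = d_tot / denom
    pd_ = d_free * k1 * p_free
    p2d = d_free * k1 * k2 * p_free ** 2
    return d_free, pd_, p2d, p_free


def _titration_states(params: SeqBindParams, design: Thermogram):
    """Cell composition and cumulative heat before/after every injection."""
    v0 = design.cell_volume_l
    d_tot = design.cell_conc_m
    p_tot = 0.0
    states = []
    for dv in design.injection_volumes_l:
        f = dv / v0
        d_tot = d_tot * (1.0 - f)
        p_tot = p_tot * (1.0 - f) + design.syringe_conc_m * f
        _, pd_, p2d, _ = species_fractions(p_tot, d_tot, params.k1, params.k2)
        # cumulative enthalpy content of the cell, cal
        q = v0 * (pd_ * params.dh1 + p2d * (params.dh1 + params.dh2)) * 1000.0
        states.append((d_tot, p_tot, pd_, p2d, q))
    return states


def simulate_heats(params: SeqBindParams, design: Thermogram) -> np.ndarray:
    """Per-injection heats (cal) with the displaced-volume correction.

    q_i = Q_i - Q_{i-1} + (dV_i/V0) (Q_i + Q_{i-1}) / 2 + baseline,
    where Q is the cumulative binding enthalpy in the cell.
    """
    v0 = design.cell_volume_l
    states = _titration_states(params, design)
    heats = np.empty(design.n_injections)
    q_prev = 0.0
    for i, (dv, st) in enumerate(zip(design.injection_volumes_l, states)):
        q = st[4]
        heats[i] = q - q_prev + (dv / v0) * (q + q_prev) / 2.0 + params.baseline
        q_prev = q
    return heats


def molar_ratios(design: Thermogram) -> np.ndarray:
    """Protein:DNA molar ratio in the cell after each injection."""
    v0 = design.cell_volume_l
    d_tot = design.cell_conc_m
    p_tot = 0.0
    out = np.empty(design.n_injections)
    for i, dv in enumerate(design.injection_volumes_l):
        f = dv / v0
        d_tot *= (1.0 - f)
        p_tot = p_tot * (1.0 - f) + design.syringe_conc_m * f
        out[i] = p_tot / d_tot if d_tot > 0 else math.inf
    return out


def thermo_convert(k: float, dh_kcal: float,
                   temperature_k: float = 295.15) -> tuple[float, float]:
    """(dG kcal/mol, dS cal/(mol K)) from an association constant and dH."""
    if k <= 0:
        raise ValueError("association constant must be positive")
    dg = -R_GAS_CAL * temperature_k * math.log(k) / 1000.0
    ds = (dh_kcal - dg) * 1000.0 / temperature_k
    return dg, ds


class SequentialBindingModel:
    """Two-site sequential binding model bound to a thermogram.

    Statsmodels-style usage::

        model = SequentialBindingModel(thermogram)
        res = model.fit()
        print(res.summary())
    """

    PARAM_NAMES = ("log10_k1", "log10_k2", "dh1", "dh2", "baseline")

    def __init__(self, thermogram: Thermogram):
        if thermogram.heats_cal is None:
            raise ValueError("thermogram carries no measured heats to fit")
        if thermogram.n_injections < 10:
            raise ValueError("need at least 10 injections for a stable fit")
        self.thermogram = thermogram

    def predict(self, params: SeqBindParams) -> np.ndarray:
        return simulate_heats(params, self.thermogram)

    def _unpack(self, x: np.ndarray) -> SeqBindParams:
        return SeqBindParams(k1=10.0 ** x[0], k2=10.0 ** x[1],
                             dh1=x[2], dh2=x[3], baseline=x[4])

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        try:
            return self.predict(self._unpack(x)) - self.thermogram.heats_cal
        except (ArithmeticError, ValueError):
            return np.full(self.thermogram.n_injections, 1e6)

    def fit(self, init: Optional[SeqBindParams] = None, n_starts: int = 5,
            seed: int = 0, fit_baseline: bool = True) -> "SequentialBindingResults":
        """Multi-start least squares; jittered restarts guard the shallow K2
        direction of the objective."""
        if init is None:
            init = SeqBindParams(k1=1e7, k2=1e5, dh1=5.0, dh2=-5.0)
        x0 = np.array([math.log10(init.k1), math.log10(init.k2),
                       init.dh1, init.dh2, init.baseline])
        rng = np.random.default_rng(seed)
        bounds = ([2.0, 2.0, -100.0, -100.0, -1.0],
                  [15.0, 15.0, 100.0, 100.0, 1.0])
        if not fit_baseline:
            bounds[0][4], bounds[1][4] = -1e-12, 1e-12

        best = None
        for start in range(max(1, n_starts)):
            xs = x0.copy()
            if start > 0:
                xs[:2] += rng.normal(0, 0.5, 2)
                xs[2:4] += rng.normal(0, 2.0, 2)
            xs = np.clip(xs, bounds[0], bounds[1])
            sol = least_squares(self._residuals, xs, bounds=bounds,
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not best.success:
            raise RuntimeError("sequential-model fit did not converge")

        # asymptotic covariance from the Jacobian at the optimum
        resid = best.fun
        dof = max(len(resid) - len(best.x), 1)
        s2 = float(resid @ resid) / dof
        jtj = best.jac.T @ best.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            cov = np.full((len(best.x),) * 2, np.nan)
            bse = np.full(len(best.x), np.nan)

        at_bound = np.any(np.isclose(best.x, bounds[0]) |
                          np.isclose(best.x, bounds[1]))
        return SequentialBindingResults(
            model=self, params=self._unpack(best.x), x=best.x, bse=bse,
            cov=cov, residuals=resid, cost=float(best.cost),
            at_bound=bool(at_bound),
        )


@dataclass
class SequentialBindingResults:
    """Fit results: estimates, asymptotic errors, diagnostics."""

    model: SequentialBindingModel
    params: SeqBindParams
    x: np.ndarray               # (log10 K1, log10 K2, dH1, dH2, baseline)
    bse: np.ndarray             # standard errors on x
    cov: np.ndarray
    residuals: np.ndarray
    cost: float
    at_bound: bool

    @property
    def kd1_nm(self) -> float:
        return self.params.kd1 * 1e9

    @property
    def kd2_um(self) -> float:
        return self.params.kd2 * 1e6

    def thermodynamics(self) -> dict:
        """dG / dH / dS per binding step at the experiment temperature."""
        t = self.model.thermogram.temperature_k
        out = {}
        for i, (k, dh) in enumerate(((self.params.k1, self.params.dh1),
                                     (self.params.k2, self.params.dh2)), 1):
            dg, ds = thermo_convert(k, dh, t)
            out[f"site{i}"] = {"dG_kcal_mol": dg, "dH_kcal_mol": dh,
                               "dS_cal_mol_K": ds}
        return out

    def summary(self) -> str:
        t = self.model.thermogram.temperature_k
        th = self.thermodynamics()
        lines = [
            "Sequential two-site binding fit",
            "=" * 46,
            f"injections: {self.model.thermogram.n_injections}"
            f"   T = {t:.2f} K   SSR = {2 * self.cost:.3e} cal^2",
            "",
            f"{'':12}{'value':>12}  {'std err (log10K / kcal)':>24}",
            f"{'Kd1':12}{self.kd1_nm:10.2f} nM  {self.bse[0]:>14.3g}",
            f"{'Kd2':12}{self.kd2_um:10.3f} uM  {self.bse[1]:>14.3g}",
            f"{'dH1':12}{self.params.dh1:10.3f} kcal/mol  {self.bse[2]:>10.3g}",
            f"{'dH2':12}{self.params.dh2:10.3f} kcal/mol  {self.bse[3]:>10.3g}",
            f"{'baseline':12}{self.params.baseline:10.3e} cal  {self.bse[4]:>10.3g}",
            "",
            f"site 1: dG = {th['site1']['dG_kcal_mol']:.2f} kcal/mol, "
            f"dS = {th['site1']['dS_cal_mol_K']:.1f} cal/(mol K)",
            f"site 2: dG = {th['site2']['dG_kcal_mol']:.2f} kcal/mol, "
            f"dS = {th['site2']['dS_cal_mol_K']:.1f} cal/(mol K)",
        ]
        if self.at_bound:
            lines.append("warning: a parameter sits at its bound")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed vs fitted injection heats against molar ratio."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ratios = molar_ratios(self.model.thermogram)
        obs = self.model.thermogram.heats_cal * 1e6
        fit = self.model.predict(self.params) * 1e6
        ax.plot(ratios, obs, "o", label="observed")
        ax.plot(ratios, fit, "-", label="sequential-model fit")
        ax.axhline(0.0, color="0.7", lw=0.8)
        ax.set_xlabel("molar ratio protein:DNA")
        ax.set_ylabel("heat per injection (ucal)")
        ax.legend()
        return ax
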