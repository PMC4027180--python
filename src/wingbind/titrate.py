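"""Titration-style curve analyses: stoichiometry breakpoints, spectral
shifts, duplex melting temperatures and Hill cooperativity.

Four independent spectroscopic/electrophoretic readouts constrain how the
protein loads onto its operator DNA:

* CD/fluorescence titrations saturate at a protein:DNA molar ratio of 2,
  located here by a continuous two-segment linear fit;
* the single-tryptophan emission maximum blue-shifts on binding, measured
  by parabolic interpolation of each spectrum's peak;
* duplex melting curves shift to higher temperature when protein is bound,
  with Tm taken as the maximum of the smoothed A260 derivative;
* EMSA fraction-bound data follow a steep Hill isotherm whose exponent
  reports apparent cooperativity of the two-site loading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar


# ---------------------------------------------------------------- breakpoint

class NoBreakpointError(ValueError):
    """The two-segment model does not beat a single line."""


@dataclass
class BreakpointResults:
    """Continuous two-segment linear fit S(r) = a + b r + c max(r - x0, 0)."""

    breakpoint: float
    intercept: float
    slope_before: float
    slope_change: float         # c; slope after the break is b + c
    sse: float

    @property
    def slope_after(self) -> float:
        return self.slope_before + self.slope_change

    def summary(self) -> str:
        return (
            "Two-segment titration fit\n"
            f"breakpoint ratio  {self.breakpoint:.4f}\n"
            f"slope before      {self.slope_before:.4g}\n"
            f"slope after       {self.slope_after:.4g}\n"
            f"SSE               {self.sse:.3e}"
        )


class BreakpointModel:
    """Locate the molar ratio where a titration signal changes slope."""

    def __init__(self, ratios: Sequence[float], signal: Sequence[float]):
        self.ratios = np.asarray(ratios, float)
        self.signal = np.asarray(signal, float)
        if len(self.ratios) < 6:
            raise ValueError("need at least 6 points spanning the break")
        if np.any(self.ratios < 0) or np.any(np.diff(self.ratios) <= 0):
            raise ValueError("ratios must be non-negative, strictly increasing")

    def _sse_at(self, x0: float):
        hinge = np.maximum(self.ratios - x0, 0.0)
        design = np.column_stack([np.ones_like(self.ratios), self.ratios, hinge])
        coef, res, *_ = np.linalg.lstsq(design, self.signal, rcond=None)
        sse = float(np.sum((design @ coef - self.signal) ** 2))
        return sse, coef

    def fit(self, rel_tol: float = 1e-6) -> BreakpointResults:
        """Profile the knot over the interior, refine, test against a line.

        Raises NoBreakpointError when the slope change is below the noise
        floor (the two-segment fit does not improve on a single line).
        """
        r = self.ratios
        interior = np.linspace(r[1], r[-2], 201)
        sses = np.array([self._sse_at(x)[0] for x in interior])
        i = int(np.argmin(sses))
        lo = interior[max(i - 1, 0)]
        hi = interior[min(i + 1, len(interior) - 1)]
        if hi > lo:
            opt = minimize_scalar(lambda x: self._sse_at(x)[0],
                                  bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-10})
            x0 = float(opt.x)
        else:
            x0 = float(interior[i])
        sse2, coef = self._sse_at(x0)

        # single-line comparison
        line = np.column_stack([np.ones_like(r), r])
        lcoef, *_ = np.linalg.lstsq(line, self.signal, rcond=None)
        sse1 = float(np.sum((line @ lcoef - self.signal) ** 2))

        scale = max(float(np.ptp(self.signal)) ** 2, 1e-300)
        c = float(coef[2])
        slope_scale = max(abs(float(coef[1])), 1e-12)
        if sse1 / scale < rel_tol or (sse1 > 0 and sse2 > 0.95 * sse1) \
                or abs(c) < 1e-8 * slope_scale:
            raise NoBreakpointError("no slope change above the noise floor")
        return BreakpointResults(breakpoint=x0, intercept=float(coef[0]),
                                 slope_before=float(coef[1]),
                                 slope_change=c, sse=sse2)


def breakpoint_stoichiometry(ratios, signal) -> BreakpointResults:
    """Functional wrapper around :class:`BreakpointModel`."""
    return BreakpointModel(ratios, signal).fit()


# ---------------------------------------------------------------- lambda max

def lambda_max(wavelengths: Sequence[float],
               intensities: Sequence[float]) -> float:
    """Emission maximum (nm) by parabolic interpolation around the peak.

    Requires at least 5 wavelengths; a maximum at the grid edge (or a flat
    spectrum) yields a warning and the uninterpolated grid value.
    """
    w = np.asarray(wavelengths, float)
    y = np.asarray(intensities, float)
    if len(w) < 5:
        raise ValueError("need at least 5 wavelengths around the peak")
    if np.any(np.diff(w) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    i = int(np.argmax(y))
    if i == 0 or i == len(w) - 1 or np.ptp(y) == 0:
        warnings.warn("spectrum maximum at grid edge or flat; returning the "
                      "grid value without interpolation", stacklevel=2)
        return float(w[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(w[i])
    # vertex of the parabola through the three points (uniform-grid formula
    # generalized to the local spacing)
    delta = 0.5 * (y0 - y2) / denom
    return float(w[i] + delta * (w[i + 1] - w[i - 1]) / 2.0)


def blue_shift(free_wavelengths, free_intensities,
               bound_wavelengths, bound_intensities) -> float:
    """lambda_max(free) - lambda_max(bound); positive for a blue shift."""
    return lambda_max(free_wavelengths, free_intensities) - \
        lambda_max(bound_wavelengths, bound_intensities)


# ------------------------------------------------------------------- melting

class NoTransitionError(ValueError):
    """Melting curve shows no detectable transition."""


def tm_from_melt(temperatures: Sequence[float],
                 a260: Sequence[float]) -> float:
    """Melting temperature as the maximum of the smoothed dA260/dT.

    The absorbance trace is smoothed with a 3-point moving average, the
    derivative taken by central differences, and the maximum refined by
    parabolic interpolation.
    """
    t = np.asarray(temperatures, float)
    y = np.asarray(a260, float)
    if len(t) < 7:
        raise ValueError("need at least 7 temperature points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperatures must be strictly increasing")
    if t[-1] - t[0] < 20:
        raise ValueError("melting curve must span at least 20 degC")
    if np.ptp(y) <= 0:
        raise NoTransitionError("flat melting curve")
    smooth = np.convolve(y, np.ones(3) / 3.0, mode="valid")
    ts = t[1:-1]
    dy = np.gradient(smooth, ts)
    i = int(np.argmax(dy))
    if i == 0 or i == len(ts) - 1:
        raise NoTransitionError("derivative maximum at the grid edge; "
                                "no interior transition")
    y0, y1, y2 = dy[i - 1], dy[i], dy[i + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return float(ts[i] + delta * (ts[i + 1] - ts[i - 1]) / 2.0)


def delta_tm(free_temps, free_a260, bound_temps, bound_a260) -> float:
    """Tm(bound) - Tm(free), degC; positive when binding stabilizes DNA."""
    return tm_from_melt(bound_temps, bound_a260) - \
        tm_from_melt(free_temps, free_a260)


# ---------------------------------------------------------------------- Hill

@dataclass
class HillResults:
    """Hill-equation fit f(c) = c^n / (K^n + c^n)."""

    n: float
    k_half: float               # same units as the concentrations
    n_se: float
    k_se: float
    residuals: np.ndarray

    def ci(self, z: float = 1.96) -> dict:
        return {"n": (self.n - z * self.n_se, self.n + z * self.n_se),
                "k_half": (self.k_half - z * self.k_se,
                           self.k_half + z * self.k_se)}

    def summary(self) -> str:
        lo_n, hi_n = self.ci()["n"]
        return (
            "Hill cooperativity fit\n"
            f"n       {self.n:.3f} +/- {self.n_se:.3f}  "
            f"(95% CI {lo_n:.2f}..{hi_n:.2f})\n"
            f"K_half  {self.k_half:.3f} +/- {self.k_se:.3f}\n"
            f"RMS residual {np.sqrt(np.mean(self.residuals ** 2)):.3e}"
        )


def hill_curve(conc, n, k_half):
    conc = np.asarray(conc, float)
    return conc ** n / (k_half ** n + conc ** n)


class HillModel:
    """Fit the Hill equation to fraction-bound binding data."""

    def __init__(self, concentrations: Sequence[float],
                 fraction_bound: Sequence[float]):
        self.conc = np.asarray(concentrations, float)
        self.frac = np.asarray(fraction_bound, float)
        if len(self.conc) < 5:
            raise ValueError("need at least 5 concentrations")
        if np.any(np.diff(self.conc) <= 0) or np.any(self.conc <= 0):
            raise ValueError("concentrations must be positive, increasing")
        if np.any((self.frac < -1e-9) | (self.frac > 1 + 1e-9)):
            raise ValueError("fractions bound must lie in [0, 1]")

    def fit(self) -> HillResults:
        if np.ptp(self.frac) < 1e-6:
            raise RuntimeError("flat binding data; Hill fit undefined")
        # half-saturation starting value from the closest point to f = 0.5
        k0 = float(self.conc[np.argmin(np.abs(self.frac - 0.5))])
        try:
            popt, pcov = curve_fit(hill_curve, self.conc, self.frac,
                                   p0=(2.0, k0),
                                   bounds=([0.05, 1e-12], [50.0, 1e12]),
                                   maxfev=20000)
        except RuntimeError as exc:
            raise RuntimeError(f"Hill fit failed: {exc}") from exc
        n, k = popt
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
        resid = hill_curve(self.conc, n, k) - self.frac
        return HillResults(n=float(n), k_half=float(k),
                           n_se=float(se[0]), k_se=float(se[1]),
                           residuals=resid)


def hill_fit(concentrations, fraction_bound) -> HillResults:
    """Functional wrapper around :class:`HillModel`."""
    return HillModel(concentrations, fraction_bound).fit()
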