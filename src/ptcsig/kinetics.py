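"""Enzyme kinetics: hyperbolic saturation fits, catalytic efficiency,
inhibition curves, and transcarbamylation equilibrium.

Transcarbamylase activity assays report rates in enzyme units per mg
protein (1 U = 1 umol product per minute) against substrate
concentrations in mM. Saturation data follow the Michaelis-Menten
hyperbola v = Vmax*S/(Km+S); catalytic efficiency is Vmax/Km
(U mg^-1 mM^-1). Inhibition data (percent of uninhibited activity vs
inhibitor concentration, e.g. the bisubstrate analog PAPU) are fitted
to a logistic decline with an IC50 and optional Hill slope. The
reversible transcarbamylation A + B <-> C + D with equilibrium constant
Keq = [C][D]/([A][B]) yields a closed-form conversion fraction of the
limiting substrate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


class FitError(RuntimeError):
    """Raised for degenerate data or non-convergent fits."""


@dataclass
class SaturationDataset:
    """Substrate saturation observations: concentrations (mM), rates (U/mg)."""

    substrate: str
    concentrations: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.concentrations.shape != self.rates.shape:
            raise ValueError("concentrations and rates differ in length")
        if len(self.concentrations) < 3:
            raise ValueError("need at least 3 points to fit a hyperbola")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if len(np.unique(self.concentrations)) != len(self.concentrations):
            raise ValueError("concentrations must be distinct")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")


@dataclass
class HyperbolicFit:
    vmax: float
    km: float
    se_vmax: float
    se_km: float
    efficiency: float  # vmax / km, U mg^-1 mM^-1
    rss: float


@dataclass
class InhibitionDataset:
    """Inhibitor concentrations vs percent of uninhibited activity."""

    inhibitor: str
    concentrations: np.ndarray
    percent_activity: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.percent_activity = np.asarray(self.percent_activity, dtype=float)
        if self.concentrations.shape != self.percent_activity.shape:
            raise ValueError("concentrations and percents differ in length")
        if len(self.concentrations) < 4:
            raise ValueError("need at least 4 points including the zero-inhibitor reference")
        if not np.any(self.concentrations == 0):
            raise ValueError("dataset must include the zero-inhibitor reference")
        if np.any(self.percent_activity < 0) or np.any(self.percent_activity > 120):
            raise ValueError("percent activity outside [0, 120]")


@dataclass
class InhibitionFit:
    ic50: float
    hill: float
    se_ic50: float
    se_hill: float
    rss: float


def michaelis_menten(s, vmax, km):
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def fit_hyperbola(data: SaturationDataset) -> HyperbolicFit:
    """Nonlinear least-squares fit of v = Vmax*S/(Km+S).

    Deterministic initializer: Vmax0 = 1.2 * max rate; Km0 = the
    concentration whose rate is nearest Vmax0/2. Standard errors come
    from the covariance of the linearized problem at the optimum.
    """
    s, v = data.concentrations, data.rates
    if np.all(v == 0):
        raise FitError("all rates are zero; nothing to fit")
    vmax0 = 1.2 * float(np.max(v))
    km0 = float(s[np.argmin(np.abs(v - vmax0 / 2))])
    try:
        popt, pcov = curve_fit(
            michaelis_menten, s, v, p0=[vmax0, km0],
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"hyperbolic fit did not converge: {exc}") from exc
    vmax, km = (float(x) for x in popt)
    if not (vmax > 0 and km > 0):
        raise FitError(f"degenerate fit: vmax={vmax}, km={km}")
    resid = v - michaelis_menten(s, vmax, km)
    se = np.sqrt(np.diag(pcov))
    return HyperbolicFit(
        vmax=vmax, km=km,
        se_vmax=float(se[0]), se_km=float(se[1]),
        efficiency=vmax / km, rss=float(np.sum(resid**2)),
    )


def round_sig(value: float, sig_figs: int) -> float:
    """Round to a number of significant figures (reporting convention)."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return round(value, sig_figs - 1 - exponent)


def catalytic_efficiency(fit: HyperbolicFit, sig_figs: int | None = None) -> float:
    """Vmax/Km in U mg^-1 mM^-1, optionally rounded to ``sig_figs``."""
    if fit.km == 0:
        raise FitError("Km is zero; efficiency undefined")
    eff = fit.vmax / fit.km
    return round_sig(eff, sig_figs) if sig_figs else eff


def _logistic(i, ic50, hill):
    i = np.asarray(i, dtype=float)
    out = np.empty_like(i)
    nz = i > 0
    out[nz] = 100.0 / (1.0 + (i[nz] / ic50) ** hill)
    out[~nz] = 100.0
    return out


def fit_inhibition(data: InhibitionDataset, fix_hill: float | None = None) -> InhibitionFit:
    """Least-squares fit of percent = 100 / (1 + ([I]/IC50)^h).

    ``fix_hill`` pins the Hill slope (e.g. 1 for simple binding);
    otherwise h is free. Raises :class:`FitError` when the data show no
    decline with concentration.
    """
    i, p = data.concentrations, data.percent_activity
    order = np.argsort(i)
    i, p = i[order], p[order]
    half = len(i) // 2
    if np.mean(p[half:]) >= np.mean(p[:half]):
        raise FitError("no inhibition detected: activity does not decline with concentration")
    pos = i[i > 0]
    ic50_0 = float(np.median(pos))
    try:
        if fix_hill is not None:
            popt, pcov = curve_fit(
                lambda x, ic50: _logistic(x, ic50, fix_hill), i, p,
                p0=[ic50_0], bounds=(0.0, np.inf), maxfev=10000,
            )
            ic50 = float(popt[0])
            hill, se_hill = float(fix_hill), 0.0
            se_ic50 = float(np.sqrt(pcov[0, 0]))
        else:
            popt, pcov = curve_fit(
                _logistic, i, p, p0=[ic50_0, 1.0],
                bounds=([0.0, 0.05], [np.inf, 10.0]), maxfev=10000,
            )
            ic50, hill = (float(x) for x in popt)
            se = np.sqrt(np.diag(pcov))
            se_ic50, se_hill = float(se[0]), float(se[1])
    except RuntimeError as exc:
        raise FitError(f"inhibition fit did not converge: {exc}") from exc
    resid = p - _logistic(i, ic50, hill)
    return InhibitionFit(ic50=ic50, hill=hill, se_ic50=se_ic50, se_hill=se_hill,
                         rss=float(np.sum(resid**2)))


def equilibrium_conversion(keq: float, a0: float, b0: float) -> float:
    """Fraction of the limiting substrate converted at equilibrium.

    For A + B <-> C + D starting from a0, b0 (mM) with no products,
    the extent x solves x^2 = Keq (a0 - x)(b0 - x); the physical root
    satisfies 0 <= x <= min(a0, b0). Returns x / min(a0, b0).
    """
    if keq < 0:
        raise ValueError("Keq must be non-negative")
    if a0 <= 0 or b0 <= 0:
        raise ValueError("initial concentrations must be positive")
    if keq == 0:
        return 0.0
    # (1 - Keq) x^2 + Keq (a0 + b0) x - Keq a0 b0 = 0
    a = 1.0 - keq
    b = keq * (a0 + b0)
    c = -keq * a0 * b0
    if a == 0:
        x = -c / b
    else:
        disc = b * b - 4 * a * c
        x = (-b + math.sqrt(disc)) / (2 * a)
        if not (0 <= x <= min(a0, b0) + 1e-12):
            x = (-b - math.sqrt(disc)) / (2 * a)
    x = min(max(x, 0.0), min(a0, b0))
    return x / min(a0, b0)
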