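"""Two-state van't Hoff analysis of thermal denaturation curves.

The observed melting signal is modeled as a linear folded baseline plus a
linear dissociated baseline mixed by the two-state dissociated fraction
theta(T).  For the default unimolecular transition, K = theta/(1-theta)
and

    K(T) = exp[ -(dH/R) (1/T - 1/Tm) ]

so theta(Tm) = 1/2 and dS = dH/Tm for the dissociation reaction.  An
optional bimolecular mode treats duplex <-> two strands at total duplex
concentration c0, where K(Tm) = c0 and dS = dH/Tm + R ln c0.  dH is in
kcal/mol, dS in cal/(mol K), dG37 = dH - 310.15 K * dS.

Dye-free parameters are obtained by ordinary least-squares extrapolation of
per-curve parameters to zero dye concentration (the intercalating reporter
dye perturbs duplex stability roughly linearly at low dye levels).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter
from scipy.stats import linregress

from .constants import R_CAL

__all__ = [
    "MeltCurve",
    "ThermoParams",
    "fit_two_state",
    "extrapolate_zero_dye",
    "two_state_signal",
]

T37_K = 310.15


@dataclass(frozen=True)
class MeltCurve:
    """Denaturation curve: signal (a.u.) vs temperature (deg C)."""

    temperature_C: np.ndarray
    signal: np.ndarray
    dye: float = 0.0
    strand_conc_M: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature_C, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or len(t) != len(s):
            raise ValueError("temperature and signal must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperature must be strictly increasing")
        if not np.all(np.isfinite(s)):
            raise ValueError("signal must be finite")
        if self.dye < 0:
            raise ValueError("dye concentration must be >= 0")
        object.__setattr__(self, "temperature_C", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class ThermoParams:
    """Van't Hoff outputs for the dissociation reaction.

    Tm in deg C; dH in kcal/mol; dS in cal/(mol K); dG37 in kcal/mol,
    satisfying dG37 = dH - 310.15 * dS / 1000 exactly.
    """

    Tm_C: float
    dH_kcal: float
    dS_cal: float
    se: dict | None = None

    @property
    def dG37_kcal(self) -> float:
        return self.dH_kcal - T37_K * self.dS_cal / 1000.0

    def to_dict(self) -> dict:
        d = {
            "Tm_C": self.Tm_C,
            "dH_kcal_per_mol": self.dH_kcal,
            "dS_cal_per_mol_K": self.dS_cal,
            "dG37_kcal_per_mol": self.dG37_kcal,
        }
        if self.se:
            d["se"] = dict(self.se)
        return d


def _theta_dissociated(T_K, Tm_K, dH_kcal, strand_conc_M=None):
    """Dissociated fraction for the two-state model (vectorized)."""
    dH_cal = dH_kcal * 1000.0
    lnK = -(dH_cal / R_CAL) * (1.0 / T_K - 1.0 / Tm_K)
    if strand_conc_M is None:
        # unimolecular: K = theta/(1-theta)
        return 1.0 / (1.0 + np.exp(-lnK))
    # bimolecular: K = 2 c0 theta^2/(1-theta), K(Tm) = c0
    K = strand_conc_M * np.exp(lnK)
    a = 2.0 * strand_conc_M
    disc = np.sqrt(K * K + 4.0 * a * K)
    return np.clip((-K + disc) / (2.0 * a), 0.0, 1.0)


def two_state_signal(
    T_C,
    Tm_C: float,
    dH_kcal: float,
    base_lo: tuple[float, float],
    base_hi: tuple[float, float],
    strand_conc_M: float | None = None,
):
    """Forward model: folded/unfolded linear baselines mixed by theta(T)."""
    T_C = np.asarray(T_C, dtype=float)
    T_K = T_C + 273.15
    theta = _theta_dissociated(T_K, Tm_C + 273.15, dH_kcal, strand_conc_M)
    lo = base_lo[0] + base_lo[1] * T_C
    hi = base_hi[0] + base_hi[1] * T_C
    return lo * (1.0 - theta) + hi * theta


def _initial_guess(curve: MeltCurve):
    T, s = curve.temperature_C, curve.signal
    n = len(T)
    window = min(max(11, (n // 20) * 2 + 1), n - 1 if (n - 1) % 2 else n - 2)
    smooth = savgol_filter(s, window, 3)
    ds = np.gradient(smooth, T)
    # transition center: extremum of the smoothed derivative
    i = int(np.argmax(np.abs(ds)))
    Tm0 = float(T[i])
    width = max((T[-1] - T[0]) / 20.0, 1.0)
    Tm_K = Tm0 + 273.15
    dH0 = 4.0 * R_CAL * Tm_K**2 / (width * 1000.0)  # kcal/mol from 10-90% width
    k = max(n // 10, 3)
    lo = np.polyfit(T[:k], s[:k], 1)[::-1]
    hi = np.polyfit(T[-k:], s[-k:], 1)[::-1]
    return Tm0, dH0, lo, hi


def fit_two_state(curve: MeltCurve, bimolecular: bool = False) -> ThermoParams:
    """Fit baselines plus a two-state transition to a melting curve.

    Baselines are linear in T and fitted jointly with (Tm, dH).  Raises if
    no transition is detectable (signal change across the curve within the
    baseline scatter).
    """
    T, s = curve.temperature_C, curve.signal
    if len(T) < 50:
        raise ValueError("melting curve too sparse; need baselines plus transition")
    strand = curve.strand_conc_M if bimolecular else None
    Tm0, dH0, lo0, hi0 = _initial_guess(curve)
    span = float(s.max() - s.min())
    k = max(len(T) // 10, 3)
    base_scatter = float(np.std(s[:k] - np.polyval(np.polyfit(T[:k], s[:k], 1), T[:k])))
    lo_at_tm = lo0[0] + lo0[1] * Tm0
    hi_at_tm = hi0[0] + hi0[1] * Tm0
    mid_jump = abs(hi_at_tm - lo_at_tm)
    if span == 0 or mid_jump < max(6.0 * base_scatter, 1e-12 * max(abs(s).max(), 1.0)):
        raise ValueError("no detectable two-state transition in the curve")

    def residuals(p):
        Tm, dH, a0, a1, b0, b1 = p
        return two_state_signal(T, Tm, dH, (a0, a1), (b0, b1), strand) - s

    x0 = np.array([Tm0, max(dH0, 20.0), lo0[0], lo0[1], hi0[0], hi0[1]])
    lo_b = [T[0], 1.0, -np.inf, -np.inf, -np.inf, -np.inf]
    hi_b = [T[-1], 2000.0, np.inf, np.inf, np.inf, np.inf]
    res = least_squares(residuals, x0, bounds=(lo_b, hi_b), xtol=1e-13, ftol=1e-13)
    Tm, dH = float(res.x[0]), float(res.x[1])
    Tm_K = Tm + 273.15
    if strand is None:
        dS = dH * 1000.0 / Tm_K
    else:
        dS = dH * 1000.0 / Tm_K + R_CAL * np.log(strand)
    return ThermoParams(Tm_C=Tm, dH_kcal=dH, dS_cal=float(dS))


def extrapolate_zero_dye(fits: list[tuple[float, ThermoParams]]) -> ThermoParams:
    """OLS extrapolation of per-curve parameters to zero dye concentration.

    ``fits`` pairs each curve's dye level with its fitted parameters
    (replicates simply appear as repeated dye values).  Returns the
    intercepts with their standard errors.
    """
    dyes = np.array([d for d, _ in fits], dtype=float)
    if len(np.unique(dyes)) < 3:
        raise ValueError("need >= 3 distinct dye concentrations to extrapolate")
    out = {}
    se = {}
    for name in ("Tm_C", "dH_kcal", "dS_cal"):
        y = np.array([getattr(p, name) for _, p in fits], dtype=float)
        if np.allclose(y, y[0]):
            out[name], se[name] = float(y[0]), 0.0
            continue
        reg = linregress(dyes, y)
        out[name] = float(reg.intercept)
        se[name] = float(reg.intercept_stderr)
    return ThermoParams(
        Tm_C=out["Tm_C"],
        dH_kcal=out["dH_kcal"],
        dS_cal=out["dS_cal"],
        se={"Tm_C": se["Tm_C"], "dH_kcal": se["dH_kcal"], "dS_cal": se["dS_cal"]},
    )
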