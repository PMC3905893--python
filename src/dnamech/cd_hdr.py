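"""Helical diagnostic ratio (HDR) from circular dichroism spectra.

Ellipticity at 290 nm is loosely diagnostic of helical family (negative for
Z-form, positive for A-form, near zero for B-form), and the ratio
HDR = Theta(290 nm)/Theta(201 nm) separates DNA-like duplexes into four
spectral families.  Classification bins partition (-1.5, 1.5], half-open on
the left and closed on the right so every ratio has a single label::

    ( 0.0, 0.5]  B-type
    (-0.5, 0.0]  B/Z-intermediate
    (-1.5,-0.5]  Z-type
    ( 0.5, 1.5]  A-type

The ratio is scale invariant (concentration and path length cancel).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

__all__ = ["CDSpectrum", "HDRResult", "compute_hdr", "classify_hdr", "correlate_hdr"]

HDR_NUMERATOR_NM = 290.0
HDR_DENOMINATOR_NM = 201.0

#: (low, high], label — in classification order.
HDR_BINS = (
    (0.0, 0.5, "B-type"),
    (-0.5, 0.0, "B/Z-intermediate"),
    (-1.5, -0.5, "Z-type"),
    (0.5, 1.5, "A-type"),
)


@dataclass(frozen=True)
class CDSpectrum:
    """CD spectrum: ellipticity (mdeg) on a wavelength grid (nm)."""

    wavelength_nm: np.ndarray
    ellipticity_mdeg: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        el = np.asarray(self.ellipticity_mdeg, dtype=float)
        if wl.ndim != 1 or len(wl) != len(el):
            raise ValueError("wavelength and ellipticity must be 1-D and equal length")
        if not np.all(np.isfinite(el)):
            raise ValueError("ellipticity must be finite")
        order = np.argsort(wl)
        object.__setattr__(self, "wavelength_nm", wl[order])
        object.__setattr__(self, "ellipticity_mdeg", el[order])

    def at(self, wavelength_nm: float, tol_nm: float = 0.5) -> float:
        """Ellipticity at the nearest grid point within ``tol_nm``."""
        i = int(np.argmin(np.abs(self.wavelength_nm - wavelength_nm)))
        if abs(self.wavelength_nm[i] - wavelength_nm) > tol_nm:
            raise ValueError(
                f"no grid point within {tol_nm} nm of {wavelength_nm} nm"
            )
        return float(self.ellipticity_mdeg[i])


@dataclass(frozen=True)
class HDRResult:
    hdr: float
    group: str | None
    out_of_range: bool

    def to_dict(self) -> dict:
        return {"hdr": self.hdr, "group": self.group, "out_of_range": self.out_of_range}


def classify_hdr(hdr: float) -> HDRResult:
    """Assign the helical-family label for a diagnostic ratio."""
    for lo, hi, label in HDR_BINS:
        if lo < hdr <= hi:
            return HDRResult(hdr=hdr, group=label, out_of_range=False)
    return HDRResult(hdr=hdr, group=None, out_of_range=True)


def compute_hdr(spectrum: CDSpectrum) -> HDRResult:
    """HDR = Theta(290)/Theta(201) with nearest-grid-point lookup."""
    num = spectrum.at(HDR_NUMERATOR_NM)
    den = spectrum.at(HDR_DENOMINATOR_NM)
    if den == 0:
        raise ZeroDivisionError("Theta(201 nm) = 0: HDR undefined")
    return classify_hdr(num / den)


def _perm_pvalue(x, y, rho, rng, n_perm):
    """Two-sided permutation p-value for Spearman rho; exact for n <= 8."""
    n = len(x)
    count = 0
    if n <= 8:
        total = 0
        for perm in itertools.permutations(range(n)):
            r = spearmanr(x, y[list(perm)]).statistic
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return count / total
    for _ in range(n_perm):
        r = spearmanr(x, rng.permutation(y)).statistic
        count += abs(r) >= abs(rho) - 1e-12
    return (count + 1) / (n_perm + 1)


def correlate_hdr(
    table,
    value_columns: list[str] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
):
    """Spearman rank correlation of HDR against per-polymer parameters.

    ``table`` is a DataFrame-like with an ``hdr`` column plus parameter
    columns (e.g. Tm, P, gamma0, C).  Ties get average ranks (scipy
    convention).  P-values are two-sided permutation tests: exact
    enumeration for n <= 8 rows, else ``n_perm`` seeded permutations.
    Returns a DataFrame indexed by parameter with rho and p.
    """
    import pandas as pd

    df = pd.DataFrame(table)
    if "hdr" not in df:
        raise ValueError("table must have an 'hdr' column")
    if len(df) < 3:
        raise ValueError("need at least 3 polymers to correlate")
    if value_columns is None:
        value_columns = [c for c in df.columns if c != "hdr"]
    rng = np.random.default_rng(seed)
    hdr = df["hdr"].to_numpy(dtype=float)
    rows = {}
    for col in value_columns:
        y = df[col].to_numpy(dtype=float)
        rho = float(spearmanr(hdr, y).statistic)
        rows[col] = {"rho": rho, "p_value": float(_perm_pvalue(hdr, y, rho, rng, n_perm))}
    return pd.DataFrame(rows).T
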