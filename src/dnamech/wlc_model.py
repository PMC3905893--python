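"""Semiempirical wormlike-chain model of the DNA cyclization J-factor.

The J-factor — the effective concentration (here nM) of one end of a short
DNA in the correctly aligned vicinity of the other — is approximated as the
product of a bending (ring-closure) component and a twisting (topoisomer)
component::

    J(L) = J_bend(L; P) * F_twist(L; P, gamma0, C)

``J_bend`` is the closed-form ring-closure factor for a wormlike chain with
aligned ends (the classic teardrop-energy approximation, valid for reduced
lengths L/P up to ~6)::

    J_bend = 112.04 (L/P)^-5 exp(-14.054 P/L + 0.246 L/P) / (2P)^3

in molecules/nm^3, converted to nM at the surface.  ``F_twist`` accounts for
the quantization of linking number on ring closure: the probability that the
total twist + writhe lands on an integer, summed over the few topoisomers
that matter (by default the seven integers nearest the relaxed linking
number Lk0 = n_bp/gamma0), with Gaussian weights of variance
var(Lk) = var(Tw) + var(Wr).  The twist-fluctuation term is
L kT / (4 pi^2 C); the writhe term is an empirical function of L/P
parameterized from Monte Carlo simulations of closed wormlike rings
(see :func:`writhe_variance` and ``scripts/calibrate_writhe.py``).

Lengths are in nm (n_bp * rise, rise 0.34 nm/bp by default), P in nm,
C in erg.cm (CGS), temperatures in K.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (
    K_B_ERG_PER_K,
    MOLEC_PER_NM3_TO_M,
    NM_PER_CM,
    RISE_NM_PER_BP,
    T_REF_K,
)

__all__ = [
    "MechanicalParams",
    "ContourLength",
    "TopoisomerSpec",
    "bend_jfactor",
    "linking_variance",
    "writhe_variance",
    "twist_factor",
    "jfactor_model",
]

#: L/P beyond which the closed-form bending approximation degrades.
BEND_VALIDITY_MAX_L_OVER_P = 6.0

# Empirical writhe-variance curve ln<Wr^2> = a + b ln(L/P) + c (L/P), frozen
# from crankshaft Monte Carlo of closed discrete wormlike rings (exact
# polygonal Gauss-integral writhe); see scripts/calibrate_writhe.py.
_WRITHE_COEFFS = (-7.0429, 2.2470, 0.0692)
#: L/P range spanned by the calibration; outside it the curve extrapolates.
_WRITHE_CALIBRATED_RANGE = (0.9, 3.2)


@dataclass(frozen=True)
class MechanicalParams:
    """Mechanical parameter triple of a DNA-like double helix.

    Attributes
    ----------
    P_nm:
        Bending persistence length (nm).
    gamma0_bp_per_turn:
        Helical repeat (base pairs per helical turn).
    C_erg_cm:
        Torsional rigidity (erg.cm, CGS).
    T_K:
        Absolute temperature (K) used for kT-dependent quantities.
    """

    P_nm: float
    gamma0_bp_per_turn: float
    C_erg_cm: float
    T_K: float = T_REF_K

    def __post_init__(self) -> None:
        if not self.P_nm > 0:
            raise ValueError(f"persistence length must be positive, got {self.P_nm}")
        if not 9.0 <= self.gamma0_bp_per_turn <= 12.0:
            raise ValueError(
                "helical repeat outside the plausible duplex range (9, 12): "
                f"{self.gamma0_bp_per_turn}"
            )
        if not self.C_erg_cm > 0:
            raise ValueError(f"torsional rigidity must be positive, got {self.C_erg_cm}")
        if not self.T_K > 0:
            raise ValueError(f"temperature must be positive, got {self.T_K}")
        if not math.isfinite(self.twist_persistence_nm):
            raise ValueError("derived twist persistence length is not finite")

    @property
    def twist_persistence_nm(self) -> float:
        """Twist persistence length P_t = C/(kT), in nm."""
        return self.C_erg_cm / (K_B_ERG_PER_K * self.T_K) * NM_PER_CM

    @classmethod
    def from_scaled(
        cls,
        P_nm: float,
        gamma0_bp_per_turn: float,
        C_1e19_erg_cm: float,
        T_K: float = T_REF_K,
    ) -> "MechanicalParams":
        """Build from C on the conventional 1e-19 erg.cm reporting scale."""
        return cls(P_nm, gamma0_bp_per_turn, C_1e19_erg_cm * 1e-19, T_K)

    def to_dict(self) -> dict:
        """Flat unit-suffixed mapping (C on the printed 1e-19 scale)."""
        return {
            "P_nm": self.P_nm,
            "gamma0_bp_per_turn": self.gamma0_bp_per_turn,
            "C_1e19_erg_cm": self.C_erg_cm * 1e19,
            "T_K": self.T_K,
            "Pt_nm": self.twist_persistence_nm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MechanicalParams":
        return cls.from_scaled(
            d["P_nm"], d["gamma0_bp_per_turn"], d["C_1e19_erg_cm"], d.get("T_K", T_REF_K)
        )


@dataclass(frozen=True)
class ContourLength:
    """Chain length as base pairs plus the axial rise converting bp to nm."""

    n_bp: int
    rise_nm_per_bp: float = RISE_NM_PER_BP

    def __post_init__(self) -> None:
        if self.n_bp < 1:
            raise ValueError(f"n_bp must be >= 1, got {self.n_bp}")
        if not self.rise_nm_per_bp > 0:
            raise ValueError("axial rise must be positive")

    @property
    def L_nm(self) -> float:
        return self.n_bp * self.rise_nm_per_bp


@dataclass(frozen=True)
class TopoisomerSpec:
    """Configuration of the topoisomer sum in the twist factor.

    ``window`` integer linking numbers nearest Lk0 are summed (odd, default
    7, which is converged to better than 1e-4 relative for the parameter
    regimes of ~200-bp DNA).  ``var_override_turns2`` replaces the computed
    linking-number variance, for sensitivity analyses.
    """

    window: int = 7
    var_override_turns2: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"topoisomer window must be odd and >= 1, got {self.window}")
        if self.var_override_turns2 is not None and self.var_override_turns2 < 0:
            raise ValueError("linking-number variance override must be >= 0")

    def with_window(self, window: int) -> "TopoisomerSpec":
        return replace(self, window=window)


def _as_length_nm(length) -> np.ndarray:
    """Accept a ContourLength, bp count or array of bp counts; return L in nm."""
    if isinstance(length, ContourLength):
        return np.asarray(length.L_nm, dtype=float)
    return np.asarray(length, dtype=float) * RISE_NM_PER_BP


def bend_jfactor(length, params: MechanicalParams) -> np.ndarray | float:
    """Torsion-free ring-closure factor J_bend in nM.

    ``length`` may be a :class:`ContourLength`, an integer bp count (axial
    rise 0.34 nm/bp implied), or an array of bp counts.  Emits a warning when
    L/P exceeds the validity range of the closed-form approximation.
    """
    L = _as_length_nm(length)
    if np.any(L <= 0):
        raise ValueError("contour length must be positive")
    P = params.P_nm
    ell = L / P
    if np.any(ell > BEND_VALIDITY_MAX_L_OVER_P):
        warnings.warn(
            f"L/P = {np.max(ell):.2f} exceeds {BEND_VALIDITY_MAX_L_OVER_P}; the "
            "closed-form bending factor degrades for long chains",
            stacklevel=2,
        )
    density = (
        112.04 * ell**-5.0 * np.exp(-14.054 / ell + 0.246 * ell) / (2.0 * P) ** 3
    )  # molecules / nm^3
    j_nM = density * MOLEC_PER_NM3_TO_M * 1e9
    return j_nM if j_nM.ndim else float(j_nM)


def writhe_variance(l_over_p) -> np.ndarray | float:
    """Variance of writhe (turns^2) of a closed wormlike ring of reduced length L/P.

    Empirical smooth curve frozen from Monte Carlo simulation of closed
    discrete wormlike rings; accurate to ~10% over L/P in [0.9, 3.2] and a
    smooth extrapolation outside.
    """
    ell = np.asarray(l_over_p, dtype=float)
    if np.any(ell <= 0):
        raise ValueError("reduced length must be positive")
    a, b, c = _WRITHE_COEFFS
    out = np.exp(a + b * np.log(ell) + c * ell)
    return out if out.ndim else float(out)


def linking_variance(length, params: MechanicalParams) -> np.ndarray | float:
    """Variance of the linking-number distribution of circles, in turns^2.

    Sum of the torsional fluctuation term L kT/(4 pi^2 C) and the empirical
    writhe term.  C -> infinity leaves the writhe-only floor.
    """
    L = _as_length_nm(length)
    if np.any(L <= 0):
        raise ValueError("contour length must be positive")
    L_cm = L / NM_PER_CM
    var_tw = L_cm * K_B_ERG_PER_K * params.T_K / (4.0 * math.pi**2 * params.C_erg_cm)
    var_wr = writhe_variance(L / params.P_nm)
    out = var_tw + var_wr
    return out if np.asarray(out).ndim else float(out)


def twist_factor(
    length, params: MechanicalParams, spec: TopoisomerSpec = TopoisomerSpec()
) -> np.ndarray | float:
    """Dimensionless torsional modulation of the J-factor.

    Gaussian-weighted sum over the ``spec.window`` integer linking numbers
    nearest Lk0 = n_bp/gamma0::

        F = sum_k (2 pi var)^-1/2 exp(-(k - Lk0)^2 / (2 var))

    F oscillates with helical phase: it peaks when Lk0 is integer (torsionally
    in-phase ends) and is minimal at half-integer Lk0.  For var -> infinity
    the sum approaches the flat-phase limit 1.
    """
    if isinstance(length, ContourLength):
        n_bp = np.asarray(length.n_bp, dtype=float)
    else:
        n_bp = np.asarray(length, dtype=float)
    lk0 = n_bp / params.gamma0_bp_per_turn
    if spec.var_override_turns2 is not None:
        var = np.asarray(spec.var_override_turns2, dtype=float)
    else:
        var = np.asarray(linking_variance(length, params), dtype=float)
    if np.any(var <= 0):
        raise ValueError("linking-number variance must be positive for the topoisomer sum")
    half = spec.window // 2
    nearest = np.round(lk0)
    offsets = np.arange(-half, half + 1, dtype=float)
    lk = nearest[..., None] + offsets
    dev2 = (lk - lk0[..., None]) ** 2
    weights = np.exp(-dev2 / (2.0 * var[..., None])) / np.sqrt(2.0 * math.pi * var[..., None])
    out = weights.sum(axis=-1)
    return out if out.ndim else float(out)


def jfactor_model(
    length, params: MechanicalParams, spec: TopoisomerSpec = TopoisomerSpec()
) -> np.ndarray | float:
    """Model J-factor in nM: bending envelope times torsional modulation.

    Oscillates in n_bp with period ~ gamma0, minima near half-integer
    n_bp/gamma0.
    """
    out = np.asarray(bend_jfactor(length, params)) * np.asarray(
        twist_factor(length, params, spec)
    )
    return out if out.ndim else float(out)
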