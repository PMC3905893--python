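"""Synthetic data generators emulating every input kind of the pipeline.

Each generator draws from the forward models of the analysis modules with
the noise structure the analysis assumes — multiplicative Gaussian noise on
J-factors (the same normal model used for Monte Carlo uncertainty),
additive Gaussian noise on band concentrations and melting signal — so
every fitting stage can be exercised in a closed loop against a known
truth.  Ground-truth parameters come from the bundled per-polymer presets
(``DNA1`` ... ``DNA9``); experimental designs default to the source
protocol: 1 nM starting material, lengths 201-211 bp, 1-min time points
over 1-15 min, dye levels 0.06/0.08/0.1/0.2x in triplicate.

All generators are deterministic under a fixed seed and return the truth
record alongside the data.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cd_hdr import CDSpectrum, classify_hdr
from .datasets import jfactor_rows, load_mechanical_presets, preset_params
from .ligation_kinetics import KineticRates, TimeCourse, simulate_ligation
from .melt_thermo import MeltCurve, two_state_signal
from .wlc_fit import JFactorDataset
from .wlc_model import MechanicalParams, TopoisomerSpec, jfactor_model

__all__ = [
    "GeneratorConfig",
    "HDR_PRESETS",
    "gen_jfactor_dataset",
    "gen_timecourse",
    "gen_meltcurves",
    "gen_cd_pairs",
    "preset_rates",
]

#: Target diagnostic ratios per polymer, consistent with the published
#: four-group memberships ({1,2,8} B-type, {3,4,7} B/Z-intermediate,
#: {5,6} Z-type, {9} A-type) and with the published ordering of torsional
#: rigidity (variant 9 the most A-like and stiffest in twist, variant 6 the
#: most Z-like and softest).
HDR_PRESETS = {
    "DNA1": 0.15,
    "DNA2": 0.25,
    "DNA3": -0.10,
    "DNA4": -0.25,
    "DNA5": -0.70,
    "DNA6": -1.10,
    "DNA7": -0.40,
    "DNA8": 0.40,
    "DNA9": 1.00,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed, preset and design knobs shared by the generators."""

    seed: int
    preset: str = "DNA1"
    # J-factor datasets
    lengths_bp: tuple = tuple(range(201, 212))
    jfactor_noise: float = 0.10
    # ligation time courses
    n_bp: int = 201
    M0_nM: float = 1.0
    times_s: tuple = tuple(60.0 * k for k in range(1, 16))
    timecourse_noise_nM: float = 0.02
    kC2_over_kC1: float = 10.0
    k_sink: float = 0.0
    # melting curves
    temp_C: tuple = (50.0, 100.0, 0.1)
    dye_levels: tuple = (0.06, 0.08, 0.1, 0.2)
    n_replicates: int = 3
    dH_kcal: float = 150.0
    dye_Tm_slope_C: float = 5.0
    dye_dH_slope_kcal: float = 0.0
    melt_noise: float = 0.01
    # CD spectra
    wavelength_nm: tuple = (200.0, 350.0, 0.1)
    cd_noise_mdeg: float = 0.0

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def gen_jfactor_dataset(
    config: GeneratorConfig,
    params: MechanicalParams | None = None,
    spec: TopoisomerSpec = TopoisomerSpec(),
) -> tuple[JFactorDataset, dict]:
    """Noisy J-factor dataset from the WLC forward model.

    J_mean = J_model * (1 + eps), eps ~ N(0, noise^2) truncated so means
    stay positive (redrawn); J_sd = noise * J_mean.  ``params`` overrides
    the preset truth.
    """
    rng = np.random.default_rng(config.seed)
    truth = params if params is not None else preset_params(config.preset)
    n_bp = np.asarray(config.lengths_bp, dtype=float)
    j_true = np.asarray(jfactor_model(n_bp, truth, spec), dtype=float)
    noise = config.jfactor_noise
    if noise > 0:
        eps = rng.normal(0.0, noise, size=j_true.shape)
        n_redraws = 0
        bad = eps <= -1.0
        while np.any(bad):
            n_redraws += int(bad.sum())
            eps[bad] = rng.normal(0.0, noise, size=int(bad.sum()))
            bad = eps <= -1.0
        j_mean = j_true * (1.0 + eps)
        j_sd = noise * j_mean
    else:
        n_redraws = 0
        j_mean = j_true.copy()
        j_sd = np.full_like(j_true, 1e-6)
    data = JFactorDataset(config.preset, n_bp, j_mean, j_sd)
    truth_record = {
        "kind": "jfactor",
        "preset": config.preset,
        "seed": config.seed,
        "noise": noise,
        "n_redraws": n_redraws,
        "params": truth.to_dict(),
        "J_true_nM": j_true.tolist(),
    }
    return data, truth_record


def preset_rates(label: str, n_bp: int, kC2_over_kC1: float = 10.0,
                 k_sink: float = 0.0) -> KineticRates:
    """Ground-truth ligation rates for a polymer/length from the bundled table.

    Rates are stored on the printed 1e-4 scale (1e-4/s and 1e-4/(nM s));
    dimer cyclization, not tabulated, defaults to a fast multiple of k_C1
    (dimer-length chains cyclize far more readily than ~200-bp monomers).
    """
    rows = jfactor_rows(label)
    row = rows[rows["n_bp"] == n_bp]
    if row.empty:
        raise KeyError(f"no tabulated rates for {label} at {n_bp} bp")
    k_C1 = float(row["kC1_1e4_per_s"].iloc[0]) * 1e-4
    k_D = float(row["kD_1e4_per_nM_s"].iloc[0]) * 1e-4
    return KineticRates(k_C1=k_C1, k_D=k_D, k_C2=kC2_over_kC1 * k_C1, k_sink=k_sink)


def gen_timecourse(
    config: GeneratorConfig, rates: KineticRates | None = None
) -> tuple[TimeCourse, dict]:
    """Noisy ligation time course from the mass-action forward model.

    Additive Gaussian noise (sd ``timecourse_noise_nM``) on each species
    concentration, floored at zero.  Mass balance holds exactly before
    noise injection.
    """
    rng = np.random.default_rng(config.seed)
    if rates is None:
        rates = preset_rates(
            config.preset, config.n_bp, config.kC2_over_kC1, config.k_sink
        )
    times = np.asarray(config.times_s, dtype=float)
    clean = simulate_ligation(rates, config.M0_nM, times)
    conc = clean.conc_nM.copy()
    if config.timecourse_noise_nM > 0:
        conc = conc + rng.normal(0.0, config.timecourse_noise_nM, size=conc.shape)
        conc = np.clip(conc, 0.0, None)
    noisy = TimeCourse(times, conc, config.M0_nM, sink_nM=clean.sink_nM)
    truth_record = {
        "kind": "timecourse",
        "preset": config.preset,
        "n_bp": config.n_bp,
        "seed": config.seed,
        "noise_nM": config.timecourse_noise_nM,
        "M0_nM": config.M0_nM,
        "rates": rates.to_dict(),
        "J_true_nM": rates.k_C1 / rates.k_D if rates.k_D > 0 else None,
    }
    return noisy, truth_record


def gen_meltcurves(config: GeneratorConfig) -> tuple[list[MeltCurve], dict]:
    """Two-state melting curves across dye levels with replicates.

    Tm rises linearly with dye concentration (slope ``dye_Tm_slope_C`` per
    1x dye), emulating reporter-dye stabilization, so linear extrapolation
    to zero dye recovers the preset Tm.  Signal is a folded (high) baseline
    melting to an unfolded (low) baseline, with additive Gaussian noise as
    a fraction of the transition amplitude.
    """
    rng = np.random.default_rng(config.seed)
    presets = load_mechanical_presets()
    tm0 = float(presets.loc[config.preset, "Tm_C"])
    lo, hi, step = config.temp_C
    T = np.arange(lo, hi + 0.5 * step, step)
    base_folded = (1.0, -0.0020)   # gain drift of the folded duplex signal
    base_melted = (0.15, -0.0005)
    curves = []
    for dye in config.dye_levels:
        tm = tm0 + config.dye_Tm_slope_C * dye
        dh = config.dH_kcal + config.dye_dH_slope_kcal * dye
        clean = two_state_signal(T, tm, dh, base_folded, base_melted)
        amp = abs(
            (base_folded[0] + base_folded[1] * tm) - (base_melted[0] + base_melted[1] * tm)
        )
        for _ in range(config.n_replicates):
            s = clean + rng.normal(0.0, config.melt_noise * amp, size=T.shape)
            curves.append(MeltCurve(T, s, dye=dye))
    truth_record = {
        "kind": "melt",
        "preset": config.preset,
        "seed": config.seed,
        "Tm0_C": tm0,
        "dH_kcal": config.dH_kcal,
        "dye_Tm_slope_C": config.dye_Tm_slope_C,
        "noise": config.melt_noise,
        "dye_levels": list(config.dye_levels),
        "n_replicates": config.n_replicates,
    }
    return curves, truth_record


def _gauss(x, center, width):
    return np.exp(-((x - center) ** 2) / (2.0 * width**2))


def gen_cd_pairs(
    config: GeneratorConfig, targets: dict[str, float] | None = None
) -> tuple[dict[str, CDSpectrum], dict]:
    """Smooth synthetic CD spectra hitting target diagnostic ratios.

    Each spectrum is a duplex-like shape (positive long-wavelength band,
    negative band near 245 nm) plus bands at the two diagnostic
    wavelengths adjusted so Theta(290)/Theta(201) equals the target exactly
    (before optional noise).  Defaults to the nine per-polymer targets in
    :data:`HDR_PRESETS`.
    """
    rng = np.random.default_rng(config.seed)
    if targets is None:
        targets = dict(HDR_PRESETS)
    lo, hi, step = config.wavelength_nm
    wl = np.arange(lo, hi + 0.5 * step, step)
    theta201 = 10.0  # mdeg at the denominator wavelength
    spectra = {}
    for label, hdr in targets.items():
        base = 3.0 * _gauss(wl, 275.0, 15.0) - 3.0 * _gauss(wl, 245.0, 12.0)
        b290 = 3.0 * np.exp(-0.5) - 3.0 * _gauss(np.array([290.0]), 245.0, 12.0)[0]
        b201 = (3.0 * _gauss(np.array([201.0]), 275.0, 15.0)
                - 3.0 * _gauss(np.array([201.0]), 245.0, 12.0))[()]
        a = hdr * theta201 - b290
        spec = base + a * _gauss(wl, 290.0, 12.0)
        a201 = a * _gauss(np.array([201.0]), 290.0, 12.0)[0]
        b = theta201 - b201 - a201
        spec = spec + b * _gauss(wl, 201.0, 8.0)
        if config.cd_noise_mdeg > 0:
            spec = spec + rng.normal(0.0, config.cd_noise_mdeg, size=wl.shape)
        spectra[label] = CDSpectrum(wl, spec)
    truth_record = {
        "kind": "cd",
        "seed": config.seed,
        "targets": dict(targets),
        "groups": {k: classify_hdr(v).group for k, v in targets.items()},
        "noise_mdeg": config.cd_noise_mdeg,
    }
    return spectra, truth_record
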