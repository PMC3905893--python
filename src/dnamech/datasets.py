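"""Bundled reference tables: published mechanical presets and J-factor data.

These are the printed per-polymer parameter sets (used as synthetic-data
ground truth and fit references) and the per-length J-factor / ligation-rate
table for the nine DNA-like polymers (natural DNA plus eight base-analog
variants).
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .wlc_model import MechanicalParams

PRESET_LABELS = [f"DNA{i}" for i in range(1, 10)]


def _read(name: str) -> pd.DataFrame:
    with resources.files("dnamech.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_mechanical_presets() -> pd.DataFrame:
    """Published per-polymer parameters (Tm, P, gamma0, C, Pt) with sds."""
    return _read("mechanical_presets.csv").set_index("label")


def load_jfactor_table() -> pd.DataFrame:
    """Published per-length J-factors (nM) and ligation rate constants."""
    return _read("jfactor_table.csv")


def preset_params(label: str) -> MechanicalParams:
    """Mechanical parameters of one polymer preset, e.g. ``"DNA1"``."""
    presets = load_mechanical_presets()
    if label not in presets.index:
        raise KeyError(f"unknown preset {label!r}; choose from {PRESET_LABELS}")
    row = presets.loc[label]
    return MechanicalParams.from_scaled(
        row["P_nm"], row["gamma0_bp_per_turn"], row["C_1e19_erg_cm"]
    )


def jfactor_rows(label: str) -> pd.DataFrame:
    """The J-factor table restricted to one polymer, sorted by length."""
    table = load_jfactor_table()
    rows = table[table["label"] == label].sort_values("n_bp")
    if rows.empty:
        raise KeyError(f"unknown polymer label {label!r}")
    return rows.reset_index(drop=True)
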