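"""CSV/JSON readers and writers for every pipeline data kind.

All CSVs are UTF-8, comma-separated with decimal points, unit-suffixed
headers, and ``#``-prefixed ``key=value`` metadata lines before the header.
Every writer's output is parsed by the matching reader to an equal
in-memory value (round-trip property).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cd_hdr import CDSpectrum
from .ligation_kinetics import TimeCourse
from .melt_thermo import MeltCurve
from .wlc_fit import JFactorDataset

__all__ = [
    "read_metadata",
    "write_jfactor_csv", "read_jfactor_csv",
    "write_timecourse_csv", "read_timecourse_csv",
    "write_melt_csv", "read_melt_csv",
    "write_cd_csv", "read_cd_csv",
    "write_report", "file_sha256",
]


def _write_csv(path, df: pd.DataFrame, metadata: dict | None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_metadata(path) -> dict:
    """Parse leading ``# key=value`` lines of a CSV."""
    meta = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def _read_csv(path) -> tuple[pd.DataFrame, dict]:
    return pd.read_csv(path, comment="#"), read_metadata(path)


def write_jfactor_csv(path, data: JFactorDataset, metadata: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "label": data.label,
            "n_bp": data.n_bp.astype(int),
            "J_nM": data.J_nM,
            "J_sd_nM": data.J_sd_nM,
        }
    )
    _write_csv(path, df, metadata)


def read_jfactor_csv(path, label: str | None = None) -> JFactorDataset:
    df, _ = _read_csv(path)
    return JFactorDataset.from_dataframe(df, label=label)


def write_timecourse_csv(path, tc: TimeCourse, metadata: dict | None = None) -> None:
    meta = {"M0_nM": repr(float(tc.M0_nM))}
    meta.update(metadata or {})
    df = pd.DataFrame(
        {
            "time_min": tc.times_s / 60.0,
            "M_nM": tc.conc_nM[:, 0],
            "D_nM": tc.conc_nM[:, 1],
            "CM_nM": tc.conc_nM[:, 2],
            "CD_nM": tc.conc_nM[:, 3],
        }
    )
    _write_csv(path, df, meta)


def read_timecourse_csv(path) -> TimeCourse:
    df, meta = _read_csv(path)
    if "M0_nM" not in meta:
        raise ValueError(f"{path}: missing '# M0_nM=' metadata line")
    conc = df[["M_nM", "D_nM", "CM_nM", "CD_nM"]].to_numpy()
    return TimeCourse(df["time_min"].to_numpy() * 60.0, conc, float(meta["M0_nM"]))


def write_melt_csv(path, curve: MeltCurve, metadata: dict | None = None) -> None:
    meta = {"dye": repr(float(curve.dye))}
    if curve.strand_conc_M is not None:
        meta["strand_conc_M"] = repr(float(curve.strand_conc_M))
    meta.update(metadata or {})
    df = pd.DataFrame({"temperature_C": curve.temperature_C, "signal": curve.signal})
    _write_csv(path, df, meta)


def read_melt_csv(path) -> MeltCurve:
    df, meta = _read_csv(path)
    strand = float(meta["strand_conc_M"]) if "strand_conc_M" in meta else None
    return MeltCurve(
        df["temperature_C"].to_numpy(),
        df["signal"].to_numpy(),
        dye=float(meta.get("dye", 0.0)),
        strand_conc_M=strand,
    )


def write_cd_csv(path, spectrum: CDSpectrum, metadata: dict | None = None) -> None:
    df = pd.DataFrame(
        {"wavelength_nm": spectrum.wavelength_nm, "theta_mdeg": spectrum.ellipticity_mdeg}
    )
    _write_csv(path, df, metadata)


def read_cd_csv(path) -> CDSpectrum:
    df, _ = _read_csv(path)
    return CDSpectrum(df["wavelength_nm"].to_numpy(), df["theta_mdeg"].to_numpy())


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class _Encoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, np.bool_):
            return bool(obj)
        return super().default(obj)


def write_report(path, payload: dict, inputs: list | None = None) -> None:
    """Write a JSON report with provenance (input hashes, package version)."""
    from . import __version__

    report = dict(payload)
    report["provenance"] = {
        "dnamech_version": __version__,
        "inputs": {str(p): file_sha256(p) for p in (inputs or [])},
    }
    Path(path).write_text(
        json.dumps(report, indent=2, cls=_Encoder, sort_keys=False) + "\n",
        encoding="utf-8",
    )
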