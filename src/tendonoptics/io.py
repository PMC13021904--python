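"""CSV/YAML/JSON input-output and provenance helpers.

CSV dialect: comma-separated UTF-8, mandatory header, ``#`` comment lines
carrying ``key = value`` metadata.  Angles are degrees and wavelengths nm at
the file boundary; everything internal is mm and mm^-1.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ParseError
from .phase_function import AngularScan
from .spectral_inversion import ScatterModelFit, SpectrumMeasurement

__all__ = [
    "read_angular_csv",
    "write_angular_csv",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_config",
    "provenance",
    "fit_to_json",
    "fit_curves_to_csv",
]

logger = logging.getLogger(__name__)


def _read_metadata(path: Path) -> dict[str, str]:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def _read_table(path, required: tuple[str, ...], hint: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: could not parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing column(s) {missing}; expected header '{hint}'"
        )
    dup = [c for c in required if list(df.columns).count(c) > 1]
    if dup:
        raise ParseError(f"{path}: duplicate column(s) {dup}")
    for col in required:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            # +2: 1-based line numbers plus the header line (comments excluded)
            raise ParseError(
                f"{path}: non-numeric value in column '{col}' at data row "
                f"{row + 1} (line {row + 2} excluding comments)"
            )
        df[col] = vals
    return df


def read_angular_csv(path) -> AngularScan:
    """Read a goniometer scan (``theta_deg,intensity`` with # metadata).

    Shuffled angle rows are sorted with a warning; duplicate angles are an
    error.
    """
    path = Path(path)
    df = _read_table(path, ("theta_deg", "intensity"), "theta_deg,intensity")
    meta = _read_metadata(path)
    theta = df["theta_deg"].to_numpy(float)
    inten = df["intensity"].to_numpy(float)
    if np.any(np.diff(theta) <= 0):
        if np.unique(theta).size != theta.size:
            raise ParseError(f"{path}: duplicate theta_deg values")
        logger.warning("%s: theta rows not sorted; sorting", path)
        order = np.argsort(theta)
        theta, inten = theta[order], inten[order]
    try:
        return AngularScan(
            theta_deg=theta, intensity=inten,
            wavelength_nm=float(meta.get("wavelength_nm", 633.0)),
            orientation=meta.get("orientation") or None,
            condition=meta.get("condition") or None,
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_angular_csv(scan: AngularScan, path) -> None:
    from .synthetic import _scan_to_csv

    _scan_to_csv(scan, Path(path))


def read_spectra_csv(path) -> SpectrumMeasurement:
    """Read Rd/Tt spectra (``wavelength_nm,Rd,Tt``); requires ``# thickness_mm``."""
    path = Path(path)
    df = _read_table(path, ("wavelength_nm", "Rd", "Tt"), "wavelength_nm,Rd,Tt")
    meta = _read_metadata(path)
    if "thickness_mm" not in meta:
        raise ParseError(
            f"{path}: missing '# thickness_mm = <value>' metadata line "
            "(slab thickness is required for inversion)"
        )
    wl = df["wavelength_nm"].to_numpy(float)
    rd = df["Rd"].to_numpy(float)
    tt = df["Tt"].to_numpy(float)
    if np.any(np.diff(wl) <= 0):
        if np.unique(wl).size != wl.size:
            raise ParseError(f"{path}: duplicate wavelengths")
        logger.warning("%s: wavelength rows not sorted; sorting", path)
        order = np.argsort(wl)
        wl, rd, tt = wl[order], rd[order], tt[order]
    try:
        return SpectrumMeasurement(
            wavelength_nm=wl, rd=rd, tt=tt,
            thickness_mm=float(meta["thickness_mm"]),
            orientation=meta.get("orientation") or None,
            condition=meta.get("condition") or None,
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_spectra_csv(meas: SpectrumMeasurement, path) -> None:
    from .synthetic import _spectra_to_csv

    _spectra_to_csv(meas, Path(path))


def read_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a YAML mapping")
    return cfg


def provenance(seed=None, config: dict | None = None) -> dict:
    """Provenance block embedded in every written artifact."""
    blob = json.dumps(config, sort_keys=True, default=str) if config else ""
    return {
        "tool": "tendonoptics",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest() if blob else None,
    }


def fit_to_json(fit: ScatterModelFit, path, seed=None, config=None) -> None:
    out = {
        "Wt": fit.wt, "a_mm^-1": fit.a, "b": fit.b, "K": fit.k,
        "residual": fit.residual,
        "provenance": provenance(seed=seed, config=config),
    }
    Path(path).write_text(json.dumps(out, indent=2) + "\n")


def fit_curves_to_csv(fit: ScatterModelFit, path) -> None:
    pd.DataFrame(
        {
            "wavelength_nm": fit.wavelength_nm,
            "mua_mm^-1": fit.mua,
            "musp_mm^-1": fit.musp,
        }
    ).to_csv(path, index=False)
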