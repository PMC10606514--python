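"""CSV readers/writers and run manifests.

Heat-curve file format
----------------------
A curve lives in two small plain-text files:

``<name>.csv`` — one row per injection, header required::

    injection_index,injection_volume_uL,heat_ucal
    1,10.0,-42.13
    ...

``<name>.meta.yaml`` — schedule and stated-concentration metadata::

    V0_mL: 1.43
    temperature_K: 298.15
    stated_R0_mM: 0.1
    stated_Ls_mM: 1.0
    label: optional free text

Heats are stored in ucal (instrument display units) and converted to the
canonical cal on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding_model import (
    CAL_PER_UCAL,
    UCAL_PER_CAL,
    HeatCurve,
    InjectionSchedule,
    ThermoParams,
)

__all__ = [
    "read_heat_curve",
    "write_heat_curve",
    "write_truths",
    "read_truths",
    "write_manifest",
]

REQUIRED_COLUMNS = ("injection_index", "injection_volume_uL", "heat_ucal")
REQUIRED_META = ("V0_mL", "temperature_K", "stated_R0_mM", "stated_Ls_mM")


class SchemaError(ValueError):
    """A heat-curve file violates the documented schema."""


def meta_path_for(csv_path: str | Path) -> Path:
    """Sidecar metadata path for a curve CSV (``x.csv`` -> ``x.meta.yaml``)."""
    p = Path(csv_path)
    return p.with_name(p.stem + ".meta.yaml")


def read_heat_curve(path: str | Path, meta_path: str | Path | None = None) -> HeatCurve:
    """Read a heat curve from CSV plus its metadata sidecar.

    Validates the schema row by row and converts units to canonical
    (heats ucal -> cal).
    """
    path = Path(path)
    if meta_path is None:
        meta_path = meta_path_for(path)
    meta_path = Path(meta_path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not meta_path.exists():
        raise FileNotFoundError(
            f"metadata sidecar {meta_path} not found for curve {path}"
        )
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    idx = df["injection_index"].to_numpy()
    if not np.array_equal(idx, np.arange(1, len(df) + 1)):
        bad = int(np.argmax(idx != np.arange(1, len(df) + 1))) + 1
        raise SchemaError(
            f"{path}: injection_index must be 1..N in order (first bad row {bad})"
        )
    vols = df["injection_volume_uL"].to_numpy(dtype=float)
    if np.any(vols <= 0):
        row = int(np.argmax(vols <= 0)) + 1
        raise SchemaError(
            f"{path}: non-positive injection_volume_uL at row {row}"
        )
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh) or {}
    for key in REQUIRED_META:
        if key not in meta:
            raise SchemaError(f"{meta_path}: missing required key '{key}'")
    schedule = InjectionSchedule(
        V0=float(meta["V0_mL"]),
        volumes=tuple(vols),
        temperature=float(meta["temperature_K"]),
    )
    return HeatCurve(
        heats=df["heat_ucal"].to_numpy(dtype=float) / UCAL_PER_CAL,
        schedule=schedule,
        stated_R0=float(meta["stated_R0_mM"]),
        stated_Ls=float(meta["stated_Ls_mM"]),
        label=str(meta.get("label", path.stem)),
    )


def write_heat_curve(curve: HeatCurve, path: str | Path) -> tuple[Path, Path]:
    """Write a curve to CSV + metadata sidecar; returns both paths."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "injection_index": np.arange(1, curve.N + 1),
            "injection_volume_uL": np.asarray(curve.schedule.volumes),
            "heat_ucal": curve.heats * UCAL_PER_CAL,
        }
    )
    df.to_csv(path, index=False)
    meta = {
        "V0_mL": float(curve.schedule.V0),
        "temperature_K": float(curve.schedule.temperature),
        "stated_R0_mM": float(curve.stated_R0),
        "stated_Ls_mM": float(curve.stated_Ls),
        "label": curve.label,
    }
    mp = meta_path_for(path)
    with open(mp, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path, mp


def write_truths(truths, path: str | Path) -> Path:
    """One row per curve of realized true parameters (display units)."""
    rows = [
        {
            "curve_index": i,
            "dG_kcal_per_mol": t.dG,
            "dH_kcal_per_mol": t.dH,
            "dH0_ucal": t.dH0 * UCAL_PER_CAL,
            "R0_mM": t.R0,
            "Ls_mM": t.Ls,
            "sigma_ucal": t.sigma * UCAL_PER_CAL,
        }
        for i, t in enumerate(truths)
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_truths(path: str | Path) -> list[ThermoParams]:
    df = pd.read_csv(path)
    return [
        ThermoParams(
            dG=r.dG_kcal_per_mol,
            dH=r.dH_kcal_per_mol,
            dH0=r.dH0_ucal * CAL_PER_UCAL,
            R0=r.R0_mM,
            Ls=r.Ls_mM,
            sigma=r.sigma_ucal * CAL_PER_UCAL,
        )
        for r in df.itertuples()
    ]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    config: dict,
    outputs: list[str | Path],
    name: str = "manifest.json",
) -> Path:
    """Record the run configuration and output checksums for reproducibility."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "package_version": __version__,
        "config": config,
        "outputs": {
            str(Path(p).name): _sha256(Path(p)) for p in outputs if Path(p).exists()
        },
    }
    path = out_dir / name
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
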