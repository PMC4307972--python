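"""File I/O: adsorption CSV datasets, config files, result serialisation.

CSV dialect is comma-separated with a required header and no index column;
configs are flat key-value JSON or YAML; structured results go to JSON.
These are plain tabular biophysical measurements, so no domain-specific
container format applies.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .fitting import AdsorptionDataset, FitResult, REQUIRED_COLUMNS
from .localization import LocalizationCurve, TwoRegionSystem
from .model import ConfigurationError, RepulsionLaw

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_config",
    "write_config",
    "law_from_config",
    "two_region_system_from_config",
    "write_fit_result",
    "write_localization_curve",
    "read_localization_curve",
]

PathLike = Union[str, Path]


def read_dataset(path: PathLike) -> AdsorptionDataset:
    """Read an adsorption CSV; malformed rows are reported with line numbers.

    Required columns: radius_um, concentration, adsorption.  Optional:
    sigma, label.  Line numbers in error messages count the header as
    line 1.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    numeric = ["radius_um", "concentration", "adsorption"] + (
        ["sigma"] if "sigma" in df.columns else []
    )
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad]
            raise ValueError(f"{path}: non-numeric {col!r} on line(s) {lines}")
        df[col] = coerced
    bad = df.index[df["radius_um"].isna() | (df["radius_um"] <= 0)]
    if len(bad):
        lines = [int(i) + 2 for i in bad]
        raise ValueError(f"{path}: nonpositive or missing radius_um on line(s) {lines}")
    bad = df.index[df["adsorption"].isna() | (df["adsorption"] < 0)]
    if len(bad):
        lines = [int(i) + 2 for i in bad]
        raise ValueError(f"{path}: negative or missing adsorption on line(s) {lines}")
    return AdsorptionDataset(df)


def write_dataset(dataset: AdsorptionDataset, path: PathLike) -> None:
    dataset.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

_LAW_KEYS = {"law.kind", "law.c1", "law.c2", "law.e_r0", "law.k_max"}
_MODEL_KEYS = _LAW_KEYS | {"eps_b", "eps_nn", "a_nm", "tol"}
_LOCALIZE_KEYS = {
    "delta_b", "eps_b", "rel_delta", "e_r0", "k_max", "K_cap",
    "area_ratio", "Cs_grid",
}
_SIMULATE_KEYS = _LAW_KEYS | {
    "A", "c_0", "radii", "concentrations", "noise_cv", "replicates",
    "seed", "label",
}

_SCHEMAS = {
    "model": _MODEL_KEYS,
    "localize": _LOCALIZE_KEYS,
    "simulate": _SIMULATE_KEYS,
}


def read_config(path: PathLike, schema: str | None = None) -> dict:
    """Read a flat key-value config (JSON or YAML, chosen by extension).

    With ``schema`` given ('model' | 'localize' | 'simulate'), unknown keys
    are rejected rather than silently ignored.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a key-value mapping")
    # nested {"law": {...}} form is flattened to dotted keys
    if isinstance(cfg.get("law"), dict):
        law = cfg.pop("law")
        for k, v in law.items():
            cfg[f"law.{k}"] = v
    if schema is not None:
        allowed = _SCHEMAS[schema]
        unknown = sorted(set(cfg) - allowed)
        if unknown:
            raise ConfigurationError(
                f"{path}: unknown config key(s) {unknown}; "
                f"allowed: {sorted(allowed)}"
            )
    return cfg


def write_config(cfg: dict, path: PathLike) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))


def law_from_config(cfg: dict) -> RepulsionLaw:
    """Build a RepulsionLaw from dotted ``law.*`` config keys."""
    kind = cfg.get("law.kind")
    if kind is None:
        raise ConfigurationError("config missing 'law.kind'")
    kwargs = {"kind": kind}
    for key, name in (("law.c1", "c1"), ("law.c2", "c2"), ("law.e_r0", "e_r0")):
        if key in cfg:
            kwargs[name] = float(cfg[key])
    if "law.k_max" in cfg:
        kwargs["k_max"] = int(cfg["law.k_max"])
    return RepulsionLaw(**kwargs)


def two_region_system_from_config(cfg: dict) -> tuple[TwoRegionSystem, list[float]]:
    """Build the two-region system plus its C_s grid from a localize config."""
    grid = cfg.get("Cs_grid")
    if not grid:
        raise ConfigurationError("localize config missing 'Cs_grid'")
    kwargs = {}
    for key in ("delta_b", "eps_b", "rel_delta", "e_r0", "area_ratio"):
        if key in cfg:
            kwargs[key] = float(cfg[key])
    for key in ("k_max", "K_cap"):
        if key in cfg:
            kwargs[key] = int(cfg[key])
    return TwoRegionSystem(**kwargs), [float(c) for c in grid]


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def write_fit_result(result: FitResult, path: PathLike) -> None:
    Path(path).write_text(result.to_json() + "\n")


def write_localization_curve(curve: LocalizationCurve, path: PathLike) -> None:
    """Delimited text with the seven named columns."""
    curve.to_frame().to_csv(path, index=False)


def read_localization_curve(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LocalizationCurve.COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing localization column(s) {missing}")
    return df
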