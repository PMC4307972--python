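"""Synthetic adsorption datasets with the structure the analysis assumes.

The vesicle-adsorption measurements the model was built against were never
deposited, so every pipeline stage is exercised on generated data instead:
adsorption surfaces A·C_v(c/c_0, e_r(r)) over a radius grid spanning
0.75–30 μm (the experimental range) and a concentration grid, corrupted by
mean-one multiplicative lognormal noise.  Positive intensity-like signals
make multiplicative noise the natural default error structure.

Defaults are the study conditions: the tension law with the wild-type
best-fit coefficients (c1 = 0.7 k_B·T, c2 = 0.61 k_B·T·μm⁻¹), radii
including 0.75, 1.75 and 3.25 μm, and 5% noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .localization import LocalizationCurve, TwoRegionSystem, localization_curve
from .model import DivergenceError, RepulsionLaw, adsorption, e_r_of_radius, series_converges
from .fitting import AdsorptionDataset

__all__ = ["GeneratorSpec", "generate_dataset", "generate_localization_inputs",
           "DEFAULT_RADII_UM", "DEFAULT_CONCENTRATIONS"]

#: radius grid (μm) emulating the experimental design: vesicles from
#: (just under) 1 to 30 μm, including the three radii highlighted in the
#: isotherm analysis (0.75, 1.75, 3.25)
DEFAULT_RADII_UM = (0.75, 1.0, 1.75, 2.5, 3.25, 5.0, 7.5, 10.0, 15.0, 20.0, 25.0, 30.0)

#: concentration grid (arbitrary units) spanning the linear through the
#: cooperative regime at the default scale c_0 = 1
DEFAULT_CONCENTRATIONS = (0.05, 0.1, 0.2, 0.35, 0.5, 0.75, 1.0, 1.4, 1.9, 2.5)


@dataclass(frozen=True)
class GeneratorSpec:
    """Full recipe for one synthetic dataset; same seed ⇒ same dataset."""

    law: RepulsionLaw = RepulsionLaw(kind="tension", c1=0.7, c2=0.61)
    A: float = 1.0
    c_0: float = 1.0
    radii: Sequence[float] = DEFAULT_RADII_UM
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS
    noise_cv: float = 0.05
    replicates: int = 1
    seed: int = 0
    label: str = "VM"

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if len(self.radii) == 0 or any(r <= 0 for r in self.radii):
            raise ValueError("radius grid must be positive and nonempty")
        if len(self.concentrations) == 0 or any(c <= 0 for c in self.concentrations):
            raise ValueError("concentration grid must be positive and nonempty")

    def to_json(self) -> str:
        d = asdict(self)
        d["law"] = {k: v for k, v in asdict(self.law).items() if v is not None}
        d["radii"] = list(self.radii)
        d["concentrations"] = list(self.concentrations)
        return json.dumps(d, indent=2)


def generate_dataset(spec: GeneratorSpec) -> AdsorptionDataset:
    """Generate adsorption records from the model surface plus noise.

    adsorption_ij = A·C_v(c_j/c_0, e_r(r_i))·exp(ε) with
    ε ~ Normal(−noise_cv²/2, noise_cv), so the noise is mean-one
    multiplicative; the ``sigma`` column is noise_cv times the deterministic
    value.  A spec whose grid contains a divergent (C_s, e_r) combination is
    rejected up front with the offending grid points listed.
    """
    bad = [
        (r, c)
        for r in spec.radii
        for c in spec.concentrations
        if not series_converges(c / spec.c_0, e_r_of_radius(r, spec.law))
    ]
    if bad:
        raise DivergenceError(
            f"generator spec implies divergent adsorption at (radius, "
            f"concentration) points: {bad[:10]}"
            + ("..." if len(bad) > 10 else "")
        )
    rng = np.random.default_rng(spec.seed)
    rows = {k: [] for k in ("radius_um", "concentration", "adsorption", "sigma", "label")}
    for r in spec.radii:
        e_r = e_r_of_radius(r, spec.law)
        for c in spec.concentrations:
            mean = spec.A * adsorption(c / spec.c_0, e_r)
            for _ in range(spec.replicates):
                eps = rng.normal(-0.5 * spec.noise_cv**2, spec.noise_cv) if spec.noise_cv > 0 else 0.0
                rows["radius_um"].append(r)
                rows["concentration"].append(c)
                rows["adsorption"].append(mean * math.exp(eps))
                rows["sigma"].append(spec.noise_cv * mean if spec.noise_cv > 0 else np.nan)
                rows["label"].append(spec.label)
    df = pd.DataFrame(rows)
    if spec.noise_cv == 0:
        df = df.drop(columns=["sigma"])
    return AdsorptionDataset(df)


def generate_localization_inputs(
    system: TwoRegionSystem,
    C_s_grid: Sequence[float],
) -> tuple[dict, LocalizationCurve]:
    """Config block plus the oracle-computed localization curve.

    The returned config round-trips through the interface layer and the
    curve serves as the frozen expected output for regression tests.
    """
    config = {
        "delta_b": system.delta_b,
        "e_r0": system.e_r0,
        "k_max": system.k_max,
        "K_cap": system.K_cap,
        "area_ratio": system.area_ratio,
        "Cs_grid": [float(c) for c in C_s_grid],
    }
    return config, localization_curve(system, C_s_grid)
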