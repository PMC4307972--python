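"""Fitting curvature- vs tension-dependent repulsion laws to adsorption data.

Observed adsorption (arbitrary units) at vesicle radius r and bath
concentration c is modelled as

    y(r, c) = A · C_v(c / c_0, e_r(r)),

with the amplitude A and concentration scale c_0 free nuisance parameters
(both experimental axes are in arbitrary units) and e_r(r) one of the two
competing laws: curvature, e_r = c1 − c2/r, or tension, e_r = c1 + c2·r.

The two laws are discriminated by weighted least squares from identical
multi-start boxes.  The curvature law carries a built-in diagnostic: with
c1, c2 > 0 its repulsion crosses zero at r_div = c2/c1, below which the
adsorption series diverges — fitted divergence radii close to the measured
radius range are the signature that the curvature form is unphysical for
this data.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import (
    DivergenceError,
    RepulsionLaw,
    adsorption,
    e_r_of_radius,
    series_converges,
)

__all__ = [
    "AdsorptionDataset",
    "FitResult",
    "predict_adsorption",
    "fit_radius_profile",
    "fit_concentration_profiles",
    "divergence_radius",
    "compare_models",
    "ModelComparison",
]

REQUIRED_COLUMNS = ("radius_um", "concentration", "adsorption")
OPTIONAL_COLUMNS = ("sigma", "label")

#: residual magnitude assigned to divergent parameter proposals; a finite
#: penalty keeps optimisation alive near the curvature law's divergence
#: boundary instead of raising
_PENALTY = 1e8


@dataclass
class AdsorptionDataset:
    """Tabular adsorption measurements: one row per (radius, concentration).

    Columns: ``radius_um`` (μm), ``concentration`` and ``adsorption``
    (arbitrary units), optional ``sigma`` (measurement s.d., adsorption
    units) and ``label`` (e.g. VM / VM_P9A).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing required column(s): {missing}")
        bad = df.index[df["radius_um"] <= 0].tolist()
        if bad:
            raise ValueError(f"nonpositive radius_um in rows {bad}")
        bad = df.index[df["adsorption"] < 0].tolist()
        if bad:
            raise ValueError(f"negative adsorption in rows {bad}")

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AdsorptionDataset):
            return NotImplemented
        a = self.frame.reset_index(drop=True)
        b = other.frame.reset_index(drop=True)
        return a.equals(b)

    @property
    def radii(self) -> np.ndarray:
        return np.unique(self.frame["radius_um"].to_numpy())

    @property
    def concentrations(self) -> np.ndarray:
        return np.unique(self.frame["concentration"].to_numpy())

    def weights(self) -> np.ndarray:
        """Least-squares weights 1/sigma (unit weights when sigma absent)."""
        if "sigma" in self.frame.columns and self.frame["sigma"].notna().all():
            s = self.frame["sigma"].to_numpy(dtype=float)
            if np.any(s <= 0):
                raise ValueError("sigma values must be positive")
            return 1.0 / s
        return np.ones(len(self.frame))

    @classmethod
    def from_arrays(cls, radius_um, concentration, adsorption, sigma=None, label=None):
        data = {
            "radius_um": np.asarray(radius_um, dtype=float),
            "concentration": np.asarray(concentration, dtype=float),
            "adsorption": np.asarray(adsorption, dtype=float),
        }
        if sigma is not None:
            data["sigma"] = np.asarray(sigma, dtype=float)
        if label is not None:
            data["label"] = label
        return cls(pd.DataFrame(data))


@dataclass
class FitResult:
    """Best-fit repulsion-law parameters and diagnostics."""

    law_kind: str
    c1: float
    c2: float
    A: float
    c_0: Optional[float]            #: concentration scale (concentration fits)
    C_s: Optional[float]            #: fixed effective concentration (radius fits)
    objective: float                #: weighted sum of squared residuals
    covariance: Optional[np.ndarray]
    converged: bool
    divergence_radius: Optional[float]
    warnings: list = field(default_factory=list)
    n_starts: int = 0
    seed: Optional[int] = None

    @property
    def law(self) -> RepulsionLaw:
        return RepulsionLaw(kind=self.law_kind, c1=self.c1, c2=self.c2)

    def to_json(self, **kwargs) -> str:
        d = {
            "law_kind": self.law_kind,
            "c1": self.c1,
            "c2": self.c2,
            "A": self.A,
            "c_0": self.c_0,
            "C_s": self.C_s,
            "objective": self.objective,
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "converged": bool(self.converged),
            "divergence_radius": self.divergence_radius,
            "warnings": list(self.warnings),
            "n_starts": self.n_starts,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2, **kwargs)


# ---------------------------------------------------------------------------
# Forward prediction
# ---------------------------------------------------------------------------

def predict_adsorption(
    r, c, law: RepulsionLaw, A: float, c_0: float = 1.0
) -> np.ndarray | float:
    """Predicted adsorption A·C_v(c/c_0, e_r(r)) in the data's units."""
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    c_arr = np.atleast_1d(np.asarray(c, dtype=float))
    r_arr, c_arr = np.broadcast_arrays(r_arr, c_arr)
    out = np.empty(r_arr.shape)
    for i, (ri, ci) in enumerate(zip(r_arr.ravel(), c_arr.ravel())):
        e_r = e_r_of_radius(ri, law)
        C_s = ci / c_0
        if not series_converges(C_s, e_r):
            raise DivergenceError(
                f"prediction diverges at r={ri:g} μm under {law.kind} law "
                f"(e_r={e_r:g}, C_s={C_s:g})"
            )
        out.ravel()[i] = A * adsorption(C_s, e_r)
    return out if np.ndim(r) or np.ndim(c) else float(out.ravel()[0])


def divergence_radius(law: RepulsionLaw) -> Optional[float]:
    """Radius (μm) where a curvature law's repulsion crosses zero.

    r_div = c2/c1; below it the adsorption series diverges.  None for laws
    with e_r > 0 at every radius (tension/constant with positive
    coefficients) or without positive c1, c2.
    """
    if law.kind == "curvature" and law.c1 > 0 and law.c2 > 0:
        return law.c2 / law.c1
    return None


# ---------------------------------------------------------------------------
# Objective machinery
# ---------------------------------------------------------------------------

def _safe_model(r, C_s, e_r):
    """Adsorption C_v or None when divergent (penalised, not raised).

    Covers both outright divergence and effectively-divergent proposals
    whose series exceed the truncation cap (e.g. e_r → 0⁺ at large C_s).
    """
    if not series_converges(C_s, e_r):
        return None
    try:
        return adsorption(C_s, e_r)
    except DivergenceError:
        return None


def _residuals_factory(radii, C_s_of_theta, e_r_of_theta, A_of_theta, y, w, log_space):
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)

    def residuals(theta):
        A = A_of_theta(theta)
        out = np.empty(y.size)
        for i, r in enumerate(radii):
            e_r = e_r_of_theta(theta, r)
            C_s = C_s_of_theta(theta, i)
            if not (math.isfinite(C_s) and math.isfinite(e_r) and C_s >= 0):
                return np.full(y.size, _PENALTY)
            cv = _safe_model(r, C_s, e_r)
            if cv is None or not math.isfinite(cv):
                return np.full(y.size, _PENALTY)
            pred = A * cv
            if log_space:
                if pred <= 0 or y[i] <= 0:
                    return np.full(y.size, _PENALTY)
                out[i] = w[i] * (math.log(pred) - math.log(y[i]))
            else:
                out[i] = w[i] * (pred - y[i])
        # keep extreme (but convergent) proposals finite for the optimizer
        return np.clip(out, -_PENALTY, _PENALTY)

    return residuals


def _multistart_least_squares(residuals, starts):
    """Local refinement from each start; best cost wins.

    Starts that land in the divergence-penalty region are skipped up front
    (the penalty plateau carries no gradient information) unless no feasible
    start exists.
    """
    feasible = [x0 for x0 in starts
                if np.abs(residuals(x0)).max() < 0.5 * _PENALTY]
    if not feasible:
        feasible = starts[:4]
    best = None
    for x0 in feasible:
        try:
            res = least_squares(
                residuals, x0, method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=400,
            )
        except Exception:  # pragma: no cover - optimizer edge cases
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimisation starts failed")
    return best


def _covariance(res, n_params):
    """Gauss–Newton covariance estimate from the final Jacobian."""
    try:
        J = res.jac
        dof = max(1, J.shape[0] - n_params)
        s2 = 2.0 * res.cost / dof
        return s2 * np.linalg.pinv(J.T @ J)
    except Exception:  # pragma: no cover
        return None


def _start_box(rng, n, data_scale):
    """Log-uniform starts over a broad box: c1, c2 ∈ [0.05, 5], A near data."""
    c1 = np.exp(rng.uniform(math.log(0.05), math.log(5.0), n))
    c2 = np.exp(rng.uniform(math.log(0.02), math.log(5.0), n))
    A = data_scale * np.exp(rng.uniform(math.log(0.1), math.log(10.0), n))
    return c1, c2, A


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------

def fit_radius_profile(
    dataset: AdsorptionDataset,
    law_kind: str,
    C_s: float = 1.0,
    fit_Cs: bool = False,
    n_starts: int = 16,
    seed: int = 0,
    log_space: bool = False,
) -> FitResult:
    """Fit (c1, c2, A) to an adsorption-vs-radius profile at one concentration.

    The dataset must hold a single concentration slice over at least three
    distinct radii.  The effective normalised concentration C_s is held fixed
    by default (A and c_0 are not separately identifiable from one slice);
    ``fit_Cs=True`` frees it as a fourth parameter.
    """
    if law_kind not in ("curvature", "tension"):
        raise ValueError(f"law_kind must be 'curvature' or 'tension', got {law_kind!r}")
    df = dataset.frame
    radii = df["radius_um"].to_numpy(dtype=float)
    y = df["adsorption"].to_numpy(dtype=float)
    w = dataset.weights()
    notes = []
    if dataset.concentrations.size > 1:
        raise ValueError(
            "radius-profile fit expects a fixed-concentration slice; "
            f"found {dataset.concentrations.size} distinct concentrations"
        )
    if dataset.radii.size < 3:
        raise ValueError("radius-profile fit needs at least 3 distinct radii")
    if np.ptp(y) < 1e-12 * max(1.0, np.max(np.abs(y))):
        notes.append("identifiability: adsorption is constant across radii; "
                     "c2 is unconstrained")

    sign = -1.0 if law_kind == "curvature" else 1.0

    def e_r_of(theta, r):
        c1, c2 = math.exp(theta[0]), math.exp(theta[1])
        return c1 + sign * c2 * (1.0 / r if law_kind == "curvature" else r)

    if fit_Cs:
        def C_s_of(theta, i):
            return math.exp(theta[3])
    else:
        def C_s_of(theta, i):
            return C_s

    residuals = _residuals_factory(
        radii, C_s_of, e_r_of, lambda th: math.exp(th[2]), y, w, log_space
    )

    rng = np.random.default_rng(seed)
    n_params = 4 if fit_Cs else 3
    c1s, c2s, As = _start_box(rng, n_starts, max(np.max(y), 1e-12))
    starts = []
    for c1_0, c2_0, A_0 in zip(c1s, c2s, As):
        th = [math.log(c1_0), math.log(c2_0), math.log(A_0)]
        if fit_Cs:
            th.append(rng.uniform(math.log(0.1), math.log(5.0)))
        starts.append(np.array(th))

    best = _multistart_least_squares(residuals, starts)
    c1, c2, A = math.exp(best.x[0]), math.exp(best.x[1]), math.exp(best.x[2])
    law = RepulsionLaw(kind=law_kind, c1=c1, c2=c2)
    return FitResult(
        law_kind=law_kind,
        c1=c1,
        c2=c2,
        A=A,
        c_0=None,
        C_s=math.exp(best.x[3]) if fit_Cs else C_s,
        objective=float(2.0 * best.cost),
        covariance=_covariance(best, n_params),
        converged=bool(best.success and 2.0 * best.cost < _PENALTY),
        divergence_radius=divergence_radius(law),
        warnings=notes,
        n_starts=n_starts,
        seed=seed,
    )


def fit_concentration_profiles(
    dataset: AdsorptionDataset,
    law_kind: str,
    n_starts: int = 16,
    seed: int = 0,
    log_space: bool = False,
) -> FitResult:
    """Fit shared (c1, c2, A, c_0) to isotherms measured at several radii.

    Requires at least two distinct radii with at least four concentrations
    each; the per-radius curvature of the isotherm (stronger cooperativity at
    lower e_r) is what identifies the law parameters.  Data confined to the
    low-concentration linear regime identifies only A/c_0, and the result is
    flagged accordingly.
    """
    if law_kind not in ("curvature", "tension"):
        raise ValueError(f"law_kind must be 'curvature' or 'tension', got {law_kind!r}")
    df = dataset.frame
    if dataset.radii.size < 2:
        raise ValueError("concentration-profile fit needs >= 2 distinct radii")
    for r, grp in df.groupby("radius_um"):
        if grp["concentration"].nunique() < 4:
            raise ValueError(
                f"radius {r} μm has fewer than 4 distinct concentrations"
            )
    radii = df["radius_um"].to_numpy(dtype=float)
    conc = df["concentration"].to_numpy(dtype=float)
    y = df["adsorption"].to_numpy(dtype=float)
    w = dataset.weights()

    sign = -1.0 if law_kind == "curvature" else 1.0

    def e_r_of(theta, r):
        c1, c2 = math.exp(theta[0]), math.exp(theta[1])
        return c1 + sign * c2 * (1.0 / r if law_kind == "curvature" else r)

    def C_s_of(theta, i):
        c_0 = math.exp(min(max(theta[3], -700.0), 700.0))
        return conc[i] / c_0 if c_0 > 0 else math.inf

    residuals = _residuals_factory(
        radii, C_s_of, e_r_of, lambda th: math.exp(th[2]), y, w, log_space
    )

    rng = np.random.default_rng(seed)
    c_med = float(np.median(conc))
    c1s, c2s, As = _start_box(rng, n_starts, max(np.max(y), 1e-12))
    starts = [
        np.array([
            math.log(c1_0), math.log(c2_0), math.log(A_0),
            rng.uniform(math.log(0.2 * c_med), math.log(5.0 * c_med)),
        ])
        for c1_0, c2_0, A_0 in zip(c1s, c2s, As)
    ]

    best = _multistart_least_squares(residuals, starts)
    c1, c2, A, c_0 = (math.exp(v) for v in best.x)
    law = RepulsionLaw(kind=law_kind, c1=c1, c2=c2)
    notes = []
    max_Cs = float(np.max(conc)) / c_0
    if max_Cs < 0.2:
        notes.append(
            "identifiability: data confined to the linear low-concentration "
            "regime; only A/c_0 is identified and (c1, c2) are weakly "
            "constrained"
        )
    return FitResult(
        law_kind=law_kind,
        c1=c1,
        c2=c2,
        A=A,
        c_0=c_0,
        C_s=None,
        objective=float(2.0 * best.cost),
        covariance=_covariance(best, 4),
        converged=bool(best.success and 2.0 * best.cost < _PENALTY),
        divergence_radius=divergence_radius(law),
        warnings=notes,
        n_starts=n_starts,
        seed=seed,
    )


@dataclass
class ModelComparison:
    """Curvature vs tension fits of the same data from identical start boxes."""

    fits: dict                      #: law kind -> FitResult
    ranked: list                    #: law kinds, best objective first
    objective_ratio: float          #: worse objective / better objective
    tie: bool                       #: single-radius / non-identifiable design

    @property
    def best(self) -> FitResult:
        return self.fits[self.ranked[0]]


def compare_models(
    dataset: AdsorptionDataset,
    C_s: float = 1.0,
    fit_Cs: bool = False,
    n_starts: int = 16,
    seed: int = 0,
    log_space: bool = False,
) -> ModelComparison:
    """Fit both repulsion laws to a radius profile and rank the objectives.

    Both fits run from identical multi-start boxes (same seed).  A
    single-radius design cannot discriminate the laws and is reported as a
    tie rather than a ranking.
    """
    if dataset.radii.size < 3:
        return ModelComparison(
            fits={}, ranked=[], objective_ratio=1.0, tie=True
        )
    fits = {
        kind: fit_radius_profile(
            dataset, kind, C_s=C_s, fit_Cs=fit_Cs,
            n_starts=n_starts, seed=seed, log_space=log_space,
        )
        for kind in ("curvature", "tension")
    }
    ranked = sorted(fits, key=lambda k: fits[k].objective)
    lo, hi = fits[ranked[0]].objective, fits[ranked[1]].objective
    return ModelComparison(
        fits=fits,
        ranked=ranked,
        objective_ratio=(hi / lo if lo > 0 else math.inf),
        tie=False,
    )
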