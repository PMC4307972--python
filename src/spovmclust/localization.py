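"""Finite-range repulsion and two-region curvature localization.

When the repulsive interaction has a finite range — modelled as a step
function in cluster units — the repulsive energy of a cluster grows
quadratically, e_r0·k(k−1)/2, only up to ``k_max`` proteins, and linearly,
e_r0·[k_max(k_max−1) + (k−k_max)(k_max−1)]/2, beyond.  A linear energy can
no longer contain the exponential growth of C_s^k, so above a critical bath
concentration the partition sum becomes dominated by its largest admissible
term: most bound protein condenses into one giant cluster of the maximum
size the region can hold (``K_cap``, the region's site budget).

This condensation makes curvature sensing exquisitely sharp.  Two membrane
regions that differ only minutely in binding energy (region 1, the more
convex one, by ``delta_b`` k_B·T — of order 1% of the binding energy) see
effective concentrations differing by exp(delta_b); a cluster of size k
amplifies this to exp(k·delta_b), so once giant clusters form, essentially
all protein sits in the higher-curvature region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .model import ConfigurationError, RepulsionLaw, repulsion_energy

__all__ = [
    "TwoRegionSystem",
    "RegionAdsorption",
    "LocalizationCurve",
    "step_log_weights",
    "region_adsorption_step",
    "localization_fraction",
    "localization_curve",
    "stoichiometric_adsorption",
]


@dataclass(frozen=True)
class TwoRegionSystem:
    """Two equal-bath membrane regions with a small binding-energy offset.

    ``delta_b`` may be given directly (k_B·T) or as a relative fraction
    ``rel_delta`` of an absolute binding energy ``eps_b`` (the two must then
    both be supplied, since a percentage alone does not fix an energy).
    Region 1 is the higher-curvature region and by convention has the
    advantage, delta_b ≥ 0.
    """

    delta_b: Optional[float] = None
    eps_b: Optional[float] = None
    rel_delta: Optional[float] = None
    e_r0: float = 0.2
    k_max: int = 10
    K_cap: int = 1000
    area_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.delta_b is None:
            if self.eps_b is None or self.rel_delta is None:
                raise ConfigurationError(
                    "supply delta_b directly, or both eps_b and rel_delta"
                )
            object.__setattr__(self, "delta_b", self.rel_delta * self.eps_b)
        if self.delta_b < 0:
            raise ConfigurationError(
                "delta_b must be >= 0 (region 1 is the higher-curvature region)"
            )
        if not (1 <= self.k_max <= self.K_cap):
            raise ConfigurationError(
                f"need 1 <= k_max <= K_cap, got k_max={self.k_max}, K_cap={self.K_cap}"
            )
        if self.area_ratio <= 0:
            raise ConfigurationError("area_ratio must be positive")

    @property
    def law(self) -> RepulsionLaw:
        return RepulsionLaw(kind="step", e_r0=self.e_r0, k_max=self.k_max)


@dataclass(frozen=True)
class RegionAdsorption:
    """Adsorption and cluster statistics of one region under step repulsion."""

    C_v: float
    log_C_v: float
    mean_size: float
    dominant_size: int
    giant_cluster: bool   #: True when the k = K_cap term is the largest summand
    K_cap: int


def step_log_weights(C_s_eff: float, e_r0: float, k_max: int, K_cap: int) -> np.ndarray:
    """log summands k·exp(−E_rep(k))·C_s_eff^k, k = 1..K_cap, step energy."""
    if C_s_eff <= 0:
        raise ValueError(f"C_s_eff must be > 0, got {C_s_eff}")
    law = RepulsionLaw(kind="step", e_r0=e_r0, k_max=k_max)
    k = np.arange(1, K_cap + 1)
    e_rep = np.array([repulsion_energy(int(kk), law) for kk in k])
    return np.log(k.astype(float)) - e_rep + k * math.log(C_s_eff)


def region_adsorption_step(
    C_s_eff: float, e_r0: float, k_max: int, K_cap: int
) -> RegionAdsorption:
    """Adsorption of one region under finite-range (step) repulsion.

    C_v = Σ_{k=1}^{K_cap} k·exp(−E_rep(k))·C_s_eff^k.  The truncation at the
    region's site budget ``K_cap`` is physical, not numerical: the linear
    energy tail makes the untruncated series divergent once
    C_s_eff·exp(−(k_max−1)·e_r0/2) ≥ 1, and a cluster cannot outgrow its
    region.  The state is flagged as giant-cluster when the k = K_cap term
    is the largest summand.
    """
    if K_cap is None or not math.isfinite(K_cap):
        raise ConfigurationError("step-repulsion adsorption requires a finite K_cap")
    K_cap = int(K_cap)
    if C_s_eff < 0:
        raise ValueError(f"C_s_eff must be >= 0, got {C_s_eff}")
    if C_s_eff == 0.0:
        return RegionAdsorption(0.0, -math.inf, 1.0, 1, False, K_cap)
    lw = step_log_weights(C_s_eff, e_r0, k_max, K_cap)
    log_k = np.log(np.arange(1, K_cap + 1, dtype=float))
    log_C_v = float(logsumexp(lw))
    mean = float(math.exp(log_C_v - logsumexp(lw - log_k)))
    k_dom = int(np.argmax(lw)) + 1
    return RegionAdsorption(
        C_v=float(math.exp(log_C_v)) if log_C_v < 709 else math.inf,
        log_C_v=log_C_v,
        mean_size=mean,
        dominant_size=k_dom,
        giant_cluster=(k_dom == K_cap),
        K_cap=K_cap,
    )


def _region_pair(C_s: float, system: TwoRegionSystem) -> tuple[RegionAdsorption, RegionAdsorption]:
    """Both regions at one bath concentration.

    Region 1's binding advantage enters as an effective concentration
    C_s·exp(delta_b): the binding energy sits in the normalisation scale
    c_0 ∝ exp(−eps_b), so a size-k cluster in region 1 is favoured by
    exp(k·delta_b).
    """
    r1 = region_adsorption_step(
        C_s * math.exp(system.delta_b), system.e_r0, system.k_max, system.K_cap
    )
    r2 = region_adsorption_step(C_s, system.e_r0, system.k_max, system.K_cap)
    return r1, r2


def localization_fraction(C_s: float, system: TwoRegionSystem) -> float:
    """Fraction of all adsorbed protein sitting in the high-curvature region.

    fraction = A₁·C_v1 / (A₁·C_v1 + A₂·C_v2), evaluated in log space.
    Equals 0.5 exactly for delta_b = 0 and equal areas; tends to
    exp(delta_b)/(1 + exp(delta_b)) in the monomer-dominated limit C_s → 0;
    approaches 1 in the giant-cluster regime.
    """
    if C_s < 0:
        raise ValueError(f"C_s must be >= 0, got {C_s}")
    if C_s == 0.0:
        raise ZeroDivisionError("total adsorption is zero at C_s = 0; fraction undefined")
    if system.delta_b == 0.0 and system.area_ratio == 1.0:
        return 0.5  # exact by symmetry
    r1, r2 = _region_pair(C_s, system)
    # 1 / (1 + (A2/A1)·C_v2/C_v1)
    log_odds = math.log(system.area_ratio) + r1.log_C_v - r2.log_C_v
    if log_odds > 700:
        return 1.0
    return 1.0 / (1.0 + math.exp(-log_odds))


@dataclass(frozen=True)
class LocalizationCurve:
    """Localization trace along a concentration grid (one row per C_s)."""

    C_s: np.ndarray
    adsorption_1: np.ndarray
    adsorption_2: np.ndarray
    total_adsorption: np.ndarray
    fraction_1: np.ndarray
    mean_size_1: np.ndarray
    mean_size_2: np.ndarray
    giant_1: np.ndarray
    giant_2: np.ndarray

    COLUMNS = (
        "C_s", "adsorption_1", "adsorption_2", "total_adsorption",
        "fraction_1", "mean_size_1", "mean_size_2",
    )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({c: getattr(self, c) for c in self.COLUMNS})


def localization_curve(system: TwoRegionSystem, C_s_grid: Sequence[float]) -> LocalizationCurve:
    """Evaluate both regions along an increasing concentration grid."""
    grid = np.asarray(C_s_grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("C_s grid must be positive")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("C_s grid must be strictly increasing")
    a1w = system.area_ratio / (1.0 + system.area_ratio)  # area weights
    a2w = 1.0 / (1.0 + system.area_ratio)
    rows = []
    for C_s in grid:
        r1, r2 = _region_pair(C_s, system)
        log_tot = logsumexp(
            [r1.log_C_v, r2.log_C_v],
            b=[a1w, a2w],
        )
        frac = (
            0.5 if (system.delta_b == 0.0 and system.area_ratio == 1.0)
            else localization_fraction(C_s, system)
        )
        rows.append((
            math.exp(r1.log_C_v) if r1.log_C_v < 709 else math.inf,
            math.exp(r2.log_C_v) if r2.log_C_v < 709 else math.inf,
            math.exp(log_tot) if log_tot < 709 else math.inf,
            frac, r1.mean_size, r2.mean_size,
            r1.giant_cluster, r2.giant_cluster,
        ))
    cols = list(zip(*rows))
    return LocalizationCurve(
        C_s=grid,
        adsorption_1=np.array(cols[0]),
        adsorption_2=np.array(cols[1]),
        total_adsorption=np.array(cols[2]),
        fraction_1=np.array(cols[3]),
        mean_size_1=np.array(cols[4]),
        mean_size_2=np.array(cols[5]),
        giant_1=np.array(cols[6], dtype=bool),
        giant_2=np.array(cols[7], dtype=bool),
    )


def stoichiometric_adsorption(C_s: float, q: int, K_q: float) -> float:
    """Adsorption for fixed-stoichiometry clustering (monomers ⇌ q-mers).

    The alternative to size-selected clusters: the protein forms clusters of
    one fixed size q (for example trimers) with formation constant K_q, so

        C_v = C_s + q·K_q·C_s^q.
    """
    if int(q) != q or q < 2:
        raise ValueError(f"fixed cluster size q must be an integer >= 2, got {q!r}")
    if K_q < 0:
        raise ValueError(f"formation constant K_q must be >= 0, got {K_q}")
    if C_s < 0:
        raise ValueError(f"C_s must be >= 0, got {C_s}")
    return C_s + q * K_q * C_s ** int(q)
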