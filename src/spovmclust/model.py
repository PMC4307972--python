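"""Equilibrium cluster-distribution model of SpoVM membrane adsorption.

A vesicle membrane in contact with a dilute protein bath is described as a
lattice of binding sites on which bound proteins form clusters.  Three energy
scales (all in units of k_B·T) govern the equilibrium: a binding energy
``eps_b`` per protein, a short-range nearest-neighbour attraction ``eps_nn``
per bond, and a longer-range pairwise repulsion ``e_r`` acting between every
pair of proteins within a cluster.  In the dilute limit the normalised
adsorption is the cluster-partition sum

    C_v = sum_{k>=1} k * exp(-k(k-1) e_r / 2) * C_s**k,

where ``C_s`` is the bath concentration normalised by the model scale
``c_0 = exp(-(eps_nn + eps_b)) * alpha``.  The repulsion strength may depend
on vesicle radius through a curvature law ``e_r = c1 - c2/r`` or a tension
law ``e_r = c1 + c2*r`` (tension of a pressurised sphere grows linearly with
radius, sigma = P*r/2, and the radius dependence is absorbed into ``c2``).

All series are evaluated in log-space so that concentrations as large as
``exp(100)`` remain tractable, and truncation is adaptive with a
geometric-tail bound.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "DivergenceError",
    "ConfigurationError",
    "InteractionParams",
    "RepulsionLaw",
    "MembraneGeometry",
    "BathState",
    "ClusterDistribution",
    "repulsion_energy",
    "e_r_of_radius",
    "series_converges",
    "cluster_weights",
    "log_adsorption",
    "adsorption",
    "mean_cluster_size",
    "dominant_cluster_size",
    "asymptotic_log_adsorption",
    "cluster_distribution",
    "denormalize",
    "rod_sphere_gap",
    "DEFAULT_TOL",
    "HARD_K_CAP",
]

#: default relative tail tolerance for adaptive series truncation
DEFAULT_TOL = 1e-12
#: hard cap on the number of series terms
HARD_K_CAP = 10**6


class DivergenceError(ValueError):
    """The cluster-partition sum does not converge for these parameters."""


class ConfigurationError(ValueError):
    """A parameter object is internally inconsistent or incomplete."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionParams:
    """Energy scales of the clustering model, in units of k_B·T.

    Temperature enters only through this convention (room temperature,
    300 K, in the experiments being modelled).

    Parameters
    ----------
    eps_b:
        Binding energy of one protein to the membrane.
    eps_nn:
        Nearest-neighbour attraction per bond within a cluster.
    e_r:
        Pairwise repulsion strength between proteins in the same cluster.
        The adsorption series converges for every ``C_s >= 0`` iff
        ``e_r > 0``.
    """

    eps_b: float = 0.0
    eps_nn: float = 0.0
    e_r: float = 0.0

    def __post_init__(self) -> None:
        for name in ("eps_b", "eps_nn", "e_r"):
            v = getattr(self, name)
            if not math.isfinite(float(v)):
                raise ConfigurationError(f"{name} must be finite, got {v!r}")


_LAW_KINDS = ("constant", "curvature", "tension", "step")


@dataclass(frozen=True)
class RepulsionLaw:
    """How the intra-cluster repulsion strength depends on radius or size.

    kind = "constant":   e_r = c1 at every radius.
    kind = "curvature":  e_r = c1 - c2/r   (expansion in powers of 1/r;
                         c2 in k_B·T·μm).  May cross zero at r = c2/c1,
                         below which adsorption diverges.
    kind = "tension":    e_r = c1 + c2*r   (expansion in powers of membrane
                         tension; c2 in k_B·T·μm⁻¹).
    kind = "step":       finite interaction range in cluster units; cluster
                         repulsive energy grows quadratically up to
                         ``k_max`` proteins and linearly beyond, with base
                         strength ``e_r0``.
    """

    kind: str
    c1: float = 0.0
    c2: float = 0.0
    e_r0: float = 0.0
    k_max: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in _LAW_KINDS:
            raise ConfigurationError(
                f"unknown repulsion-law kind {self.kind!r}; expected one of {_LAW_KINDS}"
            )
        if self.kind == "step":
            if self.k_max is None or int(self.k_max) != self.k_max or self.k_max < 1:
                raise ConfigurationError("step law requires integer k_max >= 1")

    def at_radius(self, r: float) -> float:
        """Evaluate e_r at vesicle radius ``r`` (μm); see :func:`e_r_of_radius`."""
        return e_r_of_radius(r, self)


@dataclass(frozen=True)
class MembraneGeometry:
    """Vesicle radius and the lattice-site count it implies.

    The number of binding sites is taken as ``L_v = round(4 r² / a²)`` with
    the radius converted to nanometres — the model's stated convention (no
    factor of π; only the scaling with r matters for the equilibrium).

    Parameters
    ----------
    r_um: vesicle radius in μm.
    a_nm: effective protein footprint length in nm (~4 nm for an
        amphipathic helix of 26 residues).
    """

    r_um: float
    a_nm: float = 4.0

    def __post_init__(self) -> None:
        if self.r_um <= 0:
            raise ConfigurationError(f"radius must be positive, got {self.r_um}")
        if self.a_nm <= 0:
            raise ConfigurationError(f"footprint must be positive, got {self.a_nm}")

    @property
    def L_v(self) -> int:
        r_nm = self.r_um * 1000.0
        return max(1, round(4.0 * r_nm * r_nm / (self.a_nm * self.a_nm)))


@dataclass(frozen=True)
class BathState:
    """Protein bath: occupancy fraction and concentration normalisation.

    ``ns_star = n_s / L_s`` is the site-occupancy fraction of protein in
    solution; the physical concentration is ``c_s = alpha * ns_star`` for a
    conversion constant ``alpha``.  Normalising by the model scale
    ``c_0 = exp(-(eps_nn + eps_b)) * alpha`` gives the dimensionless
    concentration ``C_s`` that enters the adsorption series.
    """

    ns_star: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.ns_star < 0:
            raise ConfigurationError("ns_star must be >= 0")
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be > 0")
        if self.ns_star > 0.1:
            warnings.warn(
                f"ns_star = {self.ns_star:g} exceeds 0.1; dilute-limit formulas "
                "are unreliable at this bath occupancy",
                stacklevel=2,
            )

    @property
    def c_s(self) -> float:
        return self.alpha * self.ns_star

    def c_0(self, params: InteractionParams) -> float:
        return math.exp(-(params.eps_nn + params.eps_b)) * self.alpha

    def C_s(self, params: InteractionParams) -> float:
        """Normalised concentration c_s / c_0 = ns_star * exp(eps_nn + eps_b)."""
        return self.ns_star * math.exp(params.eps_nn + params.eps_b)


@dataclass(frozen=True)
class ClusterDistribution:
    """Equilibrium cluster statistics at one (C_s, e_r) state point.

    ``weights[k-1]`` is the per-site density of k-clusters, m_k / L_v
    (including the exp(-eps_nn) prefactor); ``C_v`` is the normalised
    adsorption of the partition sum, so that
    ``C_v = sum_k k * weights[k-1] / exp(-eps_nn)``.
    """

    weights: np.ndarray
    C_v: float
    mean_size: float
    dominant_size: int
    truncation_K: int
    eps_nn: float = 0.0


# ---------------------------------------------------------------------------
# Repulsion laws
# ---------------------------------------------------------------------------

def repulsion_energy(k: int, law) -> float:
    """Total repulsive energy of a cluster of ``k`` proteins (k_B·T).

    ``law`` may be a scalar repulsion strength ``e_r`` (infinite interaction
    range: every pair repels, energy ``e_r * k(k-1)/2``), a constant-kind
    :class:`RepulsionLaw`, or a step-kind law with finite range ``k_max``:
    quadratic growth ``e_r0 * k(k-1)/2`` up to ``k_max`` and linear growth
    ``e_r0 * [k_max(k_max-1) + (k-k_max)(k_max-1)]/2`` beyond, continuous at
    the cutoff.
    """
    kk = k
    if isinstance(kk, (bool, np.bool_)):
        raise ValueError("cluster size must be an integer >= 1")
    if float(kk) != int(kk):
        raise ValueError(f"cluster size must be an integer, got {k!r}")
    kk = int(kk)
    if kk < 1:
        raise ValueError(f"cluster size must be >= 1, got {k!r}")

    if isinstance(law, RepulsionLaw):
        if law.kind == "step":
            return _step_energy(kk, law.e_r0, int(law.k_max))
        if law.kind == "constant":
            return 0.5 * law.c1 * kk * (kk - 1)
        raise ConfigurationError(
            f"{law.kind!r} law needs a radius; evaluate e_r_of_radius first"
        )
    e_r = float(law)
    return 0.5 * e_r * kk * (kk - 1)


def _step_energy(k: int, e_r0: float, k_max: int) -> float:
    if k <= k_max:
        return 0.5 * e_r0 * k * (k - 1)
    return 0.5 * e_r0 * (k_max * (k_max - 1) + (k - k_max) * (k_max - 1))


def e_r_of_radius(r: float, law: RepulsionLaw) -> float:
    """Repulsion strength at vesicle radius ``r`` (μm) under a radius law.

    curvature: ``c1 - c2/r``; tension: ``c1 + c2*r``; constant: ``c1``.
    The curvature law may return a nonpositive value at small radius —
    deliberately not clipped, since downstream divergence at that radius is
    itself the physically meaningful diagnostic.
    """
    if not isinstance(law, RepulsionLaw):
        raise TypeError("law must be a RepulsionLaw")
    if law.kind == "step":
        raise ConfigurationError("step law has no radius dependence")
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    if law.kind == "curvature":
        return law.c1 - law.c2 / r
    if law.kind == "tension":
        return law.c1 + law.c2 * r
    return law.c1


# ---------------------------------------------------------------------------
# Partition sums
# ---------------------------------------------------------------------------

def series_converges(C_s: float, e_r: float) -> bool:
    """Whether the adsorption series converges at this state point."""
    if C_s < 0:
        raise ValueError(f"C_s must be >= 0, got {C_s}")
    if C_s == 0:
        return True
    if e_r > 0:
        return True
    return e_r == 0 and C_s < 1


def _check_convergent(C_s: float, e_r: float) -> None:
    if not series_converges(C_s, e_r):
        raise DivergenceError(
            f"adsorption series diverges at C_s={C_s:g}, e_r={e_r:g} "
            "(requires e_r > 0, or e_r = 0 with C_s < 1)"
        )


def _log_weights(log_Cs: float, e_r: float, K: int) -> np.ndarray:
    """log of the summands w_k = k exp(-k(k-1) e_r/2) C_s^k for k=1..K."""
    k = np.arange(1, K + 1, dtype=float)
    return np.log(k) - 0.5 * k * (k - 1.0) * e_r + k * log_Cs


def _adaptive_log_weights(log_Cs: float, e_r: float, tol: float) -> np.ndarray:
    """Summand logs out to a K where the geometric tail bound is below tol.

    Successive term ratios w_{k+1}/w_k = ((k+1)/k) exp(-k e_r) C_s decrease
    in k, so once the ratio drops below 1 the tail is bounded by a geometric
    series; truncate when that bound is below ``tol`` times the partial sum.
    """
    if e_r == 0.0:
        if log_Cs >= 0.0:  # guarded upstream; defensive
            raise DivergenceError("series diverges for e_r = 0 and C_s >= 1")
        # w_{k+1}/w_k -> C_s; tail after K bounded by w_K * Cs/(1-Cs)
        ratio = math.exp(log_Cs)
        K = 64
        while K <= HARD_K_CAP:
            lw = _log_weights(log_Cs, 0.0, K)
            tail = lw[-1] + log_Cs - math.log1p(-ratio)
            if tail <= math.log(tol) + logsumexp(lw):
                return lw
            K *= 2
        return lw
    # peak near k* = log_Cs/e_r; go well past it, doubling until the tail
    # bound is met
    k_star = max(1.0, log_Cs / e_r)
    K = int(k_star) + 16
    while True:
        K = min(K, HARD_K_CAP)
        lw = _log_weights(log_Cs, e_r, K)
        log_ratio = lw[-1] - lw[-2]  # < current ratio bound for the tail
        if log_ratio < 0.0:
            ratio = math.exp(log_ratio)
            tail = lw[-1] + log_ratio - math.log1p(-ratio)
            if tail <= math.log(tol) + logsumexp(lw):
                return lw
        if K >= HARD_K_CAP:
            raise DivergenceError(
                f"series truncation cap {HARD_K_CAP} reached at "
                f"log_Cs={log_Cs:g}, e_r={e_r:g}"
            )
        K *= 2


def cluster_weights(C_s: float, e_r: float, K: int) -> np.ndarray:
    """First ``K`` summands w_k = k·exp(-k(k-1)e_r/2)·C_s^k of the series.

    The per-site density of k-clusters is recovered as
    ``w_k / k * exp(-eps_nn)``.
    """
    if C_s < 0:
        raise ValueError(f"C_s must be >= 0, got {C_s}")
    if K < 1 or int(K) != K:
        raise ValueError(f"K must be an integer >= 1, got {K!r}")
    if C_s == 0.0:
        return np.zeros(int(K))
    if e_r <= 0 and C_s >= 1:
        raise DivergenceError(
            f"series diverges at C_s={C_s:g}, e_r={e_r:g}; weights unbounded"
        )
    return np.exp(_log_weights(math.log(C_s), e_r, int(K)))


def log_adsorption(log_Cs: float, e_r: float, tol: float = DEFAULT_TOL) -> float:
    """ln C_v as a function of ln C_s — usable far beyond float overflow.

    Needed in the large-concentration regime where ln C_v grows like
    (ln C_s)²/(2 e_r) and C_v itself overflows a double.
    """
    if e_r < 0:
        raise DivergenceError(f"series diverges for e_r={e_r:g} < 0")
    if e_r == 0 and log_Cs >= 0:
        raise DivergenceError("series diverges for e_r = 0 and C_s >= 1")
    if math.isinf(e_r):
        return log_Cs  # only the monomer term survives
    if e_r == 0.0:
        # closed form: C_v = x/(1-x)^2
        x = math.exp(log_Cs)
        return log_Cs - 2.0 * math.log1p(-x)
    lw = _adaptive_log_weights(log_Cs, e_r, tol)
    return float(logsumexp(lw))


def adsorption(C_s: float, e_r: float, tol: float = DEFAULT_TOL) -> float:
    """Normalised adsorption C_v = Σ_k k·exp(-k(k-1)e_r/2)·C_s^k.

    Strictly increasing in ``C_s`` and strictly decreasing in ``e_r`` for
    ``C_s > 0``.  Raises :class:`DivergenceError` when the series does not
    converge (e_r < 0, or e_r = 0 with C_s >= 1).
    """
    if C_s < 0:
        raise ValueError(f"C_s must be >= 0, got {C_s}")
    if C_s == 0.0:
        return 0.0
    _check_convergent(C_s, e_r)
    log_cv = log_adsorption(math.log(C_s), e_r, tol)
    # a convergent sum can still exceed float range; report inf rather than
    # raise (use log_adsorption directly in that regime)
    return math.exp(log_cv) if log_cv < 709.0 else math.inf


def mean_cluster_size(
    C_s: float,
    e_r: float,
    tol: float = DEFAULT_TOL,
    mass_weighted: bool = False,
) -> float:
    """Average cluster size at equilibrium (proteins per cluster).

    Number-weighted by default: total bound proteins divided by total number
    of clusters, Σ k m_k / Σ m_k with m_k ∝ exp(-k(k-1)e_r/2) C_s^k.  With
    ``mass_weighted=True`` the average is over proteins rather than clusters,
    Σ k² m_k / Σ k m_k (always >= the number-weighted mean).  Tends to 1 as
    C_s → 0 (monomers only); returns exactly 1.0 at C_s = 0 as the limit
    value.
    """
    if C_s < 0:
        raise ValueError(f"C_s must be >= 0, got {C_s}")
    if C_s == 0.0:
        return 1.0
    _check_convergent(C_s, e_r)
    if math.isinf(e_r):
        return 1.0
    if e_r == 0.0 and not mass_weighted:
        return 1.0 / (1.0 - C_s)  # closed form of the geometric series
    log_Cs = math.log(C_s)
    lw = _adaptive_log_weights(log_Cs, e_r, tol) if e_r > 0 else None
    if lw is None:  # e_r == 0, mass-weighted
        lw = _adaptive_log_weights(log_Cs, 0.0, tol)
    log_k = np.log(np.arange(1, lw.size + 1, dtype=float))
    if mass_weighted:
        num = logsumexp(lw + log_k)  # Σ k² m_k
        den = logsumexp(lw)          # Σ k m_k
    else:
        num = logsumexp(lw)          # Σ k m_k
        den = logsumexp(lw - log_k)  # Σ m_k
    return float(math.exp(num - den))


def dominant_cluster_size(
    C_s: float, e_r: float, tol: float = DEFAULT_TOL
) -> tuple[int, float]:
    """Cluster size whose term maximises the adsorption series.

    Returns ``(k_star, estimate)`` where ``k_star`` is the exact argmax over
    k of the summand w_k (found by scanning until the weights decay) and
    ``estimate = ln(C_s)/e_r`` is the large-concentration analytic
    approximation to the dominant size.
    """
    if C_s <= 0:
        raise ValueError(f"C_s must be > 0, got {C_s}")
    if e_r <= 0:
        raise DivergenceError("dominant size defined only for e_r > 0")
    log_Cs = math.log(C_s)
    lw = _adaptive_log_weights(log_Cs, e_r, tol)
    k_star = int(np.argmax(lw)) + 1
    return k_star, log_Cs / e_r


def asymptotic_log_adsorption(C_s: float, e_r: float) -> float:
    """Large-concentration approximation ln C_v ≈ (ln C_s)² / (2 e_r).

    Valid in the asymptotic regime ``C_s > 1`` (dominant-term estimate of the
    partition sum); raises for ``C_s <= 1``.
    """
    if C_s <= 1:
        raise ValueError(
            f"asymptotic form requires C_s > 1, got C_s={C_s:g}"
        )
    if e_r <= 0:
        raise DivergenceError("asymptotic form requires e_r > 0")
    return math.log(C_s) ** 2 / (2.0 * e_r)


def cluster_distribution(
    C_s: float,
    e_r: float,
    eps_nn: float = 0.0,
    tol: float = DEFAULT_TOL,
) -> ClusterDistribution:
    """Full equilibrium summary at one state point.

    ``weights`` holds per-site cluster densities m_k/L_v (with the
    exp(-eps_nn) prefactor), truncated adaptively.
    """
    if C_s < 0:
        raise ValueError(f"C_s must be >= 0, got {C_s}")
    if C_s == 0.0:
        w = np.zeros(1)
        return ClusterDistribution(w, 0.0, 1.0, 1, 1, eps_nn)
    _check_convergent(C_s, e_r)
    log_Cs = math.log(C_s)
    lw = _adaptive_log_weights(log_Cs, e_r, tol)
    log_k = np.log(np.arange(1, lw.size + 1, dtype=float))
    C_v = float(math.exp(logsumexp(lw)))
    mean = float(math.exp(logsumexp(lw) - logsumexp(lw - log_k)))
    weights = np.exp(lw - log_k - eps_nn)
    return ClusterDistribution(
        weights=weights,
        C_v=C_v,
        mean_size=mean,
        dominant_size=int(np.argmax(lw)) + 1,
        truncation_K=lw.size,
        eps_nn=eps_nn,
    )


def denormalize(
    C_v: float, geometry: MembraneGeometry, params: InteractionParams
) -> float:
    """Bound-protein count n_v = C_v · L_v · exp(-eps_nn) on one vesicle.

    Warns when the implied coverage n_v/L_v exceeds 0.1, where the dilute
    assumption n_v ≪ L_v underlying the closed-form distribution breaks down.
    """
    if C_v < 0:
        raise ValueError(f"C_v must be >= 0, got {C_v}")
    n_v = C_v * geometry.L_v * math.exp(-params.eps_nn)
    if n_v / geometry.L_v > 0.1:
        warnings.warn(
            f"coverage n_v/L_v = {n_v / geometry.L_v:.3g} exceeds 0.1; "
            "dilute-limit result unreliable",
            stacklevel=2,
        )
    return n_v


def rod_sphere_gap(rod_length_nm: float, sphere_radius_nm: float) -> float:
    """Maximum gap between a straight rod tangent to a sphere and its surface.

    For a rod of length ℓ lying flat (tangent at one end) on a sphere of
    radius R, the far end sits √(R²+ℓ²) − R above the surface.  Evaluated in
    the cancellation-free form ℓ²/(R + √(R²+ℓ²)).  For a 4 nm protein on a
    0.5 μm-radius sphere this is ~0.016 nm (0.16 Å) — the geometric argument
    that a single protein cannot sense micron-scale curvature.
    """
    if rod_length_nm < 0 or sphere_radius_nm <= 0:
        raise ValueError(
            f"need rod length >= 0 and sphere radius > 0, got "
            f"({rod_length_nm}, {sphere_radius_nm})"
        )
    l2 = rod_length_nm * rod_length_nm
    return l2 / (sphere_radius_nm + math.hypot(sphere_radius_nm, rod_length_nm))
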