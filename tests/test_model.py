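"""Core cluster-model unit and property tests.

Expected values marked as derived were frozen from an independent
arbitrary-precision summation of the partition series (mpmath), not from the
implementation under test.
"""

import math

import mpmath as mp
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spovmclust as s
from spovmclust.model import DivergenceError, ConfigurationError


def mp_series(C_s, e_r, moment=1, dps=50, K=2000):
    """Independent oracle: Σ k^moment e^{-k(k-1)e_r/2} C_s^k at high precision."""
    with mp.workdps(dps):
        total = mp.fsum(
            mp.mpf(k) ** moment * mp.e ** (-mp.mpf(k) * (k - 1) * mp.mpf(e_r) / 2)
            * mp.mpf(C_s) ** k
            for k in range(1, K + 1)
        )
        return float(total)


# ---------------------------------------------------------------------------
# Repulsion energy and radius laws
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "k,law,expected",
    [
        (1, 0.7, 0.0),                 # no pairs in a monomer
        (1, s.RepulsionLaw(kind="step", e_r0=0.2, k_max=4), 0.0),
        (4, s.RepulsionLaw(kind="step", e_r0=0.2, k_max=4), 1.2),
        (6, s.RepulsionLaw(kind="step", e_r0=0.2, k_max=4), 1.8),
        (5, 0.4, 4.0),                 # infinite range: e_r k(k-1)/2
        (3, s.RepulsionLaw(kind="constant", c1=0.5), 1.5),
    ],
)
def test_repulsion_energy(k, law, expected):
    assert s.repulsion_energy(k, law) == pytest.approx(expected, abs=1e-12)


def test_step_energy_continuous_at_cutoff():
    """Quadratic and linear branches agree at k = k_max."""
    law = s.RepulsionLaw(kind="step", e_r0=0.37, k_max=7)
    quad = 0.5 * 0.37 * 7 * 6
    assert s.repulsion_energy(7, law) == pytest.approx(quad)
    # one past the cutoff increases by the linear slope (k_max-1) e_r0/2
    assert s.repulsion_energy(8, law) - quad == pytest.approx(0.5 * 0.37 * 6)


@pytest.mark.parametrize("bad_k", [0, -1, 2.5])
def test_repulsion_energy_rejects_bad_sizes(bad_k):
    with pytest.raises(ValueError):
        s.repulsion_energy(bad_k, 1.0)


@pytest.mark.parametrize(
    "r,law_kwargs,expected",
    [
        (0.75, dict(kind="curvature", c1=2.67, c2=1.1649), 2.67 - 1.1649 / 0.75),
        (0.75, dict(kind="tension", c1=0.7, c2=0.61), 0.7 + 0.61 * 0.75),
        (1e15, dict(kind="curvature", c1=2.67, c2=1.1649), 2.67),  # r -> inf limit
        (5.0, dict(kind="constant", c1=1.3), 1.3),
    ],
)
def test_e_r_of_radius(r, law_kwargs, expected):
    assert s.e_r_of_radius(r, s.RepulsionLaw(**law_kwargs)) == pytest.approx(
        expected, rel=1e-12
    )


def test_e_r_of_radius_errors():
    with pytest.raises(ConfigurationError):
        s.e_r_of_radius(1.0, s.RepulsionLaw(kind="step", e_r0=0.2, k_max=3))
    with pytest.raises(ValueError):
        s.e_r_of_radius(-1.0, s.RepulsionLaw(kind="tension", c1=0.7, c2=0.61))


def test_curvature_law_may_go_nonpositive():
    """Below r = c2/c1 the curvature law crosses zero — not clipped."""
    law = s.RepulsionLaw(kind="curvature", c1=2.67, c2=1.1649)
    assert s.e_r_of_radius(0.3, law) < 0


# ---------------------------------------------------------------------------
# Partition sums
# ---------------------------------------------------------------------------

def test_cluster_weights_examples():
    assert np.all(s.cluster_weights(0.0, 1.0, 5) == 0.0)
    np.testing.assert_allclose(
        s.cluster_weights(0.5, 0.0, 3), [0.5, 0.5, 0.375], rtol=1e-12
    )
    np.testing.assert_allclose(
        s.cluster_weights(1.0, 2.0, 4),
        [1.0, 0.270670566, 0.0074362565, 2.45768e-05],
        rtol=1e-5,
    )


def test_adsorption_worked_values():
    # geometric closed form at e_r = 0
    assert s.adsorption(0.5, 0.0) == pytest.approx(2.0, rel=1e-12)
    # monomer-only limit at huge repulsion
    assert s.adsorption(0.3, 1e6) == pytest.approx(0.3, rel=1e-9)
    # frozen from the mpmath oracle
    assert s.adsorption(1.0, 2.0) == pytest.approx(1.2781314, rel=1e-6)


def test_adsorption_divergence_errors():
    with pytest.raises(DivergenceError):
        s.adsorption(1.0, 0.0)
    with pytest.raises(DivergenceError):
        s.adsorption(0.5, -0.2)
    with pytest.raises(ValueError):
        s.adsorption(-0.1, 1.0)


def test_geometric_closed_forms_across_grid():
    """At e_r = 0 the series is geometric: C_v = x/(1-x)^2, mean = 1/(1-x)."""
    for x in np.arange(0.1, 0.95, 0.1):
        assert s.adsorption(x, 0.0) == pytest.approx(x / (1 - x) ** 2, rel=1e-10)
        assert s.mean_cluster_size(x, 0.0) == pytest.approx(1 / (1 - x), rel=1e-10)


def test_oracle_equivalence_on_grid():
    """Adsorption and mean size match arbitrary-precision sums to 1e-8."""
    points = [(cs, er) for cs in (0.2, 0.7, 1.0, 2.0, 5.0) for er in (0.3, 0.8, 2.0, 5.0)]
    assert len(points) == 20
    for cs, er in points:
        cv_ref = mp_series(cs, er, moment=1)
        m0_ref = mp_series(cs, er, moment=0)
        assert s.adsorption(cs, er) == pytest.approx(cv_ref, rel=1e-8)
        assert s.mean_cluster_size(cs, er) == pytest.approx(cv_ref / m0_ref, rel=1e-8)


def test_mean_cluster_size_values():
    assert s.mean_cluster_size(1e-12, 1.0) == pytest.approx(1.0, rel=1e-9)
    assert s.mean_cluster_size(1.0, 2.0) == pytest.approx(1.123316, rel=1e-5)
    # protein-weighted average always exceeds the cluster-weighted one
    assert s.mean_cluster_size(2.0, 0.5, mass_weighted=True) > s.mean_cluster_size(2.0, 0.5)


@given(
    cs=st.floats(0.01, 5.0),
    er=st.floats(0.05, 5.0),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_adsorption_monotonicity(cs, er):
    """C_v strictly increases with concentration, decreases with repulsion."""
    assert s.adsorption(cs * 1.05, er) > s.adsorption(cs, er)
    assert s.adsorption(cs, er * 1.05) < s.adsorption(cs, er)


def test_low_concentration_linearity():
    """C_v/C_s -> 1 as C_s -> 0: monomers bind independently of e_r."""
    for er in (0.2, 1.0, 5.0):
        assert s.adsorption(1e-8, er) / 1e-8 == pytest.approx(1.0, rel=1e-7)


@pytest.mark.parametrize(
    "cs,er,k_expected,estimate",
    [
        (0.1, 1.0, 1, math.log(0.1)),
        (math.e, 0.5, 3, 2.0),
        (math.e ** 10, 1.0, 11, 10.0),
    ],
)
def test_dominant_cluster_size(cs, er, k_expected, estimate):
    """Exact argmax via scan, vs the analytic ln(C_s)/e_r estimate."""
    k_star, est = s.dominant_cluster_size(cs, er)
    # brute-force check of the argmax over an ample range
    k = np.arange(1, 200)
    w = np.log(k) - 0.5 * k * (k - 1) * er + k * math.log(cs)
    assert k_star == int(np.argmax(w)) + 1 == k_expected
    assert est == pytest.approx(estimate, rel=1e-12)


def test_asymptotic_log_adsorption():
    assert s.asymptotic_log_adsorption(math.e ** 10, 1.0) == pytest.approx(50.0)
    assert s.asymptotic_log_adsorption(math.e ** 10, 2.0) == pytest.approx(25.0)
    assert s.asymptotic_log_adsorption(1.0 + 1e-12, 1.0) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        s.asymptotic_log_adsorption(0.9, 1.0)


def test_asymptotic_consistency_improves_with_concentration():
    """The quadratic-in-ln(C_s) estimate of ln C_v sharpens as C_s grows."""
    errs = [
        abs(s.log_adsorption(lc, 1.0) / (lc * lc / 2.0) - 1.0)
        for lc in (5.0, 10.0, 20.0, 40.0)
    ]
    assert all(a > b for a, b in zip(errs, errs[1:]))


# ---------------------------------------------------------------------------
# Denormalisation, geometry, containers
# ---------------------------------------------------------------------------

def test_denormalize():
    geom = s.MembraneGeometry(r_um=0.1, a_nm=20.0)  # L_v = 400
    params = s.InteractionParams(eps_nn=0.0)
    assert s.denormalize(0.0, geom, params) == 0.0
    geom2 = s.MembraneGeometry(r_um=0.05, a_nm=10.0)  # L_v = 100
    with pytest.warns(UserWarning, match="coverage"):
        assert s.denormalize(1.0, geom2, params) == pytest.approx(100.0)
    params2 = s.InteractionParams(eps_nn=1.0)
    geom3 = s.MembraneGeometry(r_um=0.5, a_nm=2.0 * math.sqrt(10))  # L_v = 25000
    with pytest.warns(UserWarning, match="coverage"):
        n_v = s.denormalize(2.0, geom3, params2)
    assert n_v == pytest.approx(2.0 * 25000 * math.exp(-1.0), rel=1e-12)


def test_membrane_geometry_site_count():
    """L_v = round(4 r²/a²) with the radius in the same units as a."""
    geom = s.MembraneGeometry(r_um=1.0, a_nm=4.0)
    assert geom.L_v == round(4 * 1000.0 ** 2 / 16.0)


def test_bath_state_normalisation():
    bath = s.BathState(ns_star=1e-4, alpha=2.0)
    params = s.InteractionParams(eps_b=2.0, eps_nn=1.0)
    assert bath.c_s == pytest.approx(2e-4)
    assert bath.c_0(params) == pytest.approx(2.0 * math.exp(-3.0))
    assert bath.C_s(params) == pytest.approx(1e-4 * math.exp(3.0), rel=1e-12)
    with pytest.warns(UserWarning, match="dilute"):
        s.BathState(ns_star=0.5)


def test_cluster_distribution_invariant():
    """C_v equals Σ k·weights_k / e^{-eps_nn} under the chosen normalisation."""
    dist = s.cluster_distribution(1.5, 0.8, eps_nn=0.7)
    k = np.arange(1, dist.weights.size + 1)
    assert dist.C_v == pytest.approx(
        float(k @ dist.weights) / math.exp(-0.7), rel=1e-10
    )
    assert dist.mean_size >= 1.0
    assert 1 <= dist.dominant_size < dist.truncation_K


@pytest.mark.parametrize(
    "l,R,expected",
    [
        (0.0, 500.0, 0.0),
        (500.0, 500.0, (math.sqrt(2) - 1) * 500.0),
        (4.0, 500.0, math.sqrt(500.0 ** 2 + 16.0) - 500.0),
    ],
)
def test_rod_sphere_gap(l, R, expected):
    assert s.rod_sphere_gap(l, R) == pytest.approx(expected, rel=1e-9, abs=1e-15)


def test_rod_sphere_gap_rejects_bad_sphere():
    with pytest.raises(ValueError):
        s.rod_sphere_gap(4.0, 0.0)
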