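"""Shared fixtures: small synthetic datasets and reference state points."""

import pytest

import spovmclust as s


@pytest.fixture(scope="session")
def tension_law():
    """Wild-type tension-law parameters (c1 k_B·T, c2 k_B·T/μm)."""
    return s.RepulsionLaw(kind="tension", c1=0.7, c2=0.61)


@pytest.fixture(scope="session")
def curvature_law():
    """Wild-type curvature-law parameters (c1 k_B·T, c2 k_B·T·μm)."""
    return s.RepulsionLaw(kind="curvature", c1=2.67, c2=1.1649)


@pytest.fixture(scope="session")
def noiseless_radius_dataset(tension_law):
    """Noiseless adsorption-vs-radius profile at one concentration."""
    spec = s.GeneratorSpec(
        law=tension_law, A=3.0, c_0=0.5, concentrations=(1.0,),
        noise_cv=0.0, seed=1,
    )
    return s.generate_dataset(spec)


@pytest.fixture(scope="session")
def two_radius_isotherms(tension_law):
    """Noiseless isotherms at the two radii of the concentration analysis."""
    spec = s.GeneratorSpec(
        law=tension_law, A=2.0, c_0=0.8, radii=(0.75, 3.0),
        noise_cv=0.0, seed=2,
    )
    return s.generate_dataset(spec)
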