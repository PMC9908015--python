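import numpy as np
import pytest

from aptaruler import (
    ParticleSpec,
    build_tether_spec,
    invert_boltzmann,
    sample_chain_conformations,
    summarize_z,
)

ENDOTOXIN_LENGTHS = (2.0, 3.0, 4.0)


@pytest.fixture(scope="session")
def unbound_spec():
    return build_tether_spec(state="unbound")


@pytest.fixture(scope="session")
def bound_specs():
    return [
        build_tether_spec(state="bound", endotoxin_length=le)
        for le in ENDOTOXIN_LENGTHS
    ]


@pytest.fixture(scope="session")
def unbound_ensemble(unbound_spec):
    return sample_chain_conformations(
        unbound_spec, ParticleSpec(), n_chains=20_000, seed=11
    )


@pytest.fixture(scope="session")
def bound_z(bound_specs):
    """Pooled bound-state gaps over the modelled complex sizes."""
    return np.concatenate(
        [
            sample_chain_conformations(s, n_chains=8_000, seed=13 + i).z_values
            for i, s in enumerate(bound_specs)
        ]
    )


@pytest.fixture(scope="session")
def unbound_profile(unbound_ensemble):
    s = summarize_z(unbound_ensemble, bin_width=0.25)
    return invert_boltzmann(s.bin_centers, s.density)


@pytest.fixture(scope="session")
def gaussian_profile():
    """Analytic harmonic reference: Gaussian density, mean 5 nm, sd 1 nm."""
    z = np.arange(1.0, 9.01, 0.1)
    p = np.exp(-((z - 5.0) ** 2) / 2.0)
    p /= p.sum() * 0.1
    return invert_boltzmann(z, p)
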