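"""Shared fixtures.

The heavy end-to-end objects (the standard toy complex, the full binding
pipelines and the brute-force reference) are session-scoped so the
acceptance tests share one computation.
"""

import numpy as np
import pytest

from geombind import (
    BindingProtocol,
    QuadratureSpec,
    ThermoState,
    brute_force_keq,
    end_to_end_toy_binding,
    keq_to_dg,
    make_toy_complex,
)

SITE_BOX = ([-1.5, -4.0, -4.0], [6.5, 4.0, 4.0])


@pytest.fixture(scope="session")
def thermo():
    return ThermoState(300.0)


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex()


@pytest.fixture(scope="session")
def base_pipeline(toy_complex):
    """The full geometric-route protocol at the standard force constants."""
    proto = BindingProtocol(
        system=toy_complex,
        seed=11,
        steps_angular=2_000_000,
        steps_rmsd=1_200_000,
        steps_separation=4_800_000,
    )
    result, artifacts = end_to_end_toy_binding(proto, return_artifacts=True)
    return proto, result, artifacts


@pytest.fixture(scope="session")
def doubled_pipeline(toy_complex):
    """The same protocol with every restraint force constant doubled."""
    proto = BindingProtocol(
        system=toy_complex,
        seed=23,
        k_angular=0.2,
        k_rmsd=200.0,
        steps_angular=2_000_000,
        steps_rmsd=1_200_000,
        steps_separation=4_800_000,
    )
    return proto, end_to_end_toy_binding(proto)


@pytest.fixture(scope="session")
def oracle_dg(toy_complex, thermo):
    """Brute-force ΔG°bind of the standard toy complex."""
    spec = QuadratureSpec(
        site_lo=SITE_BOX[0], site_hi=SITE_BOX[1], n_samples=1_000_000, seed=101
    )
    keq, se = brute_force_keq(toy_complex, spec, thermo)
    return keq_to_dg(keq, thermo, 1661.0), se / keq * thermo.kt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
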