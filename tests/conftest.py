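import math

import numpy as np
import pytest

from pbhsolv.continuum import derive_continuum_coefficients, make_background
from pbhsolv.fixtures import figure_parameter_registry, toy_lattice


@pytest.fixture(scope="session")
def registry():
    return figure_parameter_registry()


@pytest.fixture(scope="session")
def fig3_params(registry):
    return registry["fig3"].micro


@pytest.fixture(scope="session")
def section4_wave(registry):
    return registry["section4"].wave


@pytest.fixture(scope="session")
def fig3_coeffs(fig3_params):
    return derive_continuum_coefficients(fig3_params)


@pytest.fixture(scope="session")
def fig3_background(fig3_coeffs, fig3_params, section4_wave):
    return make_background(fig3_coeffs, section4_wave.lambda0, fig3_params.chi,
                           section4_wave.phi0_amp, section4_wave.psi0_amp,
                           K=section4_wave.K0)


@pytest.fixture
def small_lattice(fig3_params):
    return toy_lattice(16, seed=7, amplitude=0.05, params=fig3_params)
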