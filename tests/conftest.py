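import numpy as np
import pytest

from fracwell import (
    DoubleWellGeometry,
    EffectiveCoefficients,
    assemble_state,
    solve_doublet,
)


@pytest.fixture(scope="session")
def coeffs():
    """mu = 1, hbar_eff = 2 (equivalently m0 = 1, lam = 1, dt = anything, DF = 2)."""
    return EffectiveCoefficients.from_mu_hbar(1.0, 2.0)


@pytest.fixture(scope="session")
def geometry():
    return DoubleWellGeometry(l=2.0, d=0.5, V0=10.0)


@pytest.fixture(scope="session")
def doublet(geometry, coeffs):
    return solve_doublet(geometry, coeffs)


@pytest.fixture(scope="session")
def sym_state(doublet, geometry, coeffs):
    return assemble_state(doublet.E_S, "symmetric", geometry, coeffs.mu)


@pytest.fixture(scope="session")
def anti_state(doublet, geometry, coeffs):
    return assemble_state(doublet.E_A, "antisymmetric", geometry, coeffs.mu)
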