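import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fracwell import (
    DoubleWellGeometry,
    EffectiveCoefficients,
    assemble_state,
    degeneracy_ratio,
    secular_residual,
    solve_doublet,
    solve_matching_ratio,
    splitting_sweep,
    transfer_times,
    wavenumbers,
)
from fracwell.errors import (
    InvalidInputError,
    InvalidParameterError,
    MatchingInconsistencyError,
    NoSubBarrierStateError,
    OutOfRangeError,
)

# frozen from the exact closed forms (box levels mu*(pi/2l)^2, mu*(pi/l)^2 at l=2)
E_S_BOX = 0.6168502750680849
E_A_BOX = 2.4674011002723395


class TestGeometry:
    def test_invariants(self):
        with pytest.raises(InvalidParameterError):
            DoubleWellGeometry(l=2, d=2, V0=10)  # d must be < l
        with pytest.raises(InvalidParameterError):
            DoubleWellGeometry(l=2, d=-0.1, V0=10)
        with pytest.raises(InvalidParameterError):
            DoubleWellGeometry(l=2, d=0.5, V0=0)

    def test_potential_regions(self):
        g = DoubleWellGeometry(l=2, d=0.5, V0=10)
        z = np.array([-3, -2, -1, -0.25, 0, 0.25, 1, 2, 3])
        U = g.potential(z)
        assert np.all(np.isinf(U[np.abs(z) >= 2]))
        assert np.all(U[(np.abs(z) < 0.5)] == 10)
        assert np.all(U[(np.abs(z) >= 0.5) & (np.abs(z) < 2)] == 0)


class TestWavenumbers:
    def test_closed_form(self):
        g = DoubleWellGeometry(l=2, d=0.5, V0=25)
        wn = wavenumbers(9.0, g, mu=1.0)
        assert (wn.k, wn.q) == (3.0, 4.0)

    def test_limits_and_range(self):
        g = DoubleWellGeometry(l=2, d=0.5, V0=25)
        assert wavenumbers(25.0, g, 1.0).q == 0.0  # barrier top
        assert wavenumbers(0.0, g, 1.0).k == 0.0
        with pytest.raises(OutOfRangeError):
            wavenumbers(26.0, g, 1.0)  # above-barrier unsupported
        with pytest.raises(OutOfRangeError):
            wavenumbers(-1.0, g, 1.0)

    @given(E=st.floats(0.01, 24.99), mu=st.floats(0.1, 10))
    @settings(max_examples=50, derandomize=True)
    def test_sum_rule(self, E, mu):
        # k^2 + q^2 = V0/mu along every solver path
        g = DoubleWellGeometry(l=2, d=0.5, V0=25)
        wn = wavenumbers(E, g, mu)
        assert wn.k**2 + wn.q**2 == pytest.approx(g.V0 / mu, rel=1e-12)


class TestSecularResidual:
    def test_barrierless_reduction_symmetric(self):
        # d=0: F_sym ~ k cos(kl); root at kl = pi/2
        g = DoubleWellGeometry(l=2, d=0.0, V0=10)
        assert secular_residual(E_S_BOX, g, 1.0, "symmetric") == pytest.approx(0, abs=1e-12)
        E = 0.3
        k = math.sqrt(E)
        assert secular_residual(E, g, 1.0, "symmetric") == pytest.approx(
            k * math.cos(k * 2), rel=1e-12
        )

    def test_barrierless_reduction_antisymmetric(self):
        # d=0: F_anti ~ q sin(kl); root at kl = pi
        g = DoubleWellGeometry(l=2, d=0.0, V0=10)
        assert secular_residual(E_A_BOX, g, 1.0, "antisymmetric") == pytest.approx(0, abs=1e-12)
        E = 0.3
        k, q = math.sqrt(E), math.sqrt(10 - E)
        assert secular_residual(E, g, 1.0, "antisymmetric") == pytest.approx(
            q * math.sin(k * 2), rel=1e-12
        )

    def test_sign_change_brackets_fd_ground_state(self):
        # the residual changes sign across the lowest finite-difference eigenvalue
        from fracwell import build_hamiltonian, lowest_eigenpairs

        g = DoubleWellGeometry(l=2, d=0.5, V0=10)
        H = build_hamiltonian(g, 1.0, 2000)
        E0 = lowest_eigenpairs(H, 1)[0][0]
        lo = secular_residual(E0 - 0.2, g, 1.0, "symmetric")
        hi = secular_residual(E0 + 0.2, g, 1.0, "symmetric")
        assert lo * hi < 0

    def test_unknown_parity_rejected(self):
        g = DoubleWellGeometry(l=2, d=0.5, V0=10)
        with pytest.raises(InvalidInputError):
            secular_residual(1.0, g, 1.0, "even")


class TestMatchingRatio:
    @given(qd=st.floats(0.1, 10.0), d=st.floats(0.1, 1.9))
    @settings(max_examples=60, derandomize=True)
    def test_squared_ratio_is_unity(self, qd, d):
        g = DoubleWellGeometry(l=2.0, d=d, V0=10.0)
        rho_plus, rho_minus = solve_matching_ratio(1.0, qd / d, g)
        # root conditioning degrades as exp(2qd); 1e-6 covers qd up to 10
        assert rho_plus**2 == pytest.approx(1.0, rel=1e-6)
        assert rho_minus**2 == pytest.approx(1.0, rel=1e-6)

    def test_substitution_identity(self):
        # rho = +/-1 make the consistency equation vanish identically
        q, d = 1.0, 1.0
        a = math.exp(2 * q * d)
        for rho in (1.0, -1.0):
            lhs = (a * rho + 1) / (a * rho - 1) + (rho / a + 1) / (rho / a - 1)
            assert lhs == pytest.approx(0.0, abs=1e-14)

    def test_brute_force_scan_finds_only_unit_roots(self):
        # dense scan oracle over [-5, 5] minus poles
        q, d = 2.0, 0.3
        g = DoubleWellGeometry(l=2.0, d=d, V0=10.0)
        a = math.exp(2 * q * d)

        def f(rho):
            return (a * rho + 1) / (a * rho - 1) + (rho / a + 1) / (rho / a - 1)

        grid = np.linspace(-5, 5, 200001)
        vals = np.array([f(r) for r in grid])
        crossings = grid[:-1][np.sign(vals[:-1]) * np.sign(vals[1:]) < 0]
        # discard the sign flips across the two poles; only roots remain
        crossings = [c for c in crossings
                     if abs(c - 1 / a) > 1e-3 and abs(c - a) > 1e-3]
        assert len(crossings) == 2
        assert sorted(np.round(crossings, 2)) == [-1.0, 1.0]
        found = solve_matching_ratio(1.0, q, g)
        assert sorted(found) == pytest.approx([-1.0, 1.0], abs=1e-9)

    def test_nonpositive_q_rejected(self):
        g = DoubleWellGeometry(l=2.0, d=0.5, V0=10.0)
        with pytest.raises(InvalidInputError):
            solve_matching_ratio(1.0, 0.0, g)


class TestDoublet:
    def test_box_limit_exact(self, coeffs):
        dbl = solve_doublet(DoubleWellGeometry(l=2, d=0.0, V0=10), coeffs)
        assert dbl.E_S == pytest.approx(E_S_BOX, rel=1e-12)
        assert dbl.E_A == pytest.approx(E_A_BOX, rel=1e-12)

    def test_isolated_well_asymptote(self, coeffs):
        # V0 -> inf: both energies approach the single-well level mu*(pi/(l-d))^2
        dbl = solve_doublet(DoubleWellGeometry(l=2, d=1.0, V0=1e6), coeffs)
        assert dbl.delta_E / dbl.E_S < 1e-3
        assert dbl.E_S == pytest.approx(math.pi**2, rel=0.01)

    def test_ordering_and_transfer_times(self, doublet, coeffs):
        assert 0 < doublet.E_S < doublet.E_A < doublet.geometry.V0
        assert doublet.ratio > 1
        # tau_X * E_X = hbar_eff for both members
        assert doublet.tau_S * doublet.E_S == pytest.approx(coeffs.hbar_eff, rel=1e-14)
        assert doublet.tau_A * doublet.E_A == pytest.approx(coeffs.hbar_eff, rel=1e-14)
        tt = transfer_times(doublet)
        assert tt["ratio"] == pytest.approx(doublet.ratio, rel=1e-14)
        assert tt["tau_A"] < tt["tau_S"]  # HDL-labelled state transfers faster

    def test_q0_reference_level(self, doublet, coeffs):
        g = doublet.geometry
        assert doublet.E0_ref == pytest.approx(coeffs.mu * (math.pi / (2 * g.l)) ** 2)
        assert doublet.q0 == pytest.approx(math.sqrt((g.V0 - doublet.E0_ref) / coeffs.mu))

    def test_no_sub_barrier_state_error(self, coeffs):
        # narrow wells + low barrier: the well level exceeds V0
        with pytest.raises(NoSubBarrierStateError):
            solve_doublet(DoubleWellGeometry(l=1.0, d=0.8, V0=5.0), coeffs)

    def test_transfer_time_warning_off_coherence(self, doublet):
        from fracwell import FractalScale

        with pytest.warns(UserWarning, match="DF=3"):
            transfer_times(doublet, FractalScale(m0=1, lam=1, dt_res=1.0, DF=3.0))


class TestSplittingSweep:
    def test_delta_E_decreases_with_barrier_height(self, coeffs):
        geoms = [DoubleWellGeometry(l=2, d=1.0, V0=v) for v in (5, 10, 50, 200)]
        table = splitting_sweep(geoms, coeffs)
        assert list(table["V0"]) == [5, 10, 50, 200]
        assert np.all(np.diff(table["delta_E"]) < 0)

    def test_delta_E_decreases_with_barrier_width(self, coeffs):
        geoms = [DoubleWellGeometry(l=2, d=d, V0=10) for d in (0.25, 0.5, 0.75, 1.0)]
        table = splitting_sweep(geoms, coeffs)
        assert np.all(np.diff(table["delta_E"]) < 0)

    def test_barrierless_entry_exact_splitting(self, coeffs):
        # d=0: delta_E = 3 mu pi^2 / (4 l^2) exactly
        table = splitting_sweep([DoubleWellGeometry(l=2, d=0.0, V0=10)], coeffs)
        assert len(table) == 1
        assert table["delta_E"][0] == pytest.approx(3 * math.pi**2 / 16, rel=1e-12)

    def test_varying_both_parameters_rejected(self, coeffs):
        geoms = [
            DoubleWellGeometry(l=2, d=0.5, V0=10),
            DoubleWellGeometry(l=2, d=1.0, V0=20),
        ]
        with pytest.raises(InvalidInputError):
            splitting_sweep(geoms, coeffs)


class TestAssembledStates:
    def test_matching_defect_and_parity(self, sym_state, anti_state):
        z = np.linspace(-2, 2, 2001)
        for state, sign in ((sym_state, 1), (anti_state, -1)):
            vals = state(z)
            assert np.max(np.abs(vals - sign * vals[::-1])) < 1e-9
        assert sym_state.A == pytest.approx(-sym_state.D, rel=1e-12)
        assert anti_state.A == pytest.approx(anti_state.D, rel=1e-12)
        assert sym_state.C / sym_state.B == pytest.approx(1.0, rel=1e-9)
        assert anti_state.C / anti_state.B == pytest.approx(-1.0, rel=1e-9)

    def test_unit_norm_and_wall_conditions(self, sym_state, anti_state):
        z = np.linspace(-2, 2, 20001)
        for state in (sym_state, anti_state):
            assert np.trapezoid(state(z) ** 2, z) == pytest.approx(1.0, abs=1e-7)
            assert state(np.array([-2.0, 2.0])) == pytest.approx([0.0, 0.0], abs=1e-12)
            assert state(0.5 * (0.5 + 2.0)) > 0  # sign convention: right well positive

    def test_interface_continuity_shrinks_with_offset(self, sym_state):
        defects = []
        for off in (1e-3, 1e-6, 1e-9):
            defects.append(abs((sym_state(0.5 - off) - sym_state(0.5 + off)).item()))
        assert defects[0] > defects[1] > defects[2]
        assert defects[2] < 1e-7

    def test_antisymmetric_node_at_origin(self, anti_state):
        assert abs(anti_state(0.0).item()) < 1e-12

    def test_non_eigenenergy_rejected(self, geometry):
        with pytest.raises(MatchingInconsistencyError):
            assemble_state(1.234, "symmetric", geometry, 1.0)


class TestDegeneracyRatio:
    def test_high_precision_value(self):
        # oracle: coth^2(1) = ((e^2+1)/(e^2-1))^2 evaluated in closed form
        assert degeneracy_ratio(1.0, 1.0) == pytest.approx(1.7240616609663102, rel=1e-14)

    @given(x=st.floats(1e-3, 10.0))
    @settings(max_examples=100, derandomize=True)
    def test_always_above_one(self, x):
        # strict in exact arithmetic for all x > 0; tanh saturates to 1.0 in
        # double precision near x ~ 19, which bounds the resolvable range
        assert degeneracy_ratio(x, 1.0) > 1.0

    def test_monotone_decreasing_to_unity(self):
        xs = np.geomspace(0.01, 10, 200)
        vals = np.array([degeneracy_ratio(x, 1.0) for x in xs])
        assert np.all(np.diff(vals) < 0)
        assert degeneracy_ratio(30.0, 1.0) == pytest.approx(1.0, abs=1e-15)

    def test_nonpositive_argument_rejected(self):
        with pytest.raises(InvalidInputError):
            degeneracy_ratio(0.0, 1.0)
        with pytest.raises(InvalidInputError):
            degeneracy_ratio(1.0, -1.0)
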