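"""RF transition blocks, shift, relaxation-exchange propagators,
lineshapes, and the pulsed-saturation exponent."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epgx.models import EPGXState, TwoPoolBMModel, TwoPoolMTModel, derived_rates
from epgx.operators import (
    GAMMA_RAD_PER_S_PER_UT,
    hard_pulse_energy,
    lineshape_value,
    relaxation_exchange,
    rf_transition,
    rf_transition_block,
    saturation_exponent,
    shift,
    super_lorentzian_raw,
)


def rotation_oracle(alpha, phi):
    """Brute-force 3D rotation (angle alpha about the in-plane axis at
    azimuth phi) conjugated into the (M+, M-, Mz) basis."""
    rz = lambda t: np.array(  # noqa: E731
        [[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]]
    )
    rx = lambda t: np.array(  # noqa: E731
        [[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]]
    )
    r = rz(phi) @ rx(alpha) @ rz(-phi)
    u = np.array([[1, 1j, 0], [1, -1j, 0], [0, 0, 1]], dtype=complex)
    return u @ r @ np.linalg.inv(u)


class TestRFTransition:
    def test_zero_flip_is_identity(self):
        assert np.allclose(rf_transition(0.0, 1.3), np.eye(3))

    def test_perfect_refocusing(self):
        t = rf_transition(np.pi, 0.0)
        expected = np.array([[0, 1, 0], [1, 0, 0], [0, 0, -1]], dtype=complex)
        assert np.allclose(t, expected, atol=1e-15)

    @given(
        alpha=st.floats(0.0, 2 * np.pi),
        phi=st.floats(-np.pi, np.pi),
    )
    def test_matches_rotation_oracle(self, alpha, phi):
        assert np.allclose(rf_transition(alpha, phi), rotation_oracle(alpha, phi), atol=1e-12)

    def test_quarter_flip_about_y(self):
        # alpha=pi/2, phi=pi/2 checked against the rotation oracle entrywise
        assert np.allclose(
            rf_transition(np.pi / 2, np.pi / 2),
            rotation_oracle(np.pi / 2, np.pi / 2),
            atol=1e-14,
        )


class TestRFTransitionBlock:
    def test_mt_zero_saturation_zero_flip_is_identity(self):
        assert np.allclose(rf_transition_block(0.0, 0.0, "mt", 0.0), np.eye(4))

    def test_bm_block_diagonal_identical_blocks(self):
        b = rf_transition_block(0.4, 0.2, "bm")
        assert np.allclose(b[:3, :3], b[3:, 3:])
        assert np.allclose(b[:3, 3:], 0)
        assert np.allclose(b[3:, :3], 0)

    def test_bm_excitation_splits_pools_by_fraction(self, myelin_bm):
        st_eq = EPGXState.equilibrium(myelin_bm, order_max=4)
        t = rf_transition(np.pi / 2, 0.0)
        from epgx.sequences import _apply_rf_free

        _apply_rf_free(st_eq, t, "a")
        _apply_rf_free(st_eq, t, "b")
        assert st_eq.fplus_a[0] == pytest.approx(-1j * 0.8, abs=1e-14)
        assert st_eq.fplus_b[0] == pytest.approx(-1j * 0.2, abs=1e-14)

    def test_mt_pure_saturation_scales_all_bound_orders(self):
        b = rf_transition_block(0.0, 0.0, "mt", wsat_exponent=1.7)
        assert np.allclose(b[:3, :3], np.eye(3))
        assert b[3, 3] == pytest.approx(np.exp(-1.7))

    def test_negative_saturation_rejected(self):
        with pytest.raises(ValueError):
            rf_transition_block(0.1, 0.0, "mt", wsat_exponent=-0.1)


class TestShift:
    def test_single_state_moves_up_one_order(self, myelin_bm):
        s = EPGXState.equilibrium(myelin_bm, order_max=4)
        s.fplus_a[0] = 0.3 - 0.1j
        s.fminus_a[0] = np.conj(s.fplus_a[0])
        shift(s)
        assert s.fplus_a[1] == pytest.approx(0.3 - 0.1j)
        assert s.fplus_a[0] == 0.0  # former F(-1)* ladder was empty
        assert np.all(s.z_a == EPGXState.equilibrium(myelin_bm, 4).z_a)

    def test_matches_pointwise_phase_in_profile_domain(self, rng, myelin_bm):
        """Shifting configuration states equals multiplying the
        reconstructed intravoxel profile by e^{i psi}."""
        from epgx.isochromat import states_to_profile

        s = EPGXState.equilibrium(myelin_bm, order_max=8)
        for arr in (s.fplus_a, s.fminus_a, s.fplus_b, s.fminus_b):
            arr[:5] = rng.standard_normal(5) + 1j * rng.standard_normal(5)
        s.fminus_a[0] = np.conj(s.fplus_a[0])
        s.fminus_b[0] = np.conj(s.fplus_b[0])
        psi = np.linspace(-np.pi, np.pi, 33, endpoint=False)
        before_a, _ = states_to_profile(s, psi, pool="a")
        before_b, _ = states_to_profile(s, psi, pool="b")
        shift(s)
        after_a, _ = states_to_profile(s, psi, pool="a")
        after_b, _ = states_to_profile(s, psi, pool="b")
        assert np.allclose(after_a, before_a * np.exp(1j * psi), atol=1e-12)
        assert np.allclose(after_b, before_b * np.exp(1j * psi), atol=1e-12)

    def test_conjugate_symmetry_preserved_at_order_zero(self, rng, myelin_bm):
        s = EPGXState.equilibrium(myelin_bm, order_max=6)
        s.fplus_a[:4] = rng.standard_normal(4) + 1j * rng.standard_normal(4)
        s.fminus_a[:4] = rng.standard_normal(4) + 1j * rng.standard_normal(4)
        s.fminus_a[0] = np.conj(s.fplus_a[0])
        for _ in range(3):
            shift(s)
            assert s.fminus_a[0] == pytest.approx(np.conj(s.fplus_a[0]), abs=1e-12)


class TestRelaxationExchange:
    def test_decoupled_pools_are_scalar_decays(self):
        m = TwoPoolBMModel(t1a=1000, t1b=500, t2a=100, t2b=20, ka=0.0, f=0.2)
        p = relaxation_exchange(m, 7.0)
        assert p.xi_t[0, 0] == pytest.approx(np.exp(-7.0 / 100.0))
        assert p.xi_t[2, 2] == pytest.approx(np.exp(-7.0 / 20.0))
        assert np.allclose(p.xi_t - np.diag(np.diag(p.xi_t)), 0)
        assert p.xi_l[0, 0] == pytest.approx(np.exp(-7.0 / 1000.0))

    def test_zero_interval_is_identity_with_no_recovery(self, myelin_bm):
        p = relaxation_exchange(myelin_bm, 0.0)
        assert np.allclose(p.xi_t, np.eye(4))
        assert np.allclose(p.xi_l, np.eye(2))
        assert np.allclose(p.recovery, 0)

    def test_matches_taylor_series_exponential(self, myelin_bm):
        """Propagator agrees with an independent series evaluation of
        exp(Lambda*dt) for the myelin model at dt = 5 ms."""
        r = derived_rates(myelin_bm)
        dt = 5e-3
        lam_t = np.array(
            [
                [-r.r2a - r.ka, 0, r.kb, 0],
                [0, -r.r2a - r.ka, 0, r.kb],
                [r.ka, 0, -r.r2b - r.kb, 0],
                [0, r.ka, 0, -r.r2b - r.kb],
            ],
            dtype=complex,
        )

        def series_exp(a):
            out = np.eye(a.shape[0], dtype=complex)
            term = np.eye(a.shape[0], dtype=complex)
            for k in range(1, 40):
                term = term @ a / k
                out = out + term
            return out

        p = relaxation_exchange(myelin_bm, 5.0)
        assert np.allclose(p.xi_t, series_exp(lam_t * dt), atol=1e-12)

    def test_equilibrium_is_fixed_point_of_recovery(self, myelin_bm):
        """[M0a, M0b] maps to itself under the order-0 longitudinal
        update for any interval."""
        r = derived_rates(myelin_bm)
        eq = np.array([r.m0a, r.m0b])
        for dt in (0.1, 5.0, 500.0, 7000.0):
            p = relaxation_exchange(myelin_bm, dt)
            assert np.allclose(p.xi_l @ eq + p.recovery, eq, atol=1e-12)

    def test_exchange_couples_same_type_and_order_only(self, myelin_bm):
        """No matrix entry connects + and - transverse families."""
        p = relaxation_exchange(myelin_bm, 5.0)
        coupling = np.array(
            [[1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1]], dtype=bool
        )
        assert np.all(p.xi_t[~coupling] == 0)

    def test_free_pool_limit_reproduces_single_pool(self):
        m = TwoPoolBMModel(t1a=1000, t1b=500, t2a=100, t2b=20, ka=0.0, f=0.0)
        p = relaxation_exchange(m, 9.0)
        assert p.xi_t[0, 0] == pytest.approx(np.exp(-9.0 / 100.0), rel=1e-14)
        assert p.xi_l[0, 0] == pytest.approx(np.exp(-9.0 / 1000.0), rel=1e-14)
        assert p.recovery[0] == pytest.approx(0.8 * 0 + (1 - np.exp(-9.0 / 1000.0)), rel=1e-12)

    @given(
        ka=st.floats(0.1, 20.0),
        f=st.floats(0.02, 0.45),
        delta_b=st.floats(-100.0, 100.0),
        dt=st.floats(0.5, 20.0),
    )
    def test_relaxation_commutes_with_uniform_precession(self, ka, f, delta_b, dt):
        """exp(Lambda_T dt) exp(Omega dt) == exp((Lambda_T + Omega) dt):
        the gradient/off-resonance precession generator is a multiple of
        the identity within each +/- family and commutes with exchange."""
        from scipy.linalg import expm

        m = TwoPoolBMModel(
            t1a=1000, t1b=500, t2a=100, t2b=20, ka=ka, f=f, delta_b=delta_b
        )
        p = relaxation_exchange(m, dt)
        wz = 2 * np.pi * 37.0  # arbitrary off-resonance, rad/s
        omega = np.diag([-1j * wz, 1j * wz, -1j * wz, 1j * wz])
        r = derived_rates(m)
        lam_t = np.array(
            [
                [-r.r2a - r.ka, 0, r.kb, 0],
                [0, -r.r2a - r.ka, 0, r.kb],
                [r.ka, 0, -r.r2b - r.kb - 2j * np.pi * delta_b, 0],
                [0, r.ka, 0, -r.r2b - r.kb + 2j * np.pi * delta_b],
            ],
            dtype=complex,
        )
        dt_s = dt * 1e-3
        lhs = p.xi_t @ expm(omega * dt_s)
        rhs = expm((lam_t + omega) * dt_s)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_energy_not_created_without_recovery(self, rng, myelin_bm):
        """With the recovery term removed, total state power is
        non-increasing over an interval (passive relaxation/exchange)."""
        from epgx.sequences import _apply_relax

        s = EPGXState.equilibrium(myelin_bm, order_max=5)
        for arr in (s.fplus_a, s.fminus_a, s.fplus_b, s.fminus_b, s.z_a, s.z_b):
            arr[:] = 0.3 * (rng.standard_normal(6) + 1j * rng.standard_normal(6))
        power = lambda: sum(  # noqa: E731
            float(np.sum(np.abs(a) ** 2))
            for a in (s.fplus_a, s.fminus_a, s.fplus_b, s.fminus_b, s.z_a, s.z_b)
        )
        p = relaxation_exchange(myelin_bm, 5.0)
        p.recovery = np.zeros_like(p.recovery)
        before = power()
        _apply_relax(s, p)
        assert power() <= before + 1e-12


class TestLineshape:
    def test_on_resonance_value_for_12us(self):
        # conventional on-resonance value for a 12 us semisolid pool
        assert lineshape_value(0.0, 12.0) == pytest.approx(15.1, rel=0.01)

    def test_symmetric_in_offset(self):
        offs = np.array([500.0, 2000.0, 10000.0])
        assert np.allclose(
            lineshape_value(offs, 12.0), lineshape_value(-offs, 12.0), rtol=1e-9
        )

    def test_spline_matches_quadrature_outside_band(self):
        v = lineshape_value(2780.0, 12.0)
        assert v == pytest.approx(super_lorentzian_raw(2780.0, 12.0), rel=1e-8)

    def test_gaussian_closed_form(self):
        t2b = 12.0
        assert lineshape_value(0.0, t2b, "gaussian") == pytest.approx(
            t2b / np.sqrt(2 * np.pi), rel=1e-12
        )

    def test_table_round_trip(self, tmp_path):
        from epgx.operators import LineshapeTable

        table = LineshapeTable.build([0.0, 2000.0, 5000.0], 12.0)
        path = tmp_path / "lineshape.csv"
        table.to_csv(path)
        back = LineshapeTable.from_csv(path, 12.0)
        assert np.allclose(back.g, table.g)


class TestSaturationExponent:
    def test_zero_energy_means_no_saturation(self):
        assert saturation_exponent(0.0, 15.1) == 0.0
        assert np.exp(-saturation_exponent(0.0, 15.1)) == 1.0

    def test_unit_analysis_against_hand_formula(self):
        # pi * gamma^2 * E * G with explicit conversions, for the
        # small-flip pulse energy model E = 54.3*alpha^2 ms uT^2
        alpha = np.deg2rad(10)
        e = 54.3 * alpha**2  # ms uT^2
        g = 15.1  # us
        by_hand = (
            np.pi
            * GAMMA_RAD_PER_S_PER_UT**2
            * (e * 1e-3)
            * (g * 1e-6)
        )
        assert saturation_exponent(e, g) == pytest.approx(by_hand, rel=1e-14)

    def test_hard_pulse_exponent_linear_in_flip(self):
        g = 15.1
        exps = [
            saturation_exponent(hard_pulse_energy(a, 13.5), g)
            for a in (0.1, 0.2, 0.4)
        ]
        assert exps[1] == pytest.approx(2 * exps[0], rel=1e-12)
        assert exps[2] == pytest.approx(4 * exps[0], rel=1e-12)

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            saturation_exponent(-1.0, 15.1)
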