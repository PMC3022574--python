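import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lamella as lm
from lamella.oracles import constant_rate_t_uc_min, constant_rate_trajectory


R_CONST = 9.0


@pytest.fixture(scope="module")
def const_traj(params, controls, edge15):
    t_end = 10.0 + params.L_sys / edge15.V + 1.0
    return constant_rate_trajectory(params, R_CONST, t_end, controls.dt)


class TestPlusEndRate:
    def test_zero_monomer_gives_pure_off_rate(self, params):
        assert lm.plus_end_rate(0.0, 1.0, params) == pytest.approx(-1.4)

    def test_critical_concentration_at_zero_load(self, params):
        c_crit = params.k_off_plus / params.k_on_plus
        assert lm.plus_end_rate(c_crit, 0.0, params) == pytest.approx(0.0, abs=1e-12)

    def test_physiological_edge_rate_and_speed(self, params):
        # c0 = 15 uM under ~1 pN load: ~103 subunits/s, ~13.6 um/min
        f = lm.filament_force(params.B, params)
        r = lm.plus_end_rate(15.0, f, params)
        assert r == pytest.approx(103.0, rel=0.01)
        assert params.delta_p * r * 60.0 == pytest.approx(13.6, rel=0.01)

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            lm.plus_end_rate(-1.0, 0.0, params)


class TestEdgeState:
    def test_speed_and_density_identities(self, params):
        edge = lm.make_edge_state(12.0, params)
        assert edge.V == pytest.approx(params.delta_p * edge.r_plus)
        assert edge.B_eff == pytest.approx(edge.N0 / params.r_cap)

    def test_fixed_n0_mode_raises_load_with_capping(self, params):
        fast = lm.make_edge_state(12.0, params.replace(r_cap=2.0))
        base = lm.make_edge_state(12.0, params)
        assert fast.N0 == base.N0
        assert fast.B_eff == pytest.approx(base.B_eff / 2)
        assert fast.f == pytest.approx(2 * base.f)

    def test_fixed_b_mode_keeps_density(self, params):
        fast = lm.make_edge_state(12.0, params.replace(r_cap=2.0), "fixed_B")
        assert fast.B_eff == params.B
        assert fast.N0 == pytest.approx(params.B * 2.0)


class TestFilamentLength:
    def test_zero_times_give_zero_length(self, edge15, const_traj):
        assert lm.filament_length(0.0, 0.0, edge15, const_traj) == 0.0

    def test_constant_rate_closed_form(self, params, edge15, const_traj):
        t_uc, tau_c = 2.0, 3.0
        expected = params.delta_p * (
            edge15.r_plus * t_uc - R_CONST * (t_uc + tau_c)
        )
        got = lm.filament_length(t_uc, tau_c, edge15, const_traj)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_full_depolymerization_floors_at_zero(self, edge15, const_traj):
        # long capped time: shrinkage exceeds growth
        assert lm.filament_length(0.1, 40.0, edge15, const_traj) == 0.0


class TestMinUncappedTime:
    def test_zero_probe_zero_group(self, edge15, const_traj):
        assert lm.min_uncapped_time(0.0, 0.0, edge15, const_traj) == 0.0

    def test_constant_rate_inversion(self, params, edge15, const_traj):
        theta, tau_c = 0.5, 2.0
        expected = constant_rate_t_uc_min(theta, tau_c, edge15, R_CONST, params)
        got = lm.min_uncapped_time(theta, tau_c, edge15, const_traj)
        assert got == pytest.approx(float(expected), abs=1e-6)
        # round-trip: the returned time reaches the probe length within 1e-4 um
        L = lm.filament_length(got, tau_c, edge15, const_traj)
        assert abs(L - theta) < 1e-4

    def test_agrees_with_brute_force_grid_scan(self, edge15, const_traj):
        theta, tau_c = 0.8, 1.5
        t = const_traj.t_grid[const_traj.t_grid <= 10.0]
        L = lm.filament_length(t, tau_c, edge15, const_traj)
        brute = t[np.argmax(L >= theta)]
        got = lm.min_uncapped_time(theta, tau_c, edge15, const_traj)
        assert abs(got - brute) <= const_traj.dt

    def test_unreachable_probe_returns_infinity(self, edge15, const_traj):
        assert np.isinf(
            lm.min_uncapped_time(50.0, 0.0, edge15, const_traj, t_uc_max=10.0)
        )

    @settings(deadline=None, max_examples=20)
    @given(
        theta=st.floats(min_value=0.0, max_value=1.5),
        dtheta=st.floats(min_value=0.0, max_value=0.5),
        tau=st.floats(min_value=0.0, max_value=5.0),
        dtau=st.floats(min_value=0.0, max_value=5.0),
    )
    def test_nondecreasing_in_probe_and_capped_time(
        self, params, edge15, const_traj, theta, dtheta, tau, dtau
    ):
        a = lm.min_uncapped_time(theta, tau, edge15, const_traj, t_uc_max=10.0)
        b = lm.min_uncapped_time(
            theta + dtheta, tau + dtau, edge15, const_traj, t_uc_max=10.0
        )
        assert b >= a - 1e-12


def test_capping_density_normalization(params, edge15):
    # int_0^inf N0 r_cap exp(-r_cap t) dt = N0
    t = np.linspace(0, 60, 200001)
    total = np.trapezoid(edge15.N0 * params.r_cap * np.exp(-params.r_cap * t), t)
    assert total == pytest.approx(edge15.N0, rel=1e-6)
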