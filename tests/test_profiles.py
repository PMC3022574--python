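import numpy as np
import pytest

import lamella as lm
from lamella.profiles import compute_profiles, group_density, length_distribution
from lamella.oracles import constant_rate_trajectory, constant_rate_t_uc_min


R_CONST = 9.0


@pytest.fixture(scope="module")
def const_traj(params, controls, edge15):
    t_end = 10.0 + params.L_sys / edge15.V + 1.0
    return constant_rate_trajectory(params, R_CONST, t_end, controls.dt)


@pytest.fixture(scope="module")
def profiles(params, controls, edge15, traj_baseline):
    return compute_profiles(edge15, traj_baseline, params, controls)


class TestGroupDensity:
    def test_heaviside_ahead_of_plus_ends(self, params, edge15, const_traj):
        tau_c = 5.0
        x = 0.9 * edge15.V * tau_c
        assert group_density(x, tau_c, edge15, const_traj, params) == 0.0

    def test_constant_rate_closed_form(self, params, edge15, const_traj):
        tau_c, x = 2.0, 1.5
        theta = x - edge15.V * tau_c
        t_min = constant_rate_t_uc_min(theta, tau_c, edge15, R_CONST, params)
        expected = edge15.N0 * np.exp(-params.r_cap * t_min)
        got = group_density(x, tau_c, edge15, const_traj, params)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_quadrature_of_capping_density_matches_closed_form(
        self, params, edge15, const_traj
    ):
        # integrate the exponential capping density above t_uc_min explicitly
        tau_c, x = 1.0, 0.8
        t_min = float(lm.min_uncapped_time(
            x - edge15.V * tau_c, tau_c, edge15, const_traj
        ))
        t = np.linspace(t_min, t_min + 40.0, 400001)
        quad = np.trapezoid(
            edge15.N0 * params.r_cap * np.exp(-params.r_cap * t), t
        )
        closed = group_density(x, tau_c, edge15, const_traj, params)
        assert quad == pytest.approx(closed, rel=1e-6)


class TestFActinProfile:
    def test_leading_edge_density_equals_plus_end_density(self, profiles, edge15):
        assert profiles.F[0] == pytest.approx(edge15.B_eff)
        assert profiles.F_uc[0] == pytest.approx(edge15.B_eff)
        assert profiles.F_c[0] == 0.0

    def test_total_is_capped_plus_uncapped(self, profiles):
        assert np.allclose(profiles.F, profiles.F_c + profiles.F_uc)

    def test_no_polymerization_behind_the_edge(self, profiles):
        # F is monotone nonincreasing (depolymerization only for x > 0)
        assert np.all(np.diff(profiles.F) <= 1e-9)

    def test_fields_nonnegative(self, profiles):
        for field in (profiles.F, profiles.F_c, profiles.F_uc, profiles.M,
                      profiles.J_d, profiles.L_mean):
            assert np.all(field >= 0.0)

    def test_truncation_diagnostic_clean_at_baseline(self, profiles):
        assert profiles.meta["truncation_ok"]


class TestMinusEndsAndSource:
    def test_source_vanishes_at_the_edge(self, profiles):
        assert profiles.J_d[0] == 0.0

    def test_debranched_fraction_rises_rearward(self, params, traj_baseline,
                                                edge15):
        # under the transport-age identification the debranched fraction at x
        # is 1 - exp(-r_deb x / V): check monotone increase
        x = np.linspace(0, params.L_sys, 50)
        frac = 1.0 - np.exp(-params.r_deb * x / edge15.V)
        assert np.all(np.diff(frac) > 0)
        assert frac[-1] > 0.99

    def test_minus_end_mass_accounts_for_all_filaments(self, params, profiles,
                                                       edge15):
        # every surviving filament carries exactly one minus end; the
        # deposition must conserve the crossing bookkeeping: M <= F/… loose
        # sanity plus positivity in the bulk
        assert profiles.M[0] > 0
        assert np.all(profiles.M[:-1] > 0)


class TestRegulatorProfiles:
    def test_all_subunits_are_fresh_at_the_edge(self, profiles):
        assert profiles.F_ac[0] == 0.0
        assert profiles.F_tm[0] == 0.0

    def test_bound_fractions_below_total(self, profiles):
        assert np.all(profiles.F_ac + profiles.F_tm <= profiles.F + 1e-9)

    def test_no_tropomyosin_means_no_tm_actin(self, params, controls, edge15):
        p = params.replace(r_tm=0.0)
        traj = lm.subunit_trajectory(
            p, controls.resolved_t_uc_max(p) + p.L_sys / edge15.V + 1, controls.dt
        )
        prof = compute_profiles(edge15, traj, p, controls)
        assert np.all(prof.F_tm == 0.0)


class TestLengthDistribution:
    def test_normalized_at_every_position(self, params, controls, edge15,
                                          traj_baseline):
        ld = length_distribution([0.0, 1.0, 5.0, 9.0], edge15, traj_baseline,
                                 params, controls)
        norms = ld.P.sum(axis=1) * ld.dL
        assert np.abs(norms - 1.0).max() < 1e-3
        assert np.all(ld.P >= -1e-12)

    def test_edge_distribution_falls_off_exponentially(self, params, controls,
                                                       edge15, traj_baseline):
        # at x = 0 only the uncapped group contributes: log P is linear in L
        ld = length_distribution([0.0], edge15, traj_baseline, params, controls)
        P = ld.P[0]
        sel = P > 1e-4 * P.max()
        logp = np.log(P[sel])
        slope = np.diff(logp) / ld.dL
        assert np.all(slope < 0)                       # strictly decaying
        assert np.std(slope[5:-5]) / np.abs(np.mean(slope[5:-5])) < 0.05

    def test_mean_matches_profile_field(self, params, controls, edge15,
                                        traj_baseline, profiles):
        ld = length_distribution([2.0, 8.0], edge15, traj_baseline, params,
                                 controls)
        for xv, lmean in zip(ld.x_values, ld.L_mean):
            i = int(round(xv / controls.dx))
            assert lmean == pytest.approx(profiles.L_mean[i], rel=0.02)

    def test_undefined_where_no_filaments(self, params, controls):
        # rapid capping keeps every filament short: nothing reaches the rear
        p = params.replace(r_cap=2.0)
        edge = lm.make_edge_state(15.0, p)
        traj = constant_rate_trajectory(p, R_CONST, 40.0, controls.dt)
        with pytest.raises(ValueError):
            length_distribution([8.0], edge, traj, p, controls, x_max=10.0)
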