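import numpy as np
import pytest

import lamella as lm
from lamella.profiles import compute_profiles
from lamella.oracles import (
    constant_rate_solution,
    constant_rate_trajectory,
    deposit_spans,
    ensemble_brute_force,
    exact_age_map_solution,
)


R_CONST = 9.0


@pytest.fixture(scope="module")
def const_setup(params, controls, edge15):
    t_end = 10.0 + params.L_sys / edge15.V + 1.0
    traj = constant_rate_trajectory(params, R_CONST, t_end, controls.dt)
    prof = compute_profiles(edge15, traj, params, controls)
    return traj, prof


class TestConstantRateOracle:
    def test_uncapped_profile_closed_form(self, params, edge15, const_setup):
        traj, prof = const_setup
        x = prof.x_grid
        expected = edge15.B_eff * np.exp(
            -params.r_cap * x / (params.delta_p * (edge15.r_plus - R_CONST))
        )
        # compare above the uncapped-time truncation horizon (survival e^-10)
        sel = expected > 2.0 * np.exp(-10.0) * edge15.B_eff
        rel = np.abs(prof.F_uc[sel] - expected[sel]) / expected[sel]
        assert rel.max() < 0.01

    def test_pipeline_matches_closed_forms_under_five_percent(
        self, params, controls, edge15, const_setup
    ):
        traj, prof = const_setup
        cf = constant_rate_solution(
            params, edge15, R_CONST, prof.x_grid, t_uc_max=10.0
        )
        rel_F = np.abs(prof.F - cf["F"]) / cf["F"]
        rel_L = np.abs(prof.L_mean - cf["L_mean"]) / cf["L_mean"]
        assert rel_F.max() < 0.05
        assert rel_L.max() < 0.05

    def test_small_rate_limit_against_ensemble(self, params, controls, edge15):
        # r -> 0: the independently derived form is cross-checked against the
        # ensemble quadrature, not assumed
        r_small = 0.2
        traj = constant_rate_trajectory(params, r_small, 80.0, controls.dt)
        cf = constant_rate_solution(
            params, edge15, r_small, np.linspace(0, 10, 101), t_uc_max=10.0
        )
        bf = ensemble_brute_force(
            params, edge15, traj, x_max=10.0, dx=0.1,
            h_t_uc=controls.dt, h_tau_c=controls.dt,
            t_uc_max=10.0, tau_c_max=60.0,
        )
        Fi = np.interp(bf["x"], cf["x"], cf["F"])
        assert (np.abs(Fi - bf["F"]) / bf["F"]).max() < 0.02

    def test_rejects_rate_outside_physical_range(self, params, edge15):
        with pytest.raises(ValueError):
            constant_rate_solution(params, edge15, edge15.r_plus + 1.0,
                                   np.linspace(0, 1, 5))


class TestEnsembleBruteForce:
    def test_matches_pipeline_at_baseline(self, params, controls, edge15,
                                          traj_baseline):
        prof = compute_profiles(edge15, traj_baseline, params, controls)
        bf = ensemble_brute_force(
            params, edge15, traj_baseline, x_max=params.L_sys, dx=0.05,
            h_t_uc=controls.dt, h_tau_c=controls.dt,
        )
        Fi = np.interp(bf["x"], prof.x_grid, prof.F)
        Mi = np.interp(bf["x"], prof.x_grid, prof.M)
        Ji = np.interp(bf["x"], prof.x_grid, prof.J_d)
        assert (np.abs(Fi - bf["F"]) / bf["F"]).max() < 0.02
        assert (np.abs(Mi - bf["M"]) / bf["M"]).max() < 0.05
        mJ = bf["J_d"] > 1e-3 * bf["J_d"].max()
        assert (np.abs(Ji - bf["J_d"])[mJ] / bf["J_d"][mJ]).max() < 0.05

    def test_agreement_tightens_under_grid_refinement(
        self, params, controls, edge15, traj_baseline
    ):
        prof = compute_profiles(edge15, traj_baseline, params, controls)

        def max_err(h):
            bf = ensemble_brute_force(
                params, edge15, traj_baseline, x_max=params.L_sys, dx=0.05,
                h_t_uc=h, h_tau_c=h,
            )
            Fi = np.interp(bf["x"], prof.x_grid, prof.F)
            return (np.abs(Fi - bf["F"]) / bf["F"]).max()

        errs = [max_err(h) for h in (0.1, 0.05, 0.01)]
        assert errs[0] > errs[1] > errs[2]

    def test_degenerate_single_group_gives_rectangle(self):
        # capping density concentrated at one (t_uc, tau_c): a rectangle
        # profile of width L between the plus and minus end
        centers, F = deposit_spans(
            np.array([2.0]), np.array([5.0]), np.array([7.0]), 10.0, 0.1
        )
        inside = (centers > 2.05) & (centers < 4.95)
        assert np.allclose(F[inside], 7.0)
        assert np.all(F[centers < 1.95] == 0.0)
        assert np.all(F[centers > 5.05] == 0.0)

    def test_total_subunit_count_conserved(self, params, controls, edge15,
                                           traj_baseline):
        bf = ensemble_brute_force(
            params, edge15, traj_baseline, x_max=params.L_sys, dx=0.05,
            h_t_uc=0.02, h_tau_c=0.02,
        )
        # integral of the crossing concentration equals the deposited span
        # length inside the box, up to x-quadrature error
        assert bf["total_subunits"] == pytest.approx(
            bf["deposited_subunits"], rel=0.02
        )
        assert bf["total_subunits"] > 0


class TestExactAgeMap:
    def test_reproduces_pipeline_f_actin_exactly(self, params, controls,
                                                 edge15, traj_baseline):
        prof = compute_profiles(edge15, traj_baseline, params, controls)
        ex = exact_age_map_solution(edge15, traj_baseline, params, prof.x_grid)
        assert (np.abs(prof.F - ex["F"]) / ex["F"]).max() < 2e-3

    def test_minus_ends_consistent_with_flux_balance(self, params, controls,
                                                     edge15, traj_baseline):
        prof = compute_profiles(edge15, traj_baseline, params, controls)
        ex = exact_age_map_solution(edge15, traj_baseline, params, prof.x_grid)
        assert (np.abs(prof.M - ex["M"]) / ex["M"]).max() < 0.02
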