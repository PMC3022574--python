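"""Fixed-point drivers closing the loop c(0) -> r+ -> profiles -> c(0).

Given a leading-edge monomer concentration the edge state, the subunit
kinetics and all spatial fields are determined; the diffusion closure then
returns an output c(0).  The steady state is the fixed point of this map,
found by damped substitution guarded by a bracketing bisection (the map is
monotone decreasing: more monomer means faster growth, more F-actin and a
smaller closure residual).  Convergence criterion: |c0_out - c0_in| below
c0_tolerance (50 nM by default).

The unconfined driver embeds the network in a box large enough that F-actin
vanishes well before the rear boundary, enlarging the box and re-solving
until F at the boundary is below 1e-3 uM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .diffusion import solve_monomer_profile
from .geometry import EdgeState, make_edge_state
from .kinetics import SubunitStateTrajectory, subunit_trajectory
from .parameters import ModelParameters, NumericalControls
from .profiles import InfeasibleIterate, SpatialProfiles, compute_profiles, tau_death

__all__ = [
    "ConvergenceError",
    "ConvergenceReport",
    "SteadyStateSolution",
    "solve_steady_state",
    "network_length",
]

#: rear F-actin (uM) below which an unconfined box is considered large enough
UNCONFINED_REAR_TOL = 1e-3


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, report: "ConvergenceReport | None" = None):
        super().__init__(message)
        self.report = report


@dataclass
class ConvergenceReport:
    converged: bool
    iterations: int
    residuals: list[float]
    c0: float
    tolerance: float
    mode: str
    x_max: float
    message: str = ""
    extra: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        d = {
            "converged": self.converged,
            "iterations": self.iterations,
            "residuals": list(map(float, self.residuals)),
            "c0": float(self.c0),
            "tolerance": self.tolerance,
            "mode": self.mode,
            "x_max": self.x_max,
            "message": self.message,
        }
        d.update({k: v for k, v in self.extra.items() if np.isscalar(v)})
        return d


@dataclass
class SteadyStateSolution:
    params: ModelParameters
    controls: NumericalControls
    mode: str
    edge: EdgeState
    profiles: SpatialProfiles
    trajectory: SubunitStateTrajectory
    report: ConvergenceReport

    @property
    def c0(self) -> float:
        return self.report.c0

    @property
    def V_um_per_min(self) -> float:
        return self.edge.V * 60.0

    def network_length(self, threshold: float | None = None) -> float:
        if threshold is None:
            threshold = self.controls.length_threshold
        return network_length(self.profiles.F, self.profiles.x_grid, threshold)


def network_length(F: np.ndarray, x_grid: np.ndarray, threshold: float) -> float:
    """First x where F drops below ``threshold`` (uM), linearly interpolated;
    +inf if F never crosses (the network fills the box)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    below = F < threshold
    if not np.any(below):
        return float("inf")
    i = int(np.argmax(below))
    if i == 0:
        return 0.0
    f0, f1 = F[i - 1], F[i]
    frac = (f0 - threshold) / (f0 - f1) if f1 != f0 else 0.0
    return float(x_grid[i - 1] + frac * (x_grid[i] - x_grid[i - 1]))


def _trajectory_for(
    p: ModelParameters, controls: NumericalControls, edge: EdgeState, x_max: float
) -> SubunitStateTrajectory:
    """Kinetics trajectory long enough to cover t_uc_max + tau_c_max, where
    tau_c_max is the earlier of complete depolymerization of the oldest group
    and transport across the box.  Grown geometrically because the
    depolymerization horizon is only known once S(t) is tabulated."""
    t_uc_max = controls.resolved_t_uc_max(p)
    tau_cap = x_max / edge.V if edge.V > 0 else 0.0
    t_end = t_uc_max + min(60.0, tau_cap) + controls.dt
    while True:
        traj = subunit_trajectory(p, t_end, controls.dt)
        td = tau_death(edge, traj, t_uc_max)
        if td is not None or traj.t_grid[-1] >= t_uc_max + tau_cap:
            return traj
        t_end *= 2.0


def _lower_c0_bound(p: ModelParameters, edge_f: float) -> float:
    """c(0) at which r+ equals the largest possible minus-end rate (profile
    construction requires monotone filament growth)."""
    r_floor = p.s_ac * p.k_off_minus
    return (p.k_off_plus + r_floor) / (p.k_on_plus * np.exp(-edge_f * p.delta_p / p.kBT))


def _solve_fixed_box(
    p: ModelParameters,
    controls: NumericalControls,
    mode: str,
    x_max: float,
    nucleation: str,
    c0_start: float | None,
) -> SteadyStateSolution:
    f = make_edge_state(1.0, p, nucleation).f         # load is c0-independent
    lo = _lower_c0_bound(p, f) * (1.0 + 1e-6)
    hi = float(p.A)
    c0 = c0_start if c0_start is not None else controls.c0_initial
    c0 = min(max(c0, lo * 1.05), hi)
    residuals: list[float] = []
    best: tuple | None = None

    for it in range(1, controls.max_iterations + 1):
        edge = make_edge_state(c0, p, nucleation)
        traj = _trajectory_for(p, controls, edge, x_max)
        prof = compute_profiles(edge, traj, p, controls, x_max)
        c_prof, c0_out = solve_monomer_profile(
            prof.J_d, prof.F, prof.x_grid, edge, p, controls, mode
        )
        g = c0_out - c0
        residuals.append(abs(g))
        if g > 0:
            lo = max(lo, c0)
        else:
            hi = min(hi, c0)
        if best is None or abs(g) < best[0]:
            prof.c = c_prof
            best = (abs(g), edge, prof, traj, c0_out)
        if abs(g) < controls.c0_tolerance and c0_out > 0:
            report = ConvergenceReport(
                converged=True, iterations=it, residuals=residuals,
                c0=float(c0_out), tolerance=controls.c0_tolerance, mode=mode,
                x_max=x_max,
                extra={"tau_c_max": prof.meta["tau_c_max"],
                       "truncation_ok": bool(prof.meta["truncation_ok"])},
            )
            prof.c = c_prof
            return SteadyStateSolution(p, controls, mode, edge, prof, traj, report)
        proposal = c0 + controls.damping * g
        if not (lo < proposal < hi):
            proposal = 0.5 * (lo + hi)
        if hi - lo < 1e-12:
            break
        c0 = proposal

    report = ConvergenceReport(
        converged=False, iterations=len(residuals), residuals=residuals,
        c0=float(best[4]) if best else float("nan"),
        tolerance=controls.c0_tolerance, mode=mode, x_max=x_max,
        message="fixed-point iteration did not reach tolerance",
    )
    raise ConvergenceError(report.message, report)


def solve_steady_state(
    p: ModelParameters,
    controls: NumericalControls | None = None,
    mode: str = "confined",
    nucleation: str = "fixed_N0",
    c0_start: float | None = None,
    box0: float = 60.0,
    max_box: float = 2000.0,
) -> SteadyStateSolution:
    """Solve the steady state in confined or unconfined mode.

    Confined mode solves on [0, L_sys] with the convergence-zone boundary
    flux.  Unconfined mode solves on a growing box (initial size ``box0`` um,
    spatial step <= 0.1 um, group spacing 10*dt unless set) until rear
    F-actin falls below 1e-3 uM.
    """
    if mode == "confined":
        if controls is None:
            controls = NumericalControls()
        return _solve_fixed_box(p, controls, mode, p.L_sys, nucleation, c0_start)
    if mode != "unconfined":
        raise ValueError(f"unknown mode {mode!r}")
    if controls is None:
        controls = NumericalControls(dx=0.1, dtau_c=0.1)
    elif controls.dtau_c is None:
        controls = controls.replace(dtau_c=10.0 * controls.dt)
    if controls.dx > 0.1:
        raise ValueError("unconfined mode requires dx <= 0.1 um")
    box = box0
    c0 = c0_start
    while True:
        sol = _solve_fixed_box(p, controls, mode, box, nucleation, c0)
        if sol.profiles.F[-1] < UNCONFINED_REAR_TOL:
            return sol
        c0 = sol.c0
        # estimate of the network's compact support from the minus-end locus
        # x_m(t) = V t - delta_p S(t) at the death time of the oldest group
        traj, edge = sol.trajectory, sol.edge
        target = edge.r_plus * controls.resolved_t_uc_max(p)
        if traj.S[-1] >= target:
            t_death = float(np.interp(target, traj.S, traj.t_grid))
            support = edge.V * t_death - p.delta_p * target
        else:
            support = box
        box = max(1.5 * box, 1.05 * support)
        if box > max_box:
            raise ConvergenceError(
                f"unconfined network did not fit below the {max_box} um box cap"
            )
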