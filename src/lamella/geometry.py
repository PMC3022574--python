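"""Edge state, filament length L(t_uc, tau_c) and its inversion.

A filament is described by the time it stayed uncapped, t_uc, and the time it
has been capped since, tau_c.  Its x-projected length is

    L = delta_p * ( r_plus * t_uc - S(t_uc + tau_c) ),   floored at 0,

where S is the cumulative minus-end shrinkage.  For physiological rates
r_plus exceeds every minus-end rate, so L is strictly monotone in t_uc and
the minimal uncapped time needed to reach a probe length theta is obtained by
inverting the tabulated length row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import SubunitStateTrajectory
from .parameters import ModelParameters, filament_force, nucleation_rate

__all__ = ["EdgeState", "make_edge_state", "plus_end_rate", "filament_length",
           "min_uncapped_time"]


@dataclass(frozen=True)
class EdgeState:
    """Coupled leading-edge variables of one solver iterate."""

    c0: float       # uM, G-actin at the leading edge
    f: float        # pN, load per filament
    r_plus: float   # s^-1, net plus-end subunit addition
    V: float        # um s^-1, network growth / transport rate
    N0: float       # uM s^-1, nucleation rate
    B_eff: float    # uM, effective plus-end density N0 / r_cap


def plus_end_rate(c0: float, f: float, p: ModelParameters) -> float:
    """Net plus-end rate r+ = k_on c(0) exp(-f delta_p / kBT) - k_off (s^-1).

    The Boltzmann factor is the thermal-ratchet load penalty on the on-rate.
    May be negative; callers decide how to treat shrinking iterates.
    """
    if c0 < 0 or f < 0:
        raise ValueError("c0 and f must be nonnegative")
    return p.k_on_plus * c0 * np.exp(-f * p.delta_p / p.kBT) - p.k_off_plus


def make_edge_state(
    c0: float, p: ModelParameters, nucleation: str = "fixed_N0"
) -> EdgeState:
    """Build the edge state for a given leading-edge monomer concentration.

    ``nucleation`` selects how the plus-end density responds to the capping
    rate: ``"fixed_N0"`` (default) holds the nucleation rate at its baseline
    value so B_eff = N0 / r_cap and the per-filament load vary with r_cap;
    ``"fixed_B"`` holds B at its tabulated value instead.
    """
    if nucleation == "fixed_N0":
        N0 = nucleation_rate(p)
        B_eff = N0 / p.r_cap
    elif nucleation == "fixed_B":
        B_eff = p.B
        N0 = p.B * p.r_cap
    else:
        raise ValueError(f"unknown nucleation mode {nucleation!r}")
    f = filament_force(B_eff, p)
    r_plus = plus_end_rate(c0, f, p)
    return EdgeState(c0=c0, f=f, r_plus=r_plus, V=p.delta_p * r_plus, N0=N0,
                     B_eff=B_eff)


def _require_S(traj: SubunitStateTrajectory) -> np.ndarray:
    if traj.S is None:
        raise ValueError("trajectory lacks S; call minus_end_rate first")
    return traj.S


def _length_row(
    t_uc: np.ndarray, tau_c: float, edge: EdgeState, traj: SubunitStateTrajectory
) -> np.ndarray:
    """Unclipped length delta_p*(r+ t_uc - S(t_uc + tau_c)); may be negative."""
    S = _require_S(traj)
    t_tot = t_uc + tau_c
    if np.any(t_tot > traj.t_grid[-1] + 1e-9):
        raise ValueError("t_uc + tau_c exceeds the trajectory grid (truncation)")
    S_tot = np.interp(t_tot, traj.t_grid, S)
    return (edge.r_plus * t_uc - S_tot) * _dp(edge)


def _dp(edge: EdgeState) -> float:
    # delta_p recovered from V = delta_p * r_plus (exact by construction)
    return edge.V / edge.r_plus


def filament_length(
    t_uc, tau_c: float, edge: EdgeState, traj: SubunitStateTrajectory
):
    """x-projected filament length L(t_uc, tau_c) in um, floored at 0."""
    t_uc = np.asarray(t_uc, dtype=float)
    if np.any(t_uc < 0) or tau_c < 0:
        raise ValueError("t_uc and tau_c must be nonnegative")
    L = _length_row(t_uc, tau_c, edge, traj)
    out = np.maximum(L, 0.0)
    return float(out) if out.ndim == 0 else out


def min_uncapped_time(
    theta, tau_c: float, edge: EdgeState, traj: SubunitStateTrajectory,
    t_uc_max: float | None = None,
):
    """Smallest t_uc with L(t_uc, tau_c) >= theta; +inf if unreachable.

    The (unclipped) length row is strictly increasing in t_uc whenever
    r_plus exceeds the largest minus-end rate, so the inverse is a linear
    interpolation on the tabulated row.  ``theta`` may be an array.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("theta must be nonnegative")
    if t_uc_max is None:
        t_uc_max = traj.t_grid[-1] - tau_c
    n = int(np.floor((t_uc_max + 1e-12) / traj.dt))
    t_uc = traj.t_grid[: n + 1]
    L = _length_row(t_uc, tau_c, edge, traj)
    if L[-1] < L[0]:
        raise ValueError("length row not increasing: r_plus below minus-end rate")
    out = np.interp(theta, L, t_uc)
    out = np.where(theta > L[-1], np.inf, out)
    # theta=0 means "exists", i.e. any nonnegative length qualifies
    out = np.where(theta <= np.maximum(L[0], 0.0), np.maximum(out, 0.0), out)
    return float(out) if out.ndim == 0 else out
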