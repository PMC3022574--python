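"""Subunit state kinetics and the time-dependent minus-end rate.

An F-actin subunit added at the plus end starts ATP-bound and relaxes through
the linear state graph

    ATP --r_hyd--> ADP --r_ac/r_ac_minus--> ADF/cofilin-bound
                    ADP --r_tm-->            tropomyosin-bound (absorbing)

The minus-end dissociation rate of a filament of age t is the state-weighted
free rate gated by the debranching probability 1 - exp(-r_deb t); its running
integral S(t) is the cumulative minus-end shrinkage in subunits.  The dwell
time of the minus-end subunit is identified with the filament age t (the
minus-end subunit is the oldest in the filament).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp

from .parameters import ModelParameters

__all__ = ["SubunitStateTrajectory", "solve_state_probabilities", "minus_end_rate"]


@dataclass
class SubunitStateTrajectory:
    """State probabilities and minus-end rate on a uniform age grid."""

    t_grid: np.ndarray       # s, uniform step dt, starts at 0
    p_atp: np.ndarray
    p_adp: np.ndarray
    p_ac: np.ndarray
    p_tm: np.ndarray
    p_deb: np.ndarray        # debranching probability 1 - exp(-r_deb t)
    p_uc: np.ndarray         # plus-end survival exp(-r_cap t)
    r_minus_free: np.ndarray | None = None  # s^-1
    r_minus: np.ndarray | None = None       # s^-1, debranch-gated
    S: np.ndarray | None = None             # subunits, cumulative shrinkage

    @property
    def dt(self) -> float:
        return float(self.t_grid[1] - self.t_grid[0])

    def to_dataframe(self):
        import pandas as pd

        cols = {
            "t": self.t_grid,
            "p_atp": self.p_atp,
            "p_adp": self.p_adp,
            "p_ac": self.p_ac,
            "p_tm": self.p_tm,
        }
        if self.r_minus is not None:
            cols["r_minus"] = self.r_minus
        return pd.DataFrame(cols)


def _rate_matrix(p: ModelParameters) -> np.ndarray:
    """Generator Q of the 4-state system, d/dt (atp, adp, ac, tm) = Q @ probs."""
    return np.array(
        [
            [-p.r_hyd, 0.0, 0.0, 0.0],
            [p.r_hyd, -(p.r_ac + p.r_tm), p.r_ac_minus, 0.0],
            [0.0, p.r_ac, -p.r_ac_minus, 0.0],
            [0.0, p.r_tm, 0.0, 0.0],
        ]
    )


def _propagate_eig(Q: np.ndarray, t: np.ndarray) -> np.ndarray | None:
    """Evaluate exp(Q t) @ e_atp on all t at once via eigendecomposition.

    Returns None when Q is too close to defective for a trustworthy
    eigenbasis (degenerate rate coincidences); caller falls back to an ODE
    integration.
    """
    lam, U = np.linalg.eig(Q)
    if np.linalg.cond(U) > 1e8:
        return None
    coef = np.linalg.solve(U, np.array([1.0, 0.0, 0.0, 0.0]))
    # probs[i, j] = sum_m U[i, m] coef[m] exp(lam_m t_j); rates are real
    out = np.real(U @ (coef[:, None] * np.exp(np.outer(lam, t))))
    return out


def solve_state_probabilities(
    p: ModelParameters, t_max: float, dt: float
) -> SubunitStateTrajectory:
    """Solve the subunit state system on [0, t_max] with step dt.

    The system is linear; it is solved exactly by matrix exponential
    (eigendecomposition of the 4x4 generator), with an RK-based fallback for
    (near-)defective generators.  Initial state: pure ATP.
    """
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    n = int(round(t_max / dt))
    t = np.arange(n + 1) * dt
    Q = _rate_matrix(p)
    probs = _propagate_eig(Q, t)
    if probs is None:
        sol = solve_ivp(
            lambda _t, y: Q @ y,
            (0.0, float(t[-1])),
            np.array([1.0, 0.0, 0.0, 0.0]),
            t_eval=t,
            method="RK45",
            rtol=1e-10,
            atol=1e-12,
        )
        probs = sol.y
    probs = np.clip(probs, 0.0, 1.0)
    probs[:, 0] = [1.0, 0.0, 0.0, 0.0]   # exact initial condition

    return SubunitStateTrajectory(
        t_grid=t,
        p_atp=probs[0],
        p_adp=probs[1],
        p_ac=probs[2],
        p_tm=probs[3],
        p_deb=1.0 - np.exp(-p.r_deb * t),
        p_uc=np.exp(-p.r_cap * t),
    )


def minus_end_rate(
    traj: SubunitStateTrajectory, p: ModelParameters
) -> SubunitStateTrajectory:
    """Fill r_minus_free, r_minus and the cumulative shrinkage S in-place.

    r_free(t) weighs the in vitro minus-end off-rate by the subunit state:
    ADF/cofilin-bound subunits dissociate s_ac-fold faster, tropomyosin brings
    the rate back to its in vitro value, and ATP-bound subunits are assigned
    the same off-rate as ADP (no separate literature value; minus ends are
    almost surely ADP by debranching time).  The effective rate is gated by
    the debranching probability, and S is its trapezoidal integral.
    """
    r_free = p.k_off_minus * (traj.p_atp + traj.p_adp + traj.p_tm) + (
        p.s_ac * p.k_off_minus
    ) * traj.p_ac
    r_eff = traj.p_deb * r_free
    traj.r_minus_free = r_free
    traj.r_minus = r_eff
    traj.S = cumulative_trapezoid(r_eff, traj.t_grid, initial=0.0)
    return traj


def subunit_trajectory(
    p: ModelParameters, t_max: float, dt: float
) -> SubunitStateTrajectory:
    """Convenience: state probabilities with minus-end rate and S filled."""
    return minus_end_rate(solve_state_probabilities(p, t_max, dt), p)
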