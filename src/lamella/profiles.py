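"""Spatial fields of the treadmilling network.

Filaments nucleate at x = 0 at rate N0 and are capped as a Poisson process
with rate r_cap, so the population is a continuum over (t_uc, tau_c) with
density N0 r_cap exp(-r_cap t_uc).  Groups sharing the capped time tau_c have
their plus ends at V tau_c; a group's contribution to the F-actin
concentration at x is the surviving fraction long enough to span the distance
theta = x - V tau_c,

    f(x, tau_c) = N0 exp(-r_cap * t_uc_min(theta, tau_c)) * H(theta),

and the capped F-actin profile is the trapezoidal integral of the group
contributions over tau_c, with the single uncapped group (plus ends at x = 0)
added separately.  Concentration bookkeeping: a filament crossing a
delta_p-thick slab contributes one subunit there, so crossing counts and
subunit concentrations coincide and F(0) = B_eff.

Minus-end concentrations are accumulated by binning each surviving filament's
minus end, at x = V tau_c + L(t_uc, tau_c), with the same population weights;
the depolymerization source density is J_d(x) = M(x) * r_minus(x / V), the
minus-end rate evaluated at the transport age x/V.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .geometry import EdgeState
from .kinetics import SubunitStateTrajectory
from .parameters import ModelParameters, NumericalControls

__all__ = [
    "SpatialProfiles",
    "LengthDistribution",
    "InfeasibleIterate",
    "compute_profiles",
    "group_density",
    "f_actin_profile",
    "minus_end_profile",
    "depolymerization_density",
    "regulator_profiles",
    "length_distribution",
    "tau_death",
]


class InfeasibleIterate(RuntimeError):
    """Edge state outside the physiological regime (e.g. r+ too small)."""


@dataclass
class SpatialProfiles:
    """x-gridded steady-state fields (concentrations in uM, lengths in um)."""

    x_grid: np.ndarray
    F: np.ndarray
    F_c: np.ndarray
    F_uc: np.ndarray
    M: np.ndarray
    J_d: np.ndarray          # uM s^-1
    L_mean: np.ndarray
    F_ac: np.ndarray
    F_tm: np.ndarray
    c: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def dx(self) -> float:
        return float(self.x_grid[1] - self.x_grid[0])

    def to_dataframe(self):
        import pandas as pd

        cols = {
            "x": self.x_grid, "F": self.F, "F_uc": self.F_uc, "F_c": self.F_c,
            "M": self.M, "J_d": self.J_d,
            "c": self.c if self.c is not None else np.full_like(self.F, np.nan),
            "L_mean": self.L_mean, "F_ac": self.F_ac, "F_tm": self.F_tm,
        }
        return pd.DataFrame(cols)


@dataclass
class LengthDistribution:
    """Normalized filament length densities P(L, x) at selected positions."""

    x_values: np.ndarray     # um
    L_grid: np.ndarray       # um, bin centers
    P: np.ndarray            # um^-1, shape (n_x, n_L)
    L_mean: np.ndarray       # um, per x (first moment of P)

    @property
    def dL(self) -> float:
        return float(self.L_grid[1] - self.L_grid[0])


def tau_death(edge: EdgeState, traj: SubunitStateTrajectory, t_uc_max: float) -> float | None:
    """Capped time at which even the longest (t_uc_max) filament has fully
    depolymerized: smallest tau with S(t_uc_max + tau) >= r_plus * t_uc_max.
    None if the trajectory grid is too short to contain it."""
    target = edge.r_plus * t_uc_max
    if traj.S[-1] < target:
        return None
    t_star = float(np.interp(target, traj.S, traj.t_grid))
    return max(t_star - t_uc_max, 0.0)


def _resolve_grids(edge, traj, p, controls, x_max):
    dt = traj.dt
    t_uc_max = controls.resolved_t_uc_max(p)
    J = int(round(t_uc_max / dt))
    dtau_c = controls.dtau_c if controls.dtau_c is not None else dt
    m = max(1, int(round(dtau_c / dt)))
    dtau = m * dt
    if edge.V <= 0:
        raise InfeasibleIterate("non-positive growth rate V")
    tau_cap = x_max / edge.V
    td = tau_death(edge, traj, t_uc_max)
    tau_c_max = tau_cap if td is None else min(td, tau_cap)
    if controls.tau_c_max is not None:
        tau_c_max = min(tau_c_max, controls.tau_c_max)
    K = int(np.floor(tau_c_max / dtau + 1e-9))
    # the trajectory must cover t_uc_max + K*dtau
    K = min(K, (len(traj.t_grid) - 1 - J) // m)
    if K < 1:
        raise InfeasibleIterate("trajectory grid too short for any capped group")
    return dt, t_uc_max, J, m, dtau, K, tau_c_max


def compute_profiles(
    edge: EdgeState,
    traj: SubunitStateTrajectory,
    p: ModelParameters,
    controls: NumericalControls,
    x_max: float | None = None,
) -> SpatialProfiles:
    """Build all spatial fields (except c) on [0, x_max] with step dx."""
    if traj.S is None:
        raise ValueError("trajectory lacks r_minus/S; call minus_end_rate first")
    if x_max is None:
        x_max = p.L_sys
    r_max = float(np.max(traj.r_minus))
    if edge.r_plus <= r_max:
        raise InfeasibleIterate(
            f"r_plus={edge.r_plus:.3g} does not exceed the largest minus-end "
            f"rate {r_max:.3g}; filament length not monotone in t_uc"
        )
    dt, t_uc_max, J, m, dtau, K, tau_c_max = _resolve_grids(
        edge, traj, p, controls, x_max
    )
    dx = controls.dx
    Nx = int(round(x_max / dx)) + 1
    x = np.arange(Nx) * dx
    V, r_plus, N0, B_eff = edge.V, edge.r_plus, edge.N0, edge.B_eff
    dp = p.delta_p
    t_uc = traj.t_grid[: J + 1]
    S = traj.S
    pop = N0 * p.r_cap * np.exp(-p.r_cap * t_uc)       # capped-population density
    w_t = np.full(J + 1, dt)
    w_t[0] = w_t[-1] = 0.5 * dt                         # trapezoid in t_uc
    q = x / V                                           # transport age of position x

    # exact minimum-alive age: group tau_c = q(x) first survives at
    # t_uc = a(x) - q(x), where a(x) inverts the minus-end locus
    # x_m(t) = V t - delta_p S(t) (strictly increasing for r_plus > r_minus).
    x_m_curve = V * traj.t_grid - dp * S
    a_of_x = np.interp(x, x_m_curve, traj.t_grid)
    in_support = x <= x_m_curve[-1]
    # beyond the support a_of_x clamps and the exponent loses meaning; mask first
    expo = np.where(in_support, -p.r_cap * (a_of_x - q), -np.inf)
    g_cut = N0 * np.exp(expo)

    F_c = np.zeros(Nx)
    f_last = np.zeros(Nx)      # integrand value at the last full tau_c node
    w_last = np.full(Nx, 0.5 * dtau)  # weight applied at that node
    tau_last = np.zeros(Nx)
    F_uc = np.zeros(Nx)
    Nc = Nx - 1                # deposition bins [x_j, x_{j+1}) -> centers
    diff_F = np.zeros(Nc + 1)
    diff_num = np.zeros(Nc + 1)
    # minus-end mass CDF sampled at node-cell edges (smooth deposition)
    y_edges = np.concatenate([[0.0], (np.arange(Nc) + 0.5) * dx, [x_max]])
    cell_w = np.diff(y_edges)
    M_cdf = np.zeros(Nx + 1)
    trunc_density = 0.0

    for k in range(K + 1):
        k_idx = k * m
        tau_k = k_idx * dt
        S_row = S[k_idx : k_idx + J + 1]
        L_row = dp * (r_plus * t_uc - S_row)            # unclipped, increasing
        j0 = int(np.ceil(tau_k * V / dx - 1e-9))        # first node with x >= V tau_k
        if j0 < Nx:
            theta = x[j0:] - V * tau_k
            t_min = np.interp(theta, L_row, t_uc)
            fk = N0 * np.exp(-p.r_cap * t_min)
            fk[theta > L_row[-1]] = 0.0                 # unreachable within t_uc_max
            w_tau = 0.5 * dtau if k in (0, K) else dtau
            F_c[j0:] += w_tau * fk
            # remember per-x integrand at the last tau_c node below q(x)
            nk = int(np.ceil((tau_k + dtau) * V / dx - 1e-9))
            sel = slice(j0, min(nk, Nx))
            f_last[sel] = fk[: max(0, sel.stop - j0)]
            w_last[sel] = w_tau
            tau_last[sel] = tau_k
            if k == K:
                f_last[nk:] = fk[max(0, nk - j0):]
                w_last[nk:] = w_tau
                tau_last[nk:] = tau_k
                trunc_density = float(fk.max(initial=0.0))
        # population deposition (alive filaments only)
        L_clip = np.maximum(L_row, 0.0)
        alive = L_row > 0.0
        if not np.any(alive):
            continue
        w_tau_dep = 0.5 * dtau if k in (0, K) else dtau
        w = pop[alive] * w_t[alive] * w_tau_dep
        start = V * tau_k
        end = start + L_clip[alive]
        i_first = int(np.ceil(start / dx - 0.5))
        i_last = np.minimum(np.floor(end / dx - 0.5).astype(int), Nc - 1)
        cover = i_last >= i_first
        if i_first < Nc and np.any(cover):
            diff_F[i_first] += w[cover].sum()
            np.subtract.at(diff_F, i_last[cover] + 1, w[cover])
            wl = w * L_clip[alive]
            diff_num[i_first] += wl[cover].sum()
            np.subtract.at(diff_num, i_last[cover] + 1, wl[cover])
        x_minus = start + L_clip[alive]     # increasing in t_uc
        cw = np.cumsum(w)
        M_cdf += np.interp(y_edges, x_minus, cw, left=0.0, right=cw[-1])

    # composite-trapezoid endpoint correction + partial cell [tau_last, q]:
    # the accumulated weight at the last node is reduced to the trapezoid
    # half-weight, then the final sliver up to the Heaviside cut is added
    # with the endpoint integrand g_cut.
    with np.errstate(invalid="ignore"):
        has_groups = q > 0
        width = np.minimum(q, tau_c_max) - tau_last
        partial = width < dtau + 1e-12                  # Heaviside cut inside grid
        corr = np.where(
            has_groups & partial,
            (0.5 * dtau - w_last) * f_last
            + 0.5 * (f_last + g_cut) * np.maximum(width, 0.0),
            0.0,
        )
    F_c = np.maximum(F_c + corr, 0.0)
    F_c[0] = 0.0

    # uncapped group: plus ends at x = 0, survival exp(-r_cap t_uc)
    L0 = dp * (r_plus * t_uc - S[: J + 1])
    t_min0 = np.interp(x, L0, t_uc)
    F_uc = B_eff * np.exp(-p.r_cap * t_min0)
    F_uc[x > L0[-1]] = 0.0
    w_uc = N0 * np.exp(-p.r_cap * t_uc) * w_t
    alive0 = L0 > 0
    if np.any(alive0):
        end0 = L0[alive0]
        i_last0 = np.minimum(np.floor(end0 / dx - 0.5).astype(int), Nc - 1)
        cover0 = i_last0 >= 0
        diff_F[0] += w_uc[alive0][cover0].sum()
        np.subtract.at(diff_F, i_last0[cover0] + 1, w_uc[alive0][cover0])
        wl0 = w_uc[alive0] * end0
        diff_num[0] += wl0[cover0].sum()
        np.subtract.at(diff_num, i_last0[cover0] + 1, wl0[cover0])
        cw0 = np.cumsum(w_uc[alive0])
        M_cdf += np.interp(y_edges, end0, cw0, left=0.0, right=cw0[-1])

    F = F_c + F_uc

    # deposited fields at bin centers -> nodes
    centers = x[:-1] + 0.5 * dx
    F_dep = np.cumsum(diff_F[:-1])
    num_dep = np.cumsum(diff_num[:-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        L_mean_c = np.where(F_dep > 0, num_dep / np.maximum(F_dep, 1e-300), 0.0)
    L_mean = np.interp(x, centers, L_mean_c)
    # exact x=0 value from the uncapped group
    wsum = w_uc.sum()
    L_mean[0] = float((w_uc * np.maximum(L0, 0.0)).sum() / wsum) if wsum > 0 else 0.0

    M = np.diff(M_cdf) / cell_w * dp
    r_at_q = np.interp(q, traj.t_grid, traj.r_minus)
    J_d = M * r_at_q
    J_d[0] = 0.0

    p_ac_x = np.interp(q, traj.t_grid, traj.p_ac)
    p_tm_x = np.interp(q, traj.t_grid, traj.p_tm)
    F_ac = F * p_ac_x
    F_tm = F * p_tm_x

    return SpatialProfiles(
        x_grid=x, F=F, F_c=F_c, F_uc=F_uc, M=M, J_d=J_d, L_mean=L_mean,
        F_ac=F_ac, F_tm=F_tm,
        meta={
            "tau_c_max": tau_c_max, "t_uc_max": t_uc_max, "dtau_c": dtau,
            "n_groups": K + 1, "x_max": x_max,
            "truncated_group_density": trunc_density,
            # the tau_c horizon only truncates anything when it ends before
            # the Heaviside cut of the rearmost position
            "truncation_ok": bool(
                tau_c_max >= x_max / V - dtau or trunc_density <= 1e-6 * N0
            ),
            "F_dep_centers": F_dep, "centers": centers,
        },
    )


def group_density(
    x, tau_c: float, edge: EdgeState, traj: SubunitStateTrajectory,
    p: ModelParameters, t_uc_max: float | None = None,
):
    """Poisson-closed group contribution f(x, tau_c) in uM s^-1 (per unit
    tau_c): N0 exp(-r_cap t_uc_min(x - V tau_c, tau_c)), zero ahead of the
    group's plus ends (x < V tau_c) and beyond the t_uc truncation."""
    from .geometry import min_uncapped_time

    x = np.asarray(x, dtype=float)
    theta = x - edge.V * tau_c
    out = np.zeros_like(theta)
    inside = theta >= 0
    if np.any(inside):
        tmin = min_uncapped_time(theta[inside], tau_c, edge, traj, t_uc_max)
        out[inside] = edge.N0 * np.where(
            np.isfinite(tmin), np.exp(-p.r_cap * tmin), 0.0
        )
    return float(out) if out.ndim == 0 else out


def f_actin_profile(edge, traj, p, controls, x_max=None) -> SpatialProfiles:
    """F-actin fields (total, capped, uncapped); see :func:`compute_profiles`."""
    return compute_profiles(edge, traj, p, controls, x_max)


def minus_end_profile(edge, traj, p, controls, x_max=None) -> np.ndarray:
    """Minus-end concentration M(x) in uM."""
    return compute_profiles(edge, traj, p, controls, x_max).M


def depolymerization_density(
    M: np.ndarray, x_grid: np.ndarray, traj: SubunitStateTrajectory, edge: EdgeState
) -> np.ndarray:
    """J_d(x) = M(x) * r_minus(x/V) in uM s^-1 (zero at the edge)."""
    out = M * np.interp(x_grid / edge.V, traj.t_grid, traj.r_minus)
    if x_grid[0] == 0.0:
        out[0] = 0.0
    return out


def regulator_profiles(
    F: np.ndarray, x_grid: np.ndarray, traj: SubunitStateTrajectory, edge: EdgeState
) -> tuple[np.ndarray, np.ndarray]:
    """Cofilin- and tropomyosin-bound F-actin, F * p_ac(x/V) and F * p_tm(x/V)."""
    q = x_grid / edge.V
    return (
        F * np.interp(q, traj.t_grid, traj.p_ac),
        F * np.interp(q, traj.t_grid, traj.p_tm),
    )


def length_distribution(
    x_values,
    edge: EdgeState,
    traj: SubunitStateTrajectory,
    p: ModelParameters,
    controls: NumericalControls,
    x_max: float | None = None,
    L_grid: np.ndarray | None = None,
) -> LengthDistribution:
    """Normalized filament length densities at the requested positions.

    Each group's crossing filaments (length >= x - V tau_c) are histogrammed
    over L with the population weights; densities are normalized to unit
    integral per position.  Raises if no filament crosses a requested x.
    """
    if x_max is None:
        x_max = p.L_sys
    x_values = np.atleast_1d(np.asarray(x_values, dtype=float))
    dt, t_uc_max, J, m, dtau, K, tau_c_max = _resolve_grids(
        edge, traj, p, controls, x_max
    )
    dp, V, r_plus = p.delta_p, edge.V, edge.r_plus
    t_uc = traj.t_grid[: J + 1]
    S = traj.S
    pop = edge.N0 * p.r_cap * np.exp(-p.r_cap * t_uc)
    if L_grid is None:
        dL = 10.0 * dp
        L_top = dp * r_plus * t_uc_max
        nL = int(np.ceil(L_top / dL)) + 1
        edges = np.arange(nL + 1) * dL
    else:
        dL = float(L_grid[1] - L_grid[0])
        edges = np.concatenate([L_grid - 0.5 * dL, [L_grid[-1] + 0.5 * dL]])
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.zeros((len(x_values), len(centers)))

    def _accumulate(ix: int, theta: float, L_row: np.ndarray,
                    dens: np.ndarray, w_tau: float) -> None:
        """Bin the crossing subpopulation (length >= theta) by building its
        piecewise-linear mass CDF over L and differencing it at bin edges.
        ``dens`` is the population density over t_uc."""
        if theta > L_row[-1]:
            return
        t_min = float(np.interp(max(theta, 1e-300), L_row, t_uc))
        j_min = int(np.searchsorted(t_uc, t_min - 1e-12))
        if j_min > J:
            return
        w = np.full(J + 1 - j_min, dt)
        w[0] = min(t_uc[j_min] + 0.5 * dt - max(t_min, 0.0),
                   t_uc_max - max(t_min, 0.0))
        if len(w) > 1:
            w[-1] = 0.5 * dt
        tb = np.concatenate([[max(t_min, 0.0)], t_uc[j_min:] + 0.5 * dt])
        tb[-1] = t_uc_max
        Lb = np.interp(tb, t_uc, L_row)
        C = np.concatenate([[0.0], np.cumsum(dens[j_min:] * w)])
        hist[ix] += w_tau * np.diff(
            np.interp(edges, Lb, C, left=0.0, right=C[-1])
        )

    for k in range(K + 1):
        k_idx = k * m
        tau_k = k_idx * dt
        L_row = dp * (r_plus * t_uc - S[k_idx : k_idx + J + 1])
        w_tau = (0.5 * dtau if k in (0, K) else dtau)
        for ix, xv in enumerate(x_values):
            theta = xv - V * tau_k
            if theta >= 0:
                _accumulate(ix, theta, L_row, pop, w_tau)
    # partial capping-time cell between the last full group and the Heaviside
    # cut at tau_c = x/V (short filaments; dominates the head of the density)
    for ix, xv in enumerate(x_values):
        q = xv / V
        if q > tau_c_max:
            continue
        k_last = min(int(np.floor(q / dtau + 1e-12)), K)
        tau_l = k_last * dtau
        width = q - tau_l
        applied = 0.5 * dtau if k_last in (0, K) else dtau
        L_row = dp * (r_plus * t_uc - S[k_last * m : k_last * m + J + 1])
        _accumulate(ix, xv - V * tau_l, L_row, pop,
                    (0.5 * dtau + 0.5 * width) - applied)
        S_cut = np.interp(t_uc + q, traj.t_grid, S)
        _accumulate(ix, 0.0, dp * (r_plus * t_uc - S_cut), pop, 0.5 * width)
    # uncapped group
    L0 = dp * (r_plus * t_uc - S[: J + 1])
    dens_uc = edge.N0 * np.exp(-p.r_cap * t_uc)
    for ix, xv in enumerate(x_values):
        _accumulate(ix, xv, L0, dens_uc, 1.0)

    totals = hist.sum(axis=1)
    if np.any(totals <= 0):
        bad = x_values[totals <= 0]
        raise ValueError(f"no filamentous actin at x = {bad}; distribution undefined")
    P = hist / (totals[:, None] * dL)
    L_mean = (P * centers[None, :]).sum(axis=1) * dL
    return LengthDistribution(x_values=x_values, L_grid=centers, P=P, L_mean=L_mean)
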