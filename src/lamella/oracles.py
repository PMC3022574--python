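"""Independent verification paths for the group-integral pipeline.

Three routes that never touch the pipeline's t_uc_min inversion or its
trapezoidal group integral:

* :func:`constant_rate_solution` — closed forms for the special case of a
  constant minus-end rate r (no debranching delay, no aging), where
  t_uc_min, the group density, F(x), the length density and the mean length
  are elementary.
* :func:`ensemble_brute_force` — deterministic quadrature over the
  (t_uc, tau_c) filament population on an independent (coarser, midpoint)
  grid, depositing each filament's subunit span and minus end onto x bins.
* :func:`exact_age_map_solution` — the observation that a filament's minus
  end sits at x_m(t) = V t - delta_p S(t) regardless of when it was capped,
  which yields exact expressions F(x) = B exp(-(r_cap/r+) S(a(x))) and
  M(x) = r_cap F(x) / (r+ - r_minus(a(x))) with a(x) the inverse of x_m.
"""

from __future__ import annotations

import numpy as np

from .geometry import EdgeState
from .kinetics import SubunitStateTrajectory
from .parameters import ModelParameters

__all__ = [
    "constant_rate_trajectory",
    "constant_rate_t_uc_min",
    "constant_rate_solution",
    "ensemble_brute_force",
    "exact_age_map_solution",
    "deposit_spans",
]


def constant_rate_trajectory(
    p: ModelParameters, r_const: float, t_max: float, dt: float
) -> SubunitStateTrajectory:
    """A trajectory whose minus-end rate is forced to ``r_const`` at all ages
    (instantaneous debranching, no state aging); S(t) = r_const * t."""
    n = int(round(t_max / dt))
    t = np.arange(n + 1) * dt
    one = np.ones_like(t)
    return SubunitStateTrajectory(
        t_grid=t, p_atp=one.copy(), p_adp=0 * one, p_ac=0 * one, p_tm=0 * one,
        p_deb=one.copy(), p_uc=np.exp(-p.r_cap * t),
        r_minus_free=r_const * one, r_minus=r_const * one, S=r_const * t,
    )


def constant_rate_t_uc_min(theta, tau_c, edge: EdgeState, r_const: float,
                           p: ModelParameters):
    """Closed-form inversion of L = delta_p (r+ t_uc - r (t_uc + tau_c))."""
    return (np.asarray(theta) / p.delta_p + r_const * tau_c) / (edge.r_plus - r_const)


def constant_rate_solution(
    p: ModelParameters,
    edge: EdgeState,
    r_const: float,
    x_grid: np.ndarray,
    L_edges: np.ndarray | None = None,
    x_hist: np.ndarray | None = None,
    t_uc_max: float | None = None,
) -> dict:
    """Semi-analytical fields for a constant minus-end rate r in (0, r+).

    Returns F, F_uc, F_c, L_mean on ``x_grid`` and, when ``L_edges`` and
    ``x_hist`` are given, bin-averaged length densities P(L, x) at those
    positions.  F is in closed form; length statistics reduce to elementary
    per-group expressions integrated over the capping-time continuum by fine
    quadrature.  Nothing is shared with the numerical pipeline (no tabulated
    t_uc_min inversion, no deposition binning).

    ``t_uc_max`` applies the same uncapped-time truncation horizon as the
    population the pipeline deposits, so that comparisons measure
    discretization error rather than the (documented) truncation choice;
    ``None`` means the untruncated population.
    """
    if not (0.0 < r_const < edge.r_plus):
        raise ValueError("r_const must lie in (0, r_plus)")
    x = np.asarray(x_grid, dtype=float)
    rp, rc, dp, V = edge.r_plus, p.r_cap, p.delta_p, edge.V
    B, N0 = edge.B_eff, edge.N0
    drp = rp - r_const
    T = np.inf if t_uc_max is None else float(t_uc_max)
    A_x = x / (dp * drp)                        # t_uc needed to reach x at tau_c=0
    q = x / V
    F_uc = B * np.exp(-rc * A_x)
    F = B * np.exp(-rc * (A_x - q))             # note A_x - q = x r /(dp rp drp)
    F_c = F - F_uc

    eT = np.exp(-rc * T) if np.isfinite(T) else 0.0
    tail_T = ((T / rc + 1.0 / rc**2) * eT) if np.isfinite(T) else 0.0

    def _int_e(a):
        """int_a^T exp(-rc t) dt (0 where a >= T)."""
        a = np.minimum(a, T)
        return (np.exp(-rc * a) - eT) / rc

    def _int_te(a):
        """int_a^T t exp(-rc t) dt (0 where a >= T)."""
        a = np.minimum(a, T)
        return (a / rc + 1.0 / rc**2) * np.exp(-rc * a) - tail_T

    # length statistics: group tau_c contributes crossing lengths
    # L(t) = dp (drp t - r tau_c) for t in [A_x - tau_c, T]; fine quadrature
    # over tau_c in [0, q] of the elementary per-group mass and first moment.
    n_tau = 4096
    s = np.linspace(0.0, 1.0, n_tau + 1)
    tau = q[:, None] * s[None, :]               # (Nx, n_tau+1)
    a_grp = A_x[:, None] - tau
    mass = rc * _int_e(a_grp)
    mom = rc * (dp * drp * _int_te(a_grp) - dp * r_const * tau * _int_e(a_grp))
    F_T = N0 * np.trapezoid(mass, tau, axis=1) + N0 * _int_e(A_x)
    num = N0 * np.trapezoid(mom, tau, axis=1) + N0 * dp * drp * _int_te(A_x)
    with np.errstate(invalid="ignore", divide="ignore"):
        L_mean = np.where(F_T > 0, num / np.maximum(F_T, 1e-300), 0.0)

    out = {"x": x, "F": F, "F_uc": F_uc, "F_c": F_c, "L_mean": L_mean,
           "F_truncated": F_T}

    if L_edges is not None and x_hist is not None:
        b = rc * r_const / drp
        P = np.zeros((len(x_hist), len(L_edges) - 1))
        for ix, xv in enumerate(x_hist):
            qv = xv / V

            def density(L):
                L = np.asarray(L, dtype=float)
                t_uc_L = L / (dp * drp)
                pref = N0 * np.exp(-rc * t_uc_L) / (dp * drp)
                tau0 = np.maximum(0.0, (xv - L) / V)
                # truncation limits the group range: t_uc(L, tau) <= T
                tau_T = (T * drp - L / dp) / r_const if np.isfinite(T) else np.inf
                hi = np.minimum(qv, tau_T)
                capped = np.where(
                    hi > tau0,
                    pref * rc * (np.exp(-b * tau0) - np.exp(-b * np.minimum(hi, qv)))
                    / b,
                    0.0,
                )
                uncapped = np.where((L >= xv) & (t_uc_L <= T), pref, 0.0)
                return capped + uncapped

            # bin-average with a fine sub-grid (handles the jump at L = x)
            raw = np.zeros(len(L_edges) - 1)
            for iL in range(len(L_edges) - 1):
                sub = np.linspace(L_edges[iL], L_edges[iL + 1], 65)
                raw[iL] = np.trapezoid(density(sub), sub) / (sub[-1] - sub[0])
            total = raw.sum() * np.diff(L_edges)
            P[ix] = raw / (raw * np.diff(L_edges)).sum()
        out["P"] = P
        out["L_edges"] = np.asarray(L_edges)
        out["x_hist"] = np.asarray(x_hist)
    return out


def deposit_spans(
    starts: np.ndarray, ends: np.ndarray, weights: np.ndarray,
    x_max: float, dx: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Count weighted interval crossings at bin centers of [0, x_max).

    Each interval [start, end] adds its weight to every bin center it covers;
    returns (centers, counts).  This is the elementary deposition step of the
    ensemble quadrature."""
    n = int(round(x_max / dx))
    centers = (np.arange(n) + 0.5) * dx
    diff = np.zeros(n + 1)
    i_first = np.maximum(np.ceil(starts / dx - 0.5).astype(int), 0)
    i_last = np.minimum(np.floor(ends / dx - 0.5).astype(int), n - 1)
    cover = i_last >= i_first
    np.add.at(diff, i_first[cover], weights[cover])
    np.subtract.at(diff, i_last[cover] + 1, weights[cover])
    return centers, np.cumsum(diff[:-1])


def ensemble_brute_force(
    p: ModelParameters,
    edge: EdgeState,
    traj: SubunitStateTrajectory,
    x_max: float,
    dx: float,
    h_t_uc: float,
    h_tau_c: float,
    t_uc_max: float | None = None,
    tau_c_max: float | None = None,
) -> dict:
    """Deterministic midpoint quadrature over the filament population.

    Every (t_uc, tau_c) cell is treated as one filament bundle with weight
    N0 r_cap exp(-r_cap t_uc) h_t_uc h_tau_c; its subunit span
    [V tau_c, V tau_c + L] and its minus end are deposited onto x bins.
    Returns F, M, J_d, L_mean at bin centers.  Entirely independent of the
    group-integral pipeline (different grids, no t_uc_min inversion).
    """
    if t_uc_max is None:
        t_uc_max = 10.0 / p.r_cap
    V, rp, dp, N0 = edge.V, edge.r_plus, p.delta_p, edge.N0
    if tau_c_max is None:
        target = rp * t_uc_max
        tau_c_max = (
            float(np.interp(target, traj.S, traj.t_grid)) - t_uc_max
            if traj.S[-1] >= target
            else traj.t_grid[-1] - t_uc_max
        )
        tau_c_max = min(max(tau_c_max, h_tau_c), x_max / V)
    n_u = int(np.ceil(t_uc_max / h_t_uc))
    n_k = int(np.ceil(tau_c_max / h_tau_c))
    t_mid = (np.arange(n_u) + 0.5) * h_t_uc
    tau_mid = (np.arange(n_k) + 0.5) * h_tau_c

    Nx = int(round(x_max / dx)) + 1
    x = np.arange(Nx) * dx
    y_edges = np.concatenate([[0.0], (np.arange(Nx - 1) + 0.5) * dx, [x_max]])
    cell_w = np.diff(y_edges)
    F = np.zeros(Nx)
    num = np.zeros(Nx)
    M_cdf = np.zeros(Nx + 1)
    deposited = 0.0
    w_t = N0 * p.r_cap * np.exp(-p.r_cap * t_mid) * h_t_uc

    def _column(start: float, L_col: np.ndarray, w_col: np.ndarray) -> None:
        """Accumulate one capping-time column: spans [start, start + L],
        minus ends at the span ends (monotone in t_uc)."""
        nonlocal F, num, M_cdf, deposited
        alive = L_col > 0
        if not np.any(alive):
            return
        e = start + L_col[alive]
        cw = np.cumsum(w_col[alive])
        cwl = np.cumsum((w_col * L_col)[alive])
        # span length inside the box only (filaments may cross the rear edge)
        deposited += float(
            (w_col[alive] * np.clip(np.minimum(e, x_max) - start, 0.0, None)).sum()
        )
        covered = x >= start
        # crossing weight at x: total minus mass of spans ending before x
        F[covered] += cw[-1] - np.interp(x[covered], e, cw, left=0.0,
                                         right=cw[-1])
        num[covered] += cwl[-1] - np.interp(x[covered], e, cwl, left=0.0,
                                            right=cwl[-1])
        M_cdf += np.interp(y_edges, e, cw, left=0.0, right=cw[-1])

    for k in range(n_k):
        tau = tau_mid[k]
        S_col = np.interp(t_mid + tau, traj.t_grid, traj.S)
        _column(V * tau, dp * (rp * t_mid - S_col), w_t * h_tau_c)

    S_u = np.interp(t_mid, traj.t_grid, traj.S)
    _column(0.0, dp * (rp * t_mid - S_u), N0 * np.exp(-p.r_cap * t_mid) * h_t_uc)

    with np.errstate(invalid="ignore"):
        L_mean = np.where(F > 0, num / np.maximum(F, 1e-300), 0.0)
    M = np.diff(M_cdf) / cell_w * dp
    J_d = M * np.interp(x / V, traj.t_grid, traj.r_minus)
    return {
        "x": x, "F": F, "M": M, "J_d": J_d, "L_mean": L_mean,
        # integral of the crossing concentration vs exact deposited span
        # length (both uM um): equal up to quadrature error in x
        "total_subunits": float(np.trapezoid(F, x)),
        "deposited_subunits": deposited,
    }


def exact_age_map_solution(
    edge: EdgeState,
    traj: SubunitStateTrajectory,
    p: ModelParameters,
    x_grid: np.ndarray,
) -> dict:
    """Exact F, M and J_d via the age map x_m(t) = V t - delta_p S(t).

    Because every plus end starts at x = 0 and minus-end recession depends
    only on filament age, all minus ends at position x share the age a(x)
    solving x_m(a) = x; the surviving fraction there is exp(-(r_cap/r+) S(a)),
    giving closed forms with no group integral and no t_uc truncation.
    """
    x = np.asarray(x_grid, dtype=float)
    V, rp = edge.V, edge.r_plus
    x_m = V * traj.t_grid - p.delta_p * traj.S
    a = np.interp(x, x_m, traj.t_grid)
    S_a = np.interp(a, traj.t_grid, traj.S)
    r_a = np.interp(a, traj.t_grid, traj.r_minus)
    F = edge.B_eff * np.exp(-(p.r_cap / rp) * S_a)
    F = np.where(x <= x_m[-1], F, 0.0)
    M = p.r_cap * F / (rp - r_a)
    return {"x": x, "F": F, "M": M, "J_d": M * r_a, "age": a}
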