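"""Parameter sweeps: capping x cofilin grids, diffusion power laws,
regulator-effect characterization.

Scans follow the constant-nucleation convention: N0 is held at its baseline
value, so raising the capping rate lowers the plus-end density B_eff = N0 /
r_cap and raises the load per filament.  Unconfined sweeps disable
tropomyosin (r_tm = 0) to probe the lower bound of attainable network
lengths.  Scan grids default to a coarser spatial step (0.1 um) than the
baseline solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .parameters import ModelParameters, NumericalControls
from .solver import ConvergenceError, solve_steady_state

__all__ = [
    "ScanResult",
    "PowerLawFit",
    "fit_power_law",
    "capping_cofilin_scan",
    "diffusion_scan",
    "diffusion_for_length",
    "regulator_effect_report",
]


def _scan_controls(controls: NumericalControls | None) -> NumericalControls:
    if controls is None:
        return NumericalControls(dx=0.1, dtau_c=0.1)
    return controls


@dataclass
class ScanResult:
    axis1_name: str
    axis1_values: np.ndarray
    L_net: np.ndarray            # um; +inf where the box was filled
    V: np.ndarray                # um/min
    converged: np.ndarray        # bool mask
    axis2_name: str | None = None
    axis2_values: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        if self.axis2_name is None:
            return pd.DataFrame({
                self.axis1_name: self.axis1_values,
                "L_net": self.L_net, "V": self.V, "converged": self.converged,
            })
        a1, a2 = np.meshgrid(self.axis1_values, self.axis2_values, indexing="ij")
        return pd.DataFrame({
            self.axis1_name: a1.ravel(), self.axis2_name: a2.ravel(),
            "L_net": self.L_net.ravel(), "V": self.V.ravel(),
            "converged": self.converged.ravel(),
        })


@dataclass
class PowerLawFit:
    exponent: float
    prefactor: float
    r_squared: float
    fit_range: tuple[float, float]
    n_points: int

    def to_dict(self) -> dict:
        return {
            "exponent": self.exponent, "prefactor": self.prefactor,
            "r_squared": self.r_squared, "fit_range": list(self.fit_range),
            "n_points": self.n_points,
        }


def fit_power_law(x: np.ndarray, y: np.ndarray) -> PowerLawFit:
    """Least-squares fit of y = prefactor * x**exponent in log-log space."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    good = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    if good.sum() < 4:
        raise ValueError("power-law fit refused: fewer than 4 usable points")
    lx, ly = np.log(x[good]), np.log(y[good])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        exponent=float(slope), prefactor=float(np.exp(intercept)),
        r_squared=r2, fit_range=(float(x[good].min()), float(x[good].max())),
        n_points=int(good.sum()),
    )


def _solve_unconfined_cell(p, controls, c0_start):
    try:
        sol = solve_steady_state(
            p, controls, mode="unconfined", nucleation="fixed_N0",
            c0_start=c0_start,
        )
        return sol.network_length(), sol.V_um_per_min, sol.c0, True
    except ConvergenceError:
        return np.nan, np.nan, c0_start, False


def capping_cofilin_scan(
    p: ModelParameters,
    controls: NumericalControls | None = None,
    r_cap_values: Sequence[float] = tuple(np.geomspace(0.1, 5.0, 15)),
    r_ac_values: Sequence[float] = tuple(np.geomspace(0.03, 3.0, 13)),
    deactivation: str = "on",
) -> ScanResult:
    """Unconfined network length and growth rate over (r_cap, r_ac).

    Tropomyosin is disabled; ``deactivation="off"`` additionally sets the
    ADF/cofilin unbinding rate to zero.  Non-converged cells carry NaN and a
    False flag, never an interpolated value.
    """
    if deactivation not in ("on", "off"):
        raise ValueError("deactivation must be 'on' or 'off'")
    controls = _scan_controls(controls)
    r_cap_values = np.asarray(list(r_cap_values), float)
    r_ac_values = np.asarray(list(r_ac_values), float)
    if np.any(r_cap_values <= 0) or np.any(r_ac_values <= 0):
        raise ValueError("scan values must be positive")
    shape = (len(r_cap_values), len(r_ac_values))
    L_net = np.full(shape, np.nan)
    V = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)
    for i, rc in enumerate(r_cap_values):
        c0 = None
        for j, ra in enumerate(r_ac_values):
            pij = p.replace(
                r_cap=float(rc), r_ac=float(ra), r_tm=0.0,
                r_ac_minus=0.0 if deactivation == "off" else p.r_ac_minus,
            )
            L_net[i, j], V[i, j], c0, conv[i, j] = _solve_unconfined_cell(
                pij, controls, c0
            )
    return ScanResult(
        axis1_name="r_cap", axis1_values=r_cap_values, L_net=L_net, V=V,
        converged=conv, axis2_name="r_ac", axis2_values=r_ac_values,
        meta={"r_tm": 0.0, "deactivation": deactivation},
    )


def diffusion_scan(
    p: ModelParameters,
    controls: NumericalControls | None = None,
    D_values: Sequence[float] = (1.0, 2.0, 3.0, 5.0, 7.0, 10.0),
) -> tuple[ScanResult, PowerLawFit, PowerLawFit]:
    """Unconfined L_net and V versus the G-actin diffusion coefficient
    (tropomyosin disabled), with log-log power-law fits of both."""
    controls = _scan_controls(controls)
    D_values = np.asarray(list(D_values), float)
    if D_values.max() / D_values.min() < np.sqrt(10.0):
        raise ValueError("D_values must span at least half a decade")
    L_net = np.full(len(D_values), np.nan)
    V = np.full(len(D_values), np.nan)
    conv = np.zeros(len(D_values), dtype=bool)
    c0 = None
    for i, D in enumerate(np.sort(D_values)):
        idx = int(np.where(D_values == D)[0][0])
        pD = p.replace(D=float(D), r_tm=0.0)
        L_net[idx], V[idx], c0, conv[idx] = _solve_unconfined_cell(pD, controls, c0)
    result = ScanResult(
        axis1_name="D", axis1_values=D_values, L_net=L_net, V=V, converged=conv,
        meta={"r_tm": 0.0},
    )
    fit_L = fit_power_law(D_values[conv], L_net[conv])
    fit_V = fit_power_law(D_values[conv], V[conv])
    return result, fit_L, fit_V


def diffusion_for_length(
    p: ModelParameters,
    target_length: float = 10.0,
    controls: NumericalControls | None = None,
    bracket: tuple[float, float] = (0.3, 2.0),
    xtol_log10: float = 0.005,
) -> float:
    """Diffusion coefficient at which the unconfined network length
    (tropomyosin disabled) equals ``target_length`` um; bisection on log D."""
    controls = _scan_controls(controls)
    state = {"c0": None}

    def f(log10_D: float) -> float:
        pD = p.replace(D=float(10.0**log10_D), r_tm=0.0)
        L, _, c0, ok = _solve_unconfined_cell(pD, controls, state["c0"])
        if not ok:
            raise ConvergenceError(f"cell D={10.0**log10_D:.3g} did not converge")
        state["c0"] = c0
        return L - target_length

    lo, hi = np.log10(bracket[0]), np.log10(bracket[1])
    return float(10.0 ** brentq(f, lo, hi, xtol=xtol_log10))


def regulator_effect_report(
    p: ModelParameters,
    controls: NumericalControls | None = None,
    r_ac_values: Sequence[float] | None = None,
    r_tm_values: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Confined-mode response to filament stabilizer/destabilizer activity.

    For each scanned rate the table reports the position of the J_d maximum
    (a proxy for the lamellipodial-zone width), the growth rate V in um/min
    and the polymerized fraction int F / int (F + c).
    """
    if controls is None:
        controls = NumericalControls(dx=0.05, dtau_c=0.05)
    rows = []
    scan_axes = []
    if r_ac_values is not None:
        scan_axes.append(("r_ac", r_ac_values))
    if r_tm_values is not None:
        scan_axes.append(("r_tm", r_tm_values))
    if not scan_axes:
        scan_axes = [("r_ac", [0.25, 0.5, 1.0]), ("r_tm", [0.0, 0.2, 0.4])]
    for name, values in scan_axes:
        c0 = None
        for v in values:
            sol = solve_steady_state(
                p.replace(**{name: float(v)}), controls, mode="confined",
                c0_start=c0,
            )
            c0 = sol.c0
            prof = sol.profiles
            x, J = prof.x_grid, prof.J_d
            i_peak = int(np.argmax(J))
            intF = float(np.trapezoid(prof.F, x))
            intc = float(np.trapezoid(prof.c, x))
            rows.append({
                "parameter": name, "value": float(v),
                "J_d_peak_x": float(x[i_peak]),
                "V": sol.V_um_per_min,
                "F_fraction": intF / (intF + intc),
                "c0": sol.c0,
            })
    return pd.DataFrame(rows)
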