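"""Steady-state G-actin profile with the depolymerization source.

The monomer concentration obeys D c'' = -J_d in steady state.  Integrating
once, the gradient is fixed by the rear boundary condition (confined mode:
D c'(L_sys) = V F(L_sys), the convergence-zone influx; unconfined mode:
c'(rear) = 0 since F has vanished there); integrating again, the offset is
fixed by the total-actin closure mean(c + F) = A over the domain.  The
resulting c(0) is the fixed-point output of one solver iterate.

x increases rearward, so the forward (toward the edge) monomer flux shows up
as c'(x) > 0: the G-actin concentration rises away from the leading edge.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .geometry import EdgeState
from .parameters import ModelParameters, NumericalControls

__all__ = ["solve_monomer_profile"]


def solve_monomer_profile(
    J_d: np.ndarray,
    F: np.ndarray,
    x_grid: np.ndarray,
    edge: EdgeState,
    p: ModelParameters,
    controls: NumericalControls | None = None,
    mode: str = "confined",
) -> tuple[np.ndarray, float]:
    """Return (c(x), c(0)) for the given source density and F-actin profile.

    ``mode`` selects the rear boundary condition (see module docstring).  A
    negative c anywhere marks an infeasible iterate; the array is returned
    as-is and the caller decides (the fixed-point driver shrinks its step).
    """
    if mode not in ("confined", "unconfined"):
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(x_grid, dtype=float)
    L = float(x[-1] - x[0])
    I = cumulative_trapezoid(J_d, x, initial=0.0)      # int_0^x J_d
    F_rear = float(F[-1]) if mode == "confined" else 0.0
    C1 = (edge.V * F_rear + I[-1]) / p.D
    dc = C1 - I / p.D                                   # c'(x) >= 0
    G = cumulative_trapezoid(dc, x, initial=0.0)        # c(x) - c(0)
    mean_F = np.trapezoid(F, x) / L
    mean_G = np.trapezoid(G, x) / L
    c0 = p.A - mean_F - mean_G
    return c0 + G, c0
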