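"""Joint forward solver for the coupled degradation / bone / ultrastructure system.

The full state is eight-dimensional: the analytic volume-loss fraction
(never integrated numerically — its closed form is evaluated on the output
grid), five bone-formation states (x1, x2, I, N, H) and, optionally, the
two ultrastructure states (Cw, L).  All ODE states are integrated in one
``solve_ivp`` call so the mineralization flux dH/dt seen by the crystal
equation is exactly the one the bone equations produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .degradation import DegradationParams, volume_loss, volume_loss_rate
from .remodelling import RemodellingParams, hill_gate
from .ultrastructure import UltrastructureParams

__all__ = ["Trajectory", "simulate"]

_CORE = ["x1", "x2", "I", "N", "H"]


@dataclass
class Trajectory:
    """Solved model trajectory on an output grid.

    ``data`` holds one row per output time (column ``time_days`` plus one
    column per state variable, always including ``vloss``).  ``dense`` is
    the solver's continuous interpolant over the ODE states, used for
    evaluation at arbitrary experimental times and for the closed-form
    oracles.
    """

    data: pd.DataFrame
    rem: RemodellingParams
    deg: DegradationParams | None = None
    ultra: UltrastructureParams | None = None
    dense: object | None = field(default=None, repr=False)

    @property
    def times(self) -> np.ndarray:
        return self.data["time_days"].to_numpy()

    def state_at(self, t):
        """ODE state vector(s) at arbitrary time(s) from the dense interpolant."""
        if self.dense is None:
            raise ValueError("trajectory carries no dense interpolant")
        return self.dense(np.asarray(t, dtype=float))

    def value(self, var: str, t):
        """Interpolated value of one variable at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        if var == "vloss":
            if self.deg is None:
                out = np.zeros_like(t)
                return out if out.ndim else 0.0
            return volume_loss(self.deg, t)
        ode_names = list(_CORE) + (["cwidth", "lattice"] if self.ultra is not None else [])
        if self.dense is not None and var in ode_names:
            raw = self.state_at(t)[ode_names.index(var)]
            # the solver carries log-width internally
            return self.ultra.C0 * np.exp(raw) if var == "cwidth" else raw
        return np.interp(t, self.times, self.data[var].to_numpy())

    def dh_dt(self, t):
        """Mineralization flux dH/dt reconstructed exactly from the RHS."""
        y = self.state_at(t)
        p = self.rem
        I, N = y[2], y[3]
        gate = p.b / (p.b + np.maximum(I, 0.0) ** p.a)
        return p.k3 * gate * np.maximum(N, 0.0)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def integrate_states(
    rem: RemodellingParams,
    t_eval,
    deg: DegradationParams | None = None,
    ultra: UltrastructureParams | None = None,
    H0: float = 0.0,
    I0: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Raw state array at ``t_eval`` (rows: times, cols: states), no container.

    The lightweight path used inside calibration loops, where thousands of
    solves are needed and only a handful of output times matter.  Column
    order matches :data:`_CORE` (+ cwidth, lattice when ``ultra`` given).
    """
    from scipy.integrate import odeint

    t_eval = np.asarray(t_eval, dtype=float)
    p = rem
    vr = (lambda t: volume_loss_rate(deg, t)) if deg is not None else (lambda t: 0.0)
    with_ultra = ultra is not None
    removal_by_flux = p.inhibitor_removal == "maturation_flux"

    def rhs(y, t):
        x1, x2, I, N, H = y[:5]
        dx1 = -p.k1 * x1
        dx2 = p.k1 * x1
        dH = p.k3 * hill_gate(I, p.a, p.b) * max(N, 0.0)
        dN = p.k2 * dx2 - p.r2 * dH * N
        removal = p.r1 * (dx2 if removal_by_flux else x2) * I
        dI = p.v1 * x1 - removal + p.m2 * vr(t)
        if not with_ultra:
            return (dx1, dx2, dI, dN, dH)
        w, L = y[5], y[6]
        # crystal width integrated as w = ln(Cw/C0): linear, never stiff
        dw = ultra.k4 * max(dH, 0.0) ** ultra.k6
        dL = -ultra.k7 * vr(t) * (L - ultra.L_min) + ultra.k8 * (ultra.L_max - L)
        return (dx1, dx2, dI, dN, dH, dw, dL)

    y0 = [1.0, 0.0, I0, 0.0, H0]
    if with_ultra:
        y0 += [0.0, ultra.L_max]
    # odeint silently truncates on "excess work"; detect and retry with a
    # larger step budget before giving up
    for mxstep in (500, 50000):
        states, info = odeint(rhs, y0, t_eval, rtol=rtol, atol=atol,
                              mxstep=mxstep, full_output=True)
        if info["message"] == "Integration successful.":
            break
    else:
        raise RuntimeError(f"ODE integration failed: {info['message']}")
    if with_ultra:
        with np.errstate(over="ignore"):
            states[:, 5] = ultra.C0 * np.exp(states[:, 5])
    return states


def simulate(
    rem: RemodellingParams,
    grid,
    deg: DegradationParams | None = None,
    ultra: UltrastructureParams | None = None,
    H0: float = 0.0,
    I0: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the coupled system over ``grid`` (days, strictly increasing, from 0).

    Initial state: all collagen naive (x1 = 1, x2 = 0), inhibitor at its
    normalized resting level (I = 1), no active nucleators (N = 0), mineral
    at ``H0`` (BV/TV %), crystal width at the configured seed and lattice
    spacing at the healthy value L_max.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0) or grid[0] != 0:
        raise ValueError("grid must be strictly increasing and start at 0")

    p = rem
    vr = (lambda t: volume_loss_rate(deg, t)) if deg is not None else (lambda t: 0.0)
    with_ultra = ultra is not None
    removal_by_flux = p.inhibitor_removal == "maturation_flux"

    def rhs(t, y):
        x1, x2, I, N, H = y[:5]
        dx1 = -p.k1 * x1
        dx2 = p.k1 * x1
        dH = p.k3 * hill_gate(I, p.a, p.b) * max(N, 0.0)
        dN = p.k2 * dx2 - p.r2 * dH * N
        removal = p.r1 * (dx2 if removal_by_flux else x2) * I
        dI = p.v1 * x1 - removal + p.m2 * vr(t)
        if not with_ultra:
            return (dx1, dx2, dI, dN, dH)
        w, L = y[5], y[6]
        # crystal width integrated as w = ln(Cw/C0): the separable growth law
        # is linear in log space, so it can neither overflow nor go stiff
        dw = ultra.k4 * max(dH, 0.0) ** ultra.k6
        dL = -ultra.k7 * vr(t) * (L - ultra.L_min) + ultra.k8 * (ultra.L_max - L)
        return (dx1, dx2, dI, dN, dH, dw, dL)

    y0 = [1.0, 0.0, I0, 0.0, H0]
    names = list(_CORE)
    if with_ultra:
        y0 += [0.0, ultra.L_max]
        names += ["cwidth", "lattice"]

    sol = solve_ivp(
        rhs, (grid[0], grid[-1]), y0, method="LSODA",
        t_eval=grid, dense_output=True, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")

    frame = {"time_days": grid}
    for i, name in enumerate(names):
        col = sol.y[i]
        if name == "cwidth":
            col = ultra.C0 * np.exp(col)
        frame[name] = col
    frame["vloss"] = volume_loss(deg, grid) if deg is not None else np.zeros_like(grid)
    return Trajectory(pd.DataFrame(frame), rem=rem, deg=deg, ultra=ultra, dense=sol.sol)
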