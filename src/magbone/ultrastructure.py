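"""Hydroxyapatite ultrastructure dynamics: crystal width and lattice spacing.

Crystal width (platelet thickness, normalized by a healthy reference of
15 nm) grows multiplicatively with the mineralization flux,

    dCw/dt = k4 * Cw * (dH/dt)^k6 ,

where ``k6 >= 1`` is the order of the precipitation process and ``k4``
lumps the crystallization constant, the width-to-surface-area
proportionality and the supersaturation-to-mineral-flux conversion.

Lattice spacing ``L`` (interplanar distance along (310) or (002), in
Angstrom) shrinks while Mg2+ substitutes Ca2+ in the lattice — at a rate
proportional to the implant's volume-loss rate — and relaxes back toward
the healthy value once ion release subsides:

    dL/dt = -k7 * dVloss/dt * (L - L_min) + k8 * (L_max - L) .

Both equations admit closed-form solutions (separable and linear
first-order respectively), implemented here as independent oracles for the
joint ODE solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .degradation import DegradationParams, volume_loss, volume_loss_rate

__all__ = [
    "PLANE_BOUNDS",
    "UltrastructureParams",
    "ultrastructure_rhs",
    "crystal_width_closed_form",
    "lattice_closed_form",
]

#: Literature lattice-spacing bounds (Angstrom) per crystallographic plane:
#: L_min if all Ca2+ were substituted by Mg2+, L_max for healthy crystals.
PLANE_BOUNDS = {"002": (3.403, 3.447), "310": (2.243, 2.281)}

#: Healthy platelet-width normalization (nm).
C_HAT_NM = 15.0


@dataclass(frozen=True)
class UltrastructureParams:
    """Crystal-growth and lattice-substitution rate constants.

    ``C0`` seeds the crystal width: the multiplicative growth law has
    ``Cw = 0`` as an absorbing state, so an initial width of exactly zero
    never grows.  ``C0`` is confounded with the overall fitted scale of
    ``k4`` and is held fixed during calibration.
    """

    k4: float  # crystal growth prefactor
    k6: float  # order of the precipitation process, >= 1
    k7: float  # Ca2+ substitution rate per unit volume loss
    k8: float  # Mg2+ removal rate (1/day)
    plane: str = "002"
    L_min: float | None = None
    L_max: float | None = None
    C_hat: float = C_HAT_NM
    C0: float = 1e-3

    def __post_init__(self) -> None:
        if self.plane not in PLANE_BOUNDS:
            raise ValueError(f"plane must be one of {sorted(PLANE_BOUNDS)}, got {self.plane!r}")
        lo, hi = PLANE_BOUNDS[self.plane]
        if self.L_min is None:
            object.__setattr__(self, "L_min", lo)
        if self.L_max is None:
            object.__setattr__(self, "L_max", hi)
        for name in ("k4", "k6", "k7", "k8"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if self.k6 < 1:
            raise ValueError(f"k6 must be >= 1, got {self.k6}")
        if not self.L_min < self.L_max:
            raise ValueError("require L_min < L_max")
        if not 0 < self.C0 < 1:
            raise ValueError(f"C0 must be a small positive seed in (0, 1), got {self.C0}")


def ultrastructure_rhs(Cw, L, t, params: UltrastructureParams, dH_dt, vloss_rate=None):
    """Derivatives (dCw/dt, dL/dt) at time ``t``.

    ``dH_dt`` and ``vloss_rate`` are callables of time; tiny negative
    mineralization fluxes from solver noise are clipped at zero before the
    fractional power is taken.
    """
    if not params.L_min <= L <= params.L_max:
        raise ValueError(f"L={L} outside [{params.L_min}, {params.L_max}]")
    dh = max(float(dH_dt(t)), 0.0)
    vr = 0.0 if vloss_rate is None else float(vloss_rate(t))
    dCw = params.k4 * Cw * dh**params.k6
    dL = -params.k7 * vr * (L - params.L_min) + params.k8 * (params.L_max - L)
    return dCw, dL


def crystal_width_closed_form(params: UltrastructureParams, dH_dt, t):
    """Separable-ODE solution Cw(t) = C0 * exp(k4 * int_0^t (dH/ds)^k6 ds).

    The integral is evaluated by adaptive quadrature of the supplied
    mineralization-flux callable.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t)
    for i, ti in enumerate(t):
        integral, _ = quad(lambda s: max(float(dH_dt(s)), 0.0) ** params.k6, 0.0, ti, limit=200)
        out[i] = params.C0 * math.exp(params.k4 * integral)
    return out if out.size > 1 else float(out[0])


def lattice_closed_form(params: UltrastructureParams, deg: DegradationParams | None, t):
    """Integrating-factor solution of the linear lattice-spacing ODE.

    With a(s) = k7*vr(s) + k8 and forcing b(s) = k7*vr(s)*L_min + k8*L_max,

        L(t) = e^{-A(t)} ( L_max + int_0^t b(s) e^{A(s)} ds ),

    starting from the healthy value L(0) = L_max.  The antiderivative
    A(t) = k7*Vloss(t) + k8*t is exact because the cumulative volume loss
    has a closed form; the remaining integral uses adaptive quadrature.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    k7, k8 = params.k7, params.k8
    Lmin, Lmax = params.L_min, params.L_max

    if deg is None:
        # no ion release: L relaxes trivially (and stays) at L_max
        out = np.full_like(t, Lmax)
        return out if out.size > 1 else float(out[0])

    def A(s):
        return k7 * volume_loss(deg, s) + k8 * s

    def forcing(s):
        return (k7 * volume_loss_rate(deg, s) * Lmin + k8 * Lmax) * math.exp(A(s) - A_ref)

    out = np.empty_like(t)
    for i, ti in enumerate(t):
        # shift the exponent by A(t) to keep the integrand <= O(1)
        A_ref = A(ti)
        integral, _ = quad(forcing, 0.0, ti, limit=400)
        out[i] = math.exp(-A_ref) * Lmax + integral
    return out if out.size > 1 else float(out[0])
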