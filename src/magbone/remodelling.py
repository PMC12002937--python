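"""Peri-implant bone formation and mineralization kinetics.

An extended Komarova-type ODE system describes how mineralized bone (state
``H``, identified with the relative bone volume fraction BV/TV up to the
proportionality constant absorbed into the growth rate ``k3``) forms
around an implant:

* naive collagen matrix ``x1`` (init 1) matures into ``x2`` at rate ``k1``;
* a generalized mineralization inhibitor ``I`` (pyrophosphate, SIBLING
  proteins; init 1) is produced through the naive matrix at rate ``v1`` and
  removed during matrix maturation at rate ``r1``;
* active nucleation sites ``N`` are created during maturation (``k2`` per
  maturation event) and inactivated when enclosed in mineral at rate ``r2``;
* mineral ``H`` grows at rate ``k3`` gated by a steep Hill function of the
  inhibitor, ``b / (b + I^a)``.

For biodegradable Mg alloys, Mg2+ release — proportional to the implant's
volume-loss rate — feeds the inhibitor pool at rate ``m2``; for permanent
(Ti) implants ``m2 = 0``.

The conserved quantity ``x1 + x2`` and nonnegativity of all states are the
structural invariants the test suite enforces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["RemodellingParams", "remodelling_rhs", "simulate_remodelling", "compute_lag"]

#: Hill coefficients fixed to the values of the parent mineralization model.
HILL_A_DEFAULT = 10.0
HILL_B_DEFAULT = 0.001


@dataclass(frozen=True)
class RemodellingParams:
    """Rate constants of the bone-formation ODEs (all per day).

    ``inhibitor_removal`` selects the removal term in the inhibitor
    equation.  The default ``"mature_matrix"`` removes inhibitor in
    proportion to the mature matrix, ``-r1*x2*I``: this is the only form
    under which Mg-perturbed inhibitor levels decay after matrix
    maturation completes, so mineralization around degradable implants can
    recover.  The alternative ``"maturation_flux"`` couples removal to the
    maturation flux instead, ``-r1*(k1*x1)*I``.
    """

    k1: float  # matrix maturation rate
    v1: float  # inhibitor production rate
    r1: float  # inhibitor removal rate
    r2: float  # nucleator encapsulation rate
    k3: float  # bone growth rate (BV/TV-% scale)
    m2: float = 0.0  # effective Mg-inhibition rate (0 for Ti)
    k2: float = 1.0  # nucleators per maturation event (fixed)
    a: float = HILL_A_DEFAULT  # Hill exponent (fixed)
    b: float = HILL_B_DEFAULT  # Hill constant (fixed)
    inhibitor_removal: str = "mature_matrix"

    def __post_init__(self) -> None:
        for name in ("k1", "v1", "r1", "r2", "k3", "k2", "a", "b"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if not math.isfinite(self.m2) or self.m2 < 0:
            raise ValueError(f"m2 must be finite and >= 0, got {self.m2}")
        if self.inhibitor_removal not in ("maturation_flux", "mature_matrix"):
            raise ValueError(f"unknown inhibitor_removal {self.inhibitor_removal!r}")


def hill_gate(I: float, a: float = HILL_A_DEFAULT, b: float = HILL_B_DEFAULT) -> float:
    """Inhibitor gate ``b / (b + I^a)`` in (0, 1]; equals 1 iff I = 0."""
    return b / (b + max(I, 0.0) ** a)


def remodelling_rhs(state, t, params: RemodellingParams, vloss_rate=None):
    """Time derivative of (x1, x2, I, N, H).

    ``vloss_rate`` is the analytic degradation-rate function of time (or
    None for a non-degradable implant).  ``dH/dt`` is computed first and
    substituted into ``dN/dt`` — the two are mutually referential on paper
    but involve no algebraic loop.
    """
    x1, x2, I, N, H = (float(s) for s in state)
    if not all(map(math.isfinite, (x1, x2, I, N, H))):
        raise ValueError(f"non-finite state {state!r}")
    p = params
    dx1 = -p.k1 * x1
    dx2 = p.k1 * x1
    dH = p.k3 * hill_gate(I, p.a, p.b) * max(N, 0.0)
    dN = p.k2 * dx2 - p.r2 * dH * N
    vr = 0.0 if vloss_rate is None else vloss_rate(t)
    if p.inhibitor_removal == "maturation_flux":
        removal = p.r1 * dx2 * I
    else:
        removal = p.r1 * x2 * I
    dI = p.v1 * x1 - removal + p.m2 * vr
    return np.array([dx1, dx2, dI, dN, dH])


def simulate_remodelling(params, degradation, grid, H0=0.0, I0=1.0, rtol=1e-8, atol=1e-10):
    """Solve the bone-formation system coupled to an analytic degradation rate.

    Thin wrapper over the joint forward solver (no ultrastructure states).
    See :func:`magbone.forward.simulate`.
    """
    from .forward import simulate

    return simulate(params, grid, deg=degradation, H0=H0, I0=I0, rtol=rtol, atol=atol)


def compute_lag(t, h, flat_tol=1e-12):
    """Mineralization lag time from a growth curve, in the time units of ``t``.

    Standard growth-curve definition: the tangent at the point of maximum
    slope is extended back to the baseline ``H = H(0)``; its intersection
    is the lag.  Raises ``ValueError`` for a flat trajectory.
    """
    t = np.asarray(t, dtype=float)
    h = np.asarray(h, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points to estimate a lag")
    dh = np.gradient(h, t)
    i = int(np.argmax(dh))
    slope = dh[i]
    if slope <= flat_tol * max(1.0, np.max(np.abs(h))):
        raise ValueError("trajectory has no growth phase; lag undefined")
    return float(t[i] - (h[i] - h[0]) / slope)
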