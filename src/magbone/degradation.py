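"""Implant volume-loss kinetics.

Two reduced models of biodegradable-implant corrosion are provided, both
expressed for the volume-loss *fraction* ``Vloss`` (dimensionless, in
``[0, ~1)``; conversion to percent happens only at I/O boundaries):

* ``power_law`` — diffusion-limited corrosion, ``dV/dt = m1 / sqrt(t)``.
  The scaled diffusion coefficient ``m1`` absorbs the Mg2+ diffusivity and
  saturation concentration of the underlying transport picture.  Because the
  rate is singular at ``t = 0``, a small offset ``eps_t`` (default 1e-30) is
  added to ``t``.
* ``surface_rate`` — corrosion slowed by precipitated degradation products,
  ``dV/dt = r' d' / (r' t + d')``, where ``r'`` is the effective surface
  corrosion rate (1/day) and ``d'`` the effective precipitated-material
  fraction, both already rescaled by the implant's initial surface-to-volume
  ratio.

Both rates integrate in closed form, which the other ODE modules exploit:
the cumulative loss is never obtained by numerically differentiating or
integrating a solver trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = ["DegradationModel", "DegradationParams", "volume_loss_rate", "volume_loss"]


class DegradationModel(str, Enum):
    POWER_LAW = "power_law"
    SURFACE_RATE = "surface_rate"


@dataclass(frozen=True)
class DegradationParams:
    """Parameters of either volume-loss model.

    Parameters
    ----------
    model_id
        Which rate law to use.
    m1
        Scaled diffusion coefficient (volume fraction / day^(1-exponent));
        used iff ``model_id == POWER_LAW``.
    r_prime
        Effective surface corrosion rate (1/day); used iff
        ``model_id == SURFACE_RATE``.
    d_prime
        Effective precipitated-material fraction (dimensionless); used iff
        ``model_id == SURFACE_RATE``.
    eps_t
        Small time offset regularizing the power-law singularity at t = 0.
    exponent
        Power-law singularity exponent p in ``dV/dt = m1 (t + eps)^(-p)``.
        The diffusion-limited default is 1/2.
    """

    model_id: DegradationModel
    m1: float | None = None
    r_prime: float | None = None
    d_prime: float | None = None
    eps_t: float = 1e-30
    exponent: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_id", DegradationModel(self.model_id))
        if self.eps_t <= 0 or not math.isfinite(self.eps_t):
            raise ValueError(f"eps_t must be positive and finite, got {self.eps_t}")
        if self.model_id is DegradationModel.POWER_LAW:
            if self.m1 is None or not math.isfinite(self.m1) or self.m1 < 0:
                raise ValueError(f"power_law requires finite m1 >= 0, got {self.m1}")
            if not 0 < self.exponent < 1:
                raise ValueError(f"exponent must lie in (0, 1), got {self.exponent}")
        else:
            for name in ("r_prime", "d_prime"):
                v = getattr(self, name)
                if v is None or not math.isfinite(v) or v <= 0:
                    raise ValueError(f"surface_rate requires finite {name} > 0, got {v}")


def _check_time(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("time must be finite and nonnegative")
    return t


def volume_loss_rate(params: DegradationParams, t):
    """Instantaneous volume-loss rate dV/dt (fraction per day).

    Nonnegative and non-increasing in ``t`` for both models.  Accepts scalar
    or array time.
    """
    t = _check_time(t)
    if params.model_id is DegradationModel.POWER_LAW:
        out = params.m1 * (t + params.eps_t) ** (-params.exponent)
    else:
        r, d = params.r_prime, params.d_prime
        out = r * d / (r * t + d)
    return out if out.ndim else float(out)


def volume_loss(params: DegradationParams, t):
    """Cumulative volume-loss fraction V(t), closed form, with V(0) = 0.

    power_law:     V(t) = m1/(1-p) * ((t+eps)^(1-p) - eps^(1-p))
    surface_rate:  V(t) = d' * log(1 + r' t / d')
    """
    t = _check_time(t)
    if params.model_id is DegradationModel.POWER_LAW:
        q = 1.0 - params.exponent
        out = params.m1 / q * ((t + params.eps_t) ** q - params.eps_t**q)
    else:
        r, d = params.r_prime, params.d_prime
        out = d * np.log1p(r * t / d)
    return out if out.ndim else float(out)
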