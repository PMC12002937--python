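"""Variance-based global sensitivity analysis (Sobol indices).

First-order indices Si = V_i / Var(Y) measure each parameter's individual
contribution to output variance; total-effect indices STi add all
interaction terms involving that parameter.  Estimation uses the Saltelli
cross-sampling design: two quasi-random base matrices A and B of size
``n_base x d`` plus the d hybrid matrices AB_i (A with column i taken from
B), for ``n_base * (d + 2)`` model evaluations (second-order terms are not
estimated).  The estimators are Saltelli's 2010 first-order estimator and
Jansen's total-order estimator.

Parameters are assumed uniform within +/-20% of the calibrated optimum (the
analysis interrogates the model near the fit, not the full calibration
box); a parameter is flagged influential when Si >= 0.05 or STi >= 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

__all__ = [
    "SobolResult",
    "make_ranges",
    "pooled_ranges",
    "saltelli_sample",
    "sobol_indices",
    "classify_influential",
    "model_output_scalar",
]

SI_THRESHOLD = 0.05
STI_THRESHOLD = 0.10


@dataclass
class SobolResult:
    """Per-parameter Sobol indices with bootstrap CIs and influence flags."""

    names: list[str]
    Si: np.ndarray
    STi: np.ndarray
    Si_ci: np.ndarray  # (d, 2) bootstrap 95% interval
    STi_ci: np.ndarray
    influential: dict[str, bool]
    n_base: int
    seed: int | None = None
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "parameter": self.names, "Si": self.Si, "STi": self.STi,
            "Si_lo": self.Si_ci[:, 0], "Si_hi": self.Si_ci[:, 1],
            "STi_lo": self.STi_ci[:, 0], "STi_hi": self.STi_ci[:, 1],
            "influential": [self.influential[n] for n in self.names],
        })


def make_ranges(optimum: dict[str, float], fraction: float = 0.2,
                zero_scale: float = 1.0) -> dict[str, tuple[float, float]]:
    """Uniform interval [theta*(1-f), theta*(1+f)] around each optimum.

    A degenerate optimum of exactly zero expands to [0, f*zero_scale].
    """
    if fraction <= 0:
        raise ValueError("fraction must be > 0")
    out = {}
    for name, theta in optimum.items():
        if theta == 0:
            out[name] = (0.0, fraction * zero_scale)
        else:
            lo, hi = theta * (1 - fraction), theta * (1 + fraction)
            out[name] = (min(lo, hi), max(lo, hi))
    return out


def pooled_ranges(optima: list[dict[str, float]], fraction: float = 0.2) -> dict[str, tuple[float, float]]:
    """Interval spanning several optima (e.g. both Mg alloys), each widened by +/-f.

    Used for the volume-loss analysis, where the calibrated degradation
    parameters of Mg-5Gd and Mg-10Gd are considered jointly.
    """
    names = list(optima[0])
    out = {}
    for name in names:
        vals = [o[name] for o in optima]
        out[name] = (min(vals) * (1 - fraction), max(vals) * (1 + fraction))
    return out


def saltelli_sample(ranges: dict[str, tuple[float, float]], n_base: int,
                    seed: int | None = None) -> np.ndarray:
    """Saltelli design matrix of shape ``(n_base*(d+2), d)``.

    Row layout: the A block, then the d AB_i blocks (A with column i from
    B), then the B block.  A and B come from one scrambled Sobol' sequence
    of dimension 2d, so the design is deterministic under ``seed``.
    """
    names = list(ranges)
    d = len(names)
    lo = np.array([ranges[k][0] for k in names])
    hi = np.array([ranges[k][1] for k in names])
    if np.any(hi <= lo):
        raise ValueError("ranges must have positive width")
    base = qmc.Sobol(d=2 * d, scramble=True, seed=seed).random(n_base)
    A = lo + base[:, :d] * (hi - lo)
    B = lo + base[:, d:] * (hi - lo)
    blocks = [A]
    for i in range(d):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        blocks.append(ABi)
    blocks.append(B)
    return np.vstack(blocks)


def sobol_indices(outputs, d: int, n_base: int, names: list[str] | None = None,
                  n_boot: int = 200, seed: int | None = None,
                  ranges: dict | None = None) -> SobolResult:
    """Estimate Si and STi from outputs evaluated on a Saltelli design.

    ``outputs`` must follow the row layout of :func:`saltelli_sample`.
    Raises for a constant model (zero output variance).
    """
    y = np.asarray(outputs, dtype=float)
    if y.ndim != 1 or y.size != n_base * (d + 2):
        raise ValueError(f"expected {n_base * (d + 2)} outputs, got {y.size}")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite model outputs")
    fA = y[:n_base]
    fAB = y[n_base:n_base * (d + 1)].reshape(d, n_base)
    fB = y[n_base * (d + 1):]

    def estimate(idx):
        a, b, ab = fA[idx], fB[idx], fAB[:, idx]
        var = np.var(np.concatenate([a, b]))
        if var == 0:
            raise ValueError("constant model output: Sobol indices undefined")
        Si = np.mean(b * (ab - a), axis=1) / var
        STi = 0.5 * np.mean((a - ab) ** 2, axis=1) / var
        return Si, STi

    idx_all = np.arange(n_base)
    Si, STi = estimate(idx_all)

    rng = np.random.default_rng(seed)
    boots_S = np.empty((n_boot, d))
    boots_T = np.empty((n_boot, d))
    for k in range(n_boot):
        idx = rng.integers(0, n_base, n_base)
        try:
            boots_S[k], boots_T[k] = estimate(idx)
        except ValueError:
            boots_S[k], boots_T[k] = Si, STi
    Si_ci = np.percentile(boots_S, [2.5, 97.5], axis=0).T
    STi_ci = np.percentile(boots_T, [2.5, 97.5], axis=0).T

    names = names or [f"x{i+1}" for i in range(d)]
    flags = classify_influential(dict(zip(names, Si)), dict(zip(names, STi)))
    return SobolResult(list(names), Si, STi, Si_ci, STi_ci, flags,
                       n_base=n_base, seed=seed, ranges=ranges or {})


def classify_influential(Si: dict[str, float], STi: dict[str, float]) -> dict[str, bool]:
    """Influence flags: Si >= 0.05 or STi >= 0.1."""
    return {k: (Si[k] >= SI_THRESHOLD or STi[k] >= STI_THRESHOLD) for k in Si}


def model_output_scalar(values: np.ndarray, how: str = "mean") -> float:
    """Collapse a trajectory sampled on the experimental grid to one scalar.

    The variance decomposition needs a scalar output per parameter draw;
    the default is the trajectory mean over the grid, with the final value
    and the L2 norm as alternatives.
    """
    v = np.asarray(values, dtype=float)
    if how == "mean":
        return float(np.mean(v))
    if how == "final":
        return float(v[-1])
    if how == "l2":
        return float(np.sqrt(np.sum(v**2)))
    raise ValueError(f"unknown scalarization {how!r}")
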