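"""Goodness-of-fit metrics and residual-based confidence bands.

MAE is reported in the variable's own units; NRMSE is the RMSE divided by
the observed range (so it is comparable across variables of very different
scales — volume-loss fractions vs. BV/TV percent vs. lattice Angstrom); a
mean-normalized variant is available behind a flag.  The confidence band is
a constant-half-width ribbon, half-width MOE = 1.96 * sigma / sqrt(n) with
sigma the residual standard deviation — a residual-based heuristic, not a
bootstrap or profile-likelihood interval.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["mae", "rmse", "nrmse", "moe_band", "MetricReport", "metric_report"]

Z_95 = 1.96


def _pair(model, observed):
    m = np.asarray(model, dtype=float)
    o = np.asarray(observed, dtype=float)
    if m.shape != o.shape or m.size < 1:
        raise ValueError(f"length mismatch or empty series: {m.shape} vs {o.shape}")
    return m, o


def mae(model, observed) -> float:
    """Mean absolute error, in the variable's units."""
    m, o = _pair(model, observed)
    return float(np.mean(np.abs(m - o)))


def rmse(model, observed) -> float:
    m, o = _pair(model, observed)
    return float(np.sqrt(np.mean((m - o) ** 2)))


def nrmse(model, observed, normalization: str = "range") -> float:
    """RMSE normalized by the observed range (or mean)."""
    m, o = _pair(model, observed)
    if normalization == "range":
        denom = float(np.max(o) - np.min(o))
    elif normalization == "mean":
        denom = float(abs(np.mean(o)))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if denom == 0:
        raise ValueError("degenerate observations: zero normalization denominator")
    return rmse(m, o) / denom


def moe_band(sigma: float, n: int) -> float:
    """Margin of error 1.96 * sigma / sqrt(n) (95% normal-quantile half-width)."""
    if sigma < 0 or n < 1:
        raise ValueError("require sigma >= 0 and n >= 1")
    return Z_95 * sigma / np.sqrt(n)


@dataclass(frozen=True)
class MetricReport:
    """Per-variable fit-quality summary."""

    variable: str
    n: int
    mae: float
    nrmse: float
    residual_sd: float
    moe: float

    def to_dict(self) -> dict:
        return asdict(self)


def metric_report(variable: str, model, observed, normalization: str = "range") -> MetricReport:
    """Assemble MAE, NRMSE and the MOE half-width for one variable."""
    m, o = _pair(model, observed)
    resid = m - o
    sigma = float(np.std(resid, ddof=0))
    return MetricReport(
        variable=variable,
        n=m.size,
        mae=mae(m, o),
        nrmse=nrmse(m, o, normalization),
        residual_sd=sigma,
        moe=float(moe_band(sigma, m.size)),
    )
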