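"""Derivative-free optimization: CMA-ES with box constraints, LHS multi-start.

The covariance matrix adaptation evolution strategy is implemented with the
standard (mu/mu_w, lambda) update equations: rank-based recombination
weights, cumulation paths for the step size and the rank-one covariance
update, and a rank-mu update from the current population.  Box constraints
are handled by repair-plus-penalty: candidates are evaluated at their
projection onto the box, with a quadratic penalty on the projection
distance, while the strategy state is updated with the unrepaired samples.

Parameters are optimized in a [0, 1]-rescaled box; callers work with named
parameter dictionaries and physical bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

__all__ = ["OptimizerConfig", "CMAResult", "cma_es_minimize", "lhs_init"]


@dataclass(frozen=True)
class OptimizerConfig:
    """CMA-ES settings.

    ``sigma0`` is the initial step size as a fraction of the box width per
    dimension.  ``popsize`` defaults to the standard 4 + floor(3 ln d).
    """

    sigma0: float = 0.25
    popsize: int | None = None
    max_iter: int = 500
    ftol: float = 1e-10
    penalty: float = 1e6

    def __post_init__(self) -> None:
        if not 0 < self.sigma0 <= 1:
            raise ValueError("sigma0 must be in (0, 1]")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class CMAResult:
    x: np.ndarray
    fun: float
    n_iter: int
    n_eval: int
    converged: bool
    history: list = field(default_factory=list, repr=False)


def cma_es_minimize(f, x0, config: OptimizerConfig, rng) -> CMAResult:
    """Minimize ``f`` over the unit box [0,1]^d starting from ``x0``.

    ``rng`` is a ``numpy.random.Generator``; the run is deterministic given
    its state.
    """
    x0 = np.asarray(x0, dtype=float)
    d = x0.size
    lam = config.popsize or (4 + int(3 * math.log(d)))
    lam = max(lam, 4)
    mu = lam // 2
    w = math.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)

    cc = (4 + mueff / d) / (d + 4 + 2 * mueff / d)
    cs = (mueff + 2) / (d + mueff + 5)
    c1 = 2 / ((d + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((d + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, math.sqrt((mueff - 1) / (d + 1)) - 1) + cs
    chi_d = math.sqrt(d) * (1 - 1 / (4 * d) + 1 / (21 * d**2))

    m = np.clip(x0, 0.0, 1.0)
    sigma = config.sigma0
    C = np.eye(d)
    ps = np.zeros(d)
    pc = np.zeros(d)

    best_x, best_f = m.copy(), math.inf
    history: list[float] = []
    n_eval = 0
    converged = False

    for it in range(1, config.max_iter + 1):
        # sample around the mean with the current covariance
        C = (C + C.T) / 2
        evals, B = np.linalg.eigh(C)
        evals = np.maximum(evals, 1e-20)
        D = np.sqrt(evals)
        z = rng.standard_normal((lam, d))
        y = z * D @ B.T  # y_k = B D z_k
        x = m + sigma * y

        x_rep = np.clip(x, 0.0, 1.0)
        dist2 = np.sum((x - x_rep) ** 2, axis=1)
        fit = np.empty(lam)
        for k in range(lam):
            fit[k] = f(x_rep[k]) + config.penalty * dist2[k]
        n_eval += lam

        order = np.argsort(fit)
        if fit[order[0]] < best_f:
            best_f = float(fit[order[0]])
            best_x = x_rep[order[0]].copy()
        history.append(float(fit[order[0]]))

        y_sel = y[order[:mu]]
        y_w = w @ y_sel
        m = m + sigma * y_w

        # step-size path (uses C^{-1/2} y_w)
        c_inv_half_yw = B @ ((B.T @ y_w) / D)
        ps = (1 - cs) * ps + math.sqrt(cs * (2 - cs) * mueff) * c_inv_half_yw
        hsig = (
            np.linalg.norm(ps) / math.sqrt(1 - (1 - cs) ** (2 * it)) / chi_d
            < 1.4 + 2 / (d + 1)
        )
        pc = (1 - cc) * pc + hsig * math.sqrt(cc * (2 - cc) * mueff) * y_w

        rank_mu = (y_sel * w[:, None]).T @ y_sel
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (1 - hsig) * cc * (2 - cc) * C)
            + cmu * rank_mu
        )
        sigma *= math.exp((cs / damps) * (np.linalg.norm(ps) / chi_d - 1))
        sigma = min(sigma, 1.0)

        if len(history) > 20 and abs(history[-20] - history[-1]) < config.ftol:
            converged = True
            break
        if sigma < 1e-12:
            converged = True
            break

    return CMAResult(best_x, best_f, it, n_eval, converged, history)


def lhs_init(bounds: dict[str, tuple[float, float]], n_samples: int, seed) -> list[dict[str, float]]:
    """Latin hypercube starting points within named parameter bounds.

    Each dimension is stratified into ``n_samples`` equal-probability bins
    with exactly one sample per bin; deterministic under a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    names = list(bounds)
    lo = np.array([bounds[k][0] for k in names], dtype=float)
    hi = np.array([bounds[k][1] for k in names], dtype=float)
    if np.any(~np.isfinite(lo)) or np.any(~np.isfinite(hi)) or np.any(lo >= hi):
        raise ValueError("bounds must be finite with lo < hi")
    unit = qmc.LatinHypercube(d=len(names), seed=seed).random(n_samples)
    scaled = qmc.scale(unit, lo, hi)
    return [dict(zip(names, row)) for row in scaled]
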