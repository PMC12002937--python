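"""Synthetic study generator: the statistical stand-in for the animal data.

The underlying animal experiments (Ti, Mg-5Gd and Mg-10Gd screws in rat
tibiae, plus a second Ti-pin study at earlier time points) report only
per-time-point medians with dispersion, and the raw tables are not publicly
deposited.  This module generates datasets of exactly that shape from
forward-model truth parameters: per-animal trajectory values perturbed by
measurement noise, then summarized to (median, sd, n) rows per material,
variable and time point.

Design defaults emulate the two studies:

* study 1 — BV/TV and volume loss at 4, 8, 10, 12, 20, 32 weeks
  ({28, 56, 70, 84, 140, 224} days); crystal width and (310) lattice spacing
  at 4, 8, 12 weeks; (002) lattice spacing at 10, 20, 32 weeks; H(0) = 0.
* study 2 — BV/TV at {3, 7, 14, 28, 90} days, Ti only, with the initial
  bone fraction set to the day-3 level (H(0) = 42.47 %).

Noise is multiplicative Gaussian (default CV 10 %) for volume loss, BV/TV
and crystal width, whose reported dispersions scale with the signal, and
additive in Angstrom (default sd 0.005) for lattice spacing, whose dynamic
range is a few hundredths of an Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .degradation import DegradationParams
from .forward import simulate
from .remodelling import RemodellingParams
from .ultrastructure import UltrastructureParams

__all__ = [
    "MATERIALS",
    "VARIABLES",
    "StudyDesign",
    "StudyDataset",
    "MaterialTruth",
    "default_truth",
    "study1_design",
    "study2_design",
    "generate_study",
    "fixture_bundle",
]

MATERIALS = ("Ti", "Mg-5Gd", "Mg-10Gd")
VARIABLES = ("vloss", "bvtv", "cwidth", "l310", "l002")

#: Variables reported per material: lattice spacing and volume loss are only
#: measured for the degradable alloys.
_DEFAULT_VARIABLES = {
    "Ti": ("bvtv", "cwidth"),
    "Mg-5Gd": ("vloss", "bvtv", "cwidth", "l310", "l002"),
    "Mg-10Gd": ("vloss", "bvtv", "cwidth", "l310", "l002"),
}

_STUDY1_GRIDS = {
    "vloss": (28.0, 56.0, 70.0, 84.0, 140.0, 224.0),
    "bvtv": (28.0, 56.0, 70.0, 84.0, 140.0, 224.0),
    "cwidth": (28.0, 56.0, 84.0),
    "l310": (28.0, 56.0, 84.0),
    "l002": (70.0, 140.0, 224.0),
}
_STUDY2_GRIDS = {"bvtv": (3.0, 7.0, 14.0, 28.0, 90.0)}

#: Median BV/TV (%) observed at day 3 in the second study, used as H(0).
STUDY2_H0 = 42.47


@dataclass(frozen=True)
class StudyDesign:
    study_id: str
    materials: tuple[str, ...]
    grids: dict[str, tuple[float, ...]]
    variables_by_material: dict[str, tuple[str, ...]]
    animals: int = 6
    cv: float = 0.10
    lattice_sd: float = 0.005
    H0: float = 0.0

    def __post_init__(self) -> None:
        if self.animals < 1:
            raise ValueError("animals must be >= 1")
        if self.cv < 0 or self.lattice_sd < 0:
            raise ValueError("noise levels must be >= 0")
        for var, grid in self.grids.items():
            g = np.asarray(grid, dtype=float)
            if np.any(np.diff(g) <= 0) or np.any(g < 0):
                raise ValueError(f"grid for {var} must be strictly increasing and >= 0")


def study1_design(**overrides) -> StudyDesign:
    kw = dict(
        study_id="study1",
        materials=MATERIALS,
        grids=dict(_STUDY1_GRIDS),
        variables_by_material=dict(_DEFAULT_VARIABLES),
        H0=0.0,
    )
    kw.update(overrides)
    return StudyDesign(**kw)


def study2_design(**overrides) -> StudyDesign:
    kw = dict(
        study_id="study2",
        materials=("Ti",),
        grids=dict(_STUDY2_GRIDS),
        variables_by_material={"Ti": ("bvtv",)},
        H0=STUDY2_H0,
    )
    kw.update(overrides)
    return StudyDesign(**kw)


@dataclass(frozen=True)
class MaterialTruth:
    """Generating parameters for one material (ultrastructure per plane)."""

    rem: RemodellingParams
    deg: DegradationParams | None = None
    ultra: dict[str, UltrastructureParams] = field(default_factory=dict)


def default_truth(degradation_model: str = "surface_rate") -> dict[str, MaterialTruth]:
    """Calibrated parameter sets used as generator truth.

    Ti bone rates: k1 = 0.3880, v1 = 0.0164, r1 = 0.4915, r2 = 23.1846,
    k3 = 0.5744; Mg alloys share the Ti rates but add Mg inhibition
    m2 = 84.0455 and faster growth k3 = 6.9291.  Degradation: surface-rate
    (r', d') = (1.104, 0.040) for Mg-5Gd and (0.062, 0.068) for Mg-10Gd, or
    the power law with m1 = 0.015 for both.  Mg-5Gd inherits the Mg-10Gd
    bone and ultrastructure parameters (the transfer assumption the staged
    calibration is designed to test).
    """
    ti_rem = RemodellingParams(k1=0.3880, v1=0.0164, r1=0.4915, r2=23.1846, k3=0.5744, m2=0.0)
    mg_rem = RemodellingParams(k1=0.3880, v1=0.0164, r1=0.4915, r2=23.1846, k3=6.9291, m2=84.0455)

    def ultra(k4, k6, k7_310, k8_310, k7_002, k8_002):
        return {
            "310": UltrastructureParams(k4=k4, k6=k6, k7=k7_310, k8=k8_310, plane="310"),
            "002": UltrastructureParams(k4=k4, k6=k6, k7=k7_002, k8=k8_002, plane="002"),
        }

    # Ti releases no Mg2+, so its lattice never leaves L_max; the k7/k8
    # values are inert placeholders kept equal to the Mg ones.
    ti_ultra = ultra(38.1357, 1.2694, 6.2619, 0.0109, 2.3037, 0.0092)
    mg_ultra = ultra(115.0688, 1.4712, 6.2619, 0.0109, 2.3037, 0.0092)

    if degradation_model == "surface_rate":
        deg5 = DegradationParams("surface_rate", r_prime=1.104, d_prime=0.040)
        deg10 = DegradationParams("surface_rate", r_prime=0.062, d_prime=0.068)
    elif degradation_model == "power_law":
        deg5 = DegradationParams("power_law", m1=0.015)
        deg10 = DegradationParams("power_law", m1=0.015)
    else:
        raise ValueError(f"unknown degradation_model {degradation_model!r}")

    return {
        "Ti": MaterialTruth(rem=ti_rem, deg=None, ultra=ti_ultra),
        "Mg-5Gd": MaterialTruth(rem=mg_rem, deg=deg5, ultra=mg_ultra),
        "Mg-10Gd": MaterialTruth(rem=mg_rem, deg=deg10, ultra=mg_ultra),
    }


def study2_truth() -> dict[str, MaterialTruth]:
    """Generator truth for the second (Ti-pin, early-time) study.

    Calibrated on the percent scale with the day-3 bone level as the
    initial condition: k1 = 18.5965, v1 = 0.3474, r1 = 9.6068,
    r2 = 0.8024, k3 = 0.6029.  Crystal-width parameters reuse the Ti
    defaults (study 2 reports no ultrastructure data).
    """
    rem = RemodellingParams(k1=18.5965, v1=0.3474, r1=9.6068, r2=0.8024, k3=0.6029, m2=0.0)
    ultra = {
        "310": UltrastructureParams(k4=38.1357, k6=1.2694, k7=6.2619, k8=0.0109, plane="310"),
        "002": UltrastructureParams(k4=38.1357, k6=1.2694, k7=2.3037, k8=0.0092, plane="002"),
    }
    return {"Ti": MaterialTruth(rem=rem, deg=None, ultra=ultra)}


@dataclass
class StudyDataset:
    """Summarized study table: one (median, sd, n) row per material/variable/time."""

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    _COLUMNS = ("material", "variable", "time_days", "median", "sd", "n")

    def __post_init__(self) -> None:
        missing = set(self._COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        if (self.data["sd"] < 0).any():
            raise ValueError("sd must be >= 0")

    def subset(self, material: str, variable: str) -> pd.DataFrame:
        sel = self.data[
            (self.data["material"] == material) & (self.data["variable"] == variable)
        ]
        return sel.sort_values("time_days").reset_index(drop=True)

    def materials(self) -> list[str]:
        return sorted(self.data["material"].unique())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StudyDataset":
        return cls(pd.read_csv(path))


def _solver_grid(sample_times: np.ndarray) -> np.ndarray:
    times = np.unique(np.concatenate([[0.0], sample_times]))
    return times


def generate_study(
    design: StudyDesign, truth: dict[str, MaterialTruth], seed: int
) -> StudyDataset:
    """Draw one synthetic study: per-animal noise on truth trajectories.

    Per animal and time point the sampled value is ``x * (1 + eps)`` with
    ``eps ~ N(0, CV^2)`` (additive ``N(0, lattice_sd^2)`` for lattice
    spacing), summarized across ``design.animals`` animals to median and
    sample standard deviation.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for material in design.materials:
        mt = truth[material]
        variables = design.variables_by_material.get(material, ())
        times_needed = np.unique(
            np.concatenate([design.grids[v] for v in variables if v in design.grids])
        )
        grid = _solver_grid(times_needed)
        trajs = {}
        for plane in ("310", "002"):
            trajs[plane] = simulate(
                mt.rem, grid, deg=mt.deg, ultra=mt.ultra.get(plane), H0=design.H0
            )
        for var in variables:
            t_var = np.asarray(design.grids[var], dtype=float)
            traj = trajs["002"] if var == "l002" else trajs["310"]
            col = {"vloss": "vloss", "bvtv": "H", "cwidth": "cwidth", "l310": "lattice", "l002": "lattice"}[var]
            base = np.interp(t_var, traj.times, traj.data[col].to_numpy())
            for tv, x in zip(t_var, base):
                if var in ("l310", "l002"):
                    draws = x + design.lattice_sd * rng.standard_normal(design.animals)
                else:
                    draws = x * (1.0 + design.cv * rng.standard_normal(design.animals))
                sd = float(np.std(draws, ddof=1)) if design.animals > 1 else 0.0
                rows.append(
                    dict(
                        material=material,
                        variable=var,
                        time_days=float(tv),
                        median=float(np.median(draws)),
                        sd=sd,
                        n=design.animals,
                    )
                )
    df = pd.DataFrame(rows, columns=list(StudyDataset._COLUMNS))
    provenance = {
        "study_id": design.study_id,
        "seed": int(seed),
        "cv": design.cv,
        "lattice_sd": design.lattice_sd,
        "animals": design.animals,
        "H0": design.H0,
        "synthetic": True,
    }
    return StudyDataset(df, provenance)


def fixture_bundle(study_id: str, out_dir, seed: int = 7) -> "StudyDataset":
    """Write a frozen-seed synthetic dataset CSV for the given study design."""
    from pathlib import Path

    if study_id == "study1":
        design, truth = study1_design(), default_truth()
    else:
        design, truth = study2_design(), study2_truth()
    ds = generate_study(design, truth, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.to_csv(out / f"synthetic_{study_id}_seed{seed}.csv")
    return ds
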