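"""Run configuration schema and reproducibility manifests.

A ``RunConfig`` is validated strictly (unknown keys rejected) before any
computation starts; every CLI run writes a manifest recording the config
hash, the seed and the package version next to its outputs, so any output
file can be traced back to the exact settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .optim import OptimizerConfig
from .calibration import WorkflowConfig


class RunConfig(BaseModel):
    """Validated settings for a calibration run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_starts: int = Field(10, ge=1)
    n_starts_refit: int = Field(1, ge=1)
    max_iter: int = Field(500, ge=1)
    sigma0: float = Field(0.25, gt=0, le=1)
    ftol: float = Field(1e-10, gt=0)
    degradation_model: str = "surface_rate"
    H0: float = Field(0.0, ge=0)
    artificial_point_t: float = Field(3.0, ge=0)
    use_artificial_point: bool = True
    lambda_k: float = Field(0.001, ge=0)
    lambda_v: float = Field(0.01, ge=0)
    rtol: float = Field(1e-6, gt=0)
    atol: float = Field(1e-9, gt=0)
    refit_lattice_per_material: bool = False
    inhibitor_removal: str = "mature_matrix"

    def to_workflow(self, seed: int | None = None) -> WorkflowConfig:
        return WorkflowConfig(
            seed=self.seed if seed is None else seed,
            n_starts=self.n_starts,
            n_starts_refit=self.n_starts_refit,
            optimizer=OptimizerConfig(sigma0=self.sigma0, max_iter=self.max_iter,
                                      ftol=self.ftol),
            degradation_model=self.degradation_model,
            H0=self.H0,
            artificial_point_t=self.artificial_point_t,
            use_artificial_point=self.use_artificial_point,
            lambda_k=self.lambda_k,
            lambda_v=self.lambda_v,
            rtol=self.rtol,
            atol=self.atol,
            refit_lattice_per_material=self.refit_lattice_per_material,
            inhibitor_removal=self.inhibitor_removal,
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


def config_hash(payload: dict) -> str:
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_manifest(out_dir, command: str, payload: dict, seed: int | None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config_hash": config_hash(payload),
        "config": payload,
        "seed": seed,
        "version": __version__,
    }
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
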