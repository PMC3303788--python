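"""Run configuration, YAML round-tripping and run records.

A RunConfig is a flat, human-editable key set covering the reference
dose-response curves, the dose grid, the simulation constants and the
optimizer settings.  Defaults reproduce the reference study conditions
(alpha = 2.0, gamma = 0.2, dt = 1, t_end = 200, 10,000 cells, 34 doses,
activity map {0, 1, 10}, noise SDs 0.5).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .chain import ChainKind, PromoterState
from .doseresponse import ReferenceCurves
from .estimation import default_dox_grid
from .simulate import SimulationConfig

__all__ = ["RunConfig", "write_run_record", "OUTPUT_SCHEMAS"]

# Fixed column headers of every CSV the package writes.
OUTPUT_SCHEMAS = {
    "switching_model": ["function", "parameter", "value"],
    "population": ["dox", "cell_index", "X_final"],
    "population_summary": ["dox", "mean_X", "sd_X"],
    "dose_response": ["dox", "mean_X", "sd_X", "norm_mean"],
    "ensemble_trace": ["cycle", "mean_X", "sd_X"],
    "prediction_report": ["quantity", "value", "se"],
}


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration of a pipeline run; YAML round-trips losslessly."""

    chain: str = ChainKind.COMPETING_3STATE.value
    # reference (observed) single-factor Hill curves
    H_act: float = 1.6
    K_act: float = 0.6
    H_rep: float = 1.8
    K_rep: float = 0.6
    # dose grid
    n_doses: int = 34
    dox_min: float = 0.01
    dox_max: float = 10.0
    include_zero: bool = True
    # simulation constants
    alpha: float = 2.0
    gamma: float = 0.2
    dt: float = 1.0
    t_end: int = 200
    n_cells: int = 10_000
    deg_noise_sd: float = 0.5
    bl_noise_sd: float = 0.5
    activity_repressor_bound: float = 0.0
    activity_unbound: float = 1.0
    activity_activator_bound: float = 10.0
    update_mode: str = "two_jump"
    # optimizer
    budget: int = 50_000
    seed: int = 0
    outdir: str = "mcmgene_out"

    # ---- derived objects -------------------------------------------------
    def chain_kind(self) -> ChainKind:
        return ChainKind(self.chain)

    def reference(self) -> ReferenceCurves:
        return ReferenceCurves(H_act=self.H_act, K_act=self.K_act,
                               H_rep=self.H_rep, K_rep=self.K_rep)

    def dox_grid(self) -> np.ndarray:
        return default_dox_grid(self.n_doses, self.dox_min, self.dox_max,
                                self.include_zero)

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(
            alpha=self.alpha, gamma=self.gamma, dt=self.dt, t_end=self.t_end,
            n_cells=self.n_cells, deg_noise_sd=self.deg_noise_sd,
            bl_noise_sd=self.bl_noise_sd,
            activity_map={
                PromoterState.REPRESSOR_BOUND: self.activity_repressor_bound,
                PromoterState.UNBOUND: self.activity_unbound,
                PromoterState.ACTIVATOR_BOUND: self.activity_activator_bound,
            },
            update_mode=self.update_mode, seed=self.seed,
        )

    # ---- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"configuration file {path} is not a mapping")
        return cls.from_dict(data)

    def departures_from_defaults(self) -> dict:
        """Keys whose values differ from the reference study conditions."""
        ref = RunConfig()
        skip = {"chain", "seed", "outdir", "budget"}
        return {f.name: getattr(self, f.name)
                for f in dataclasses.fields(self)
                if f.name not in skip
                and getattr(self, f.name) != getattr(ref, f.name)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_run_record(outdir, config: RunConfig, seeds: dict,
                     output_files: list, flags: dict | None = None) -> Path:
    """Write a JSON run record: config snapshot, seeds, version, timestamp
    and a checksummed manifest of every output file."""
    from . import __version__

    outdir = Path(outdir)
    manifest = {Path(f).name: _sha256(Path(f)) for f in output_files}
    record = {
        "config": config.to_dict(),
        "seeds": seeds,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "manifest": manifest,
    }
    if flags:
        record["flags"] = flags
    path = outdir / "run_record.json"
    path.write_text(json.dumps(record, indent=2))
    return path
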