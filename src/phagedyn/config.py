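"""Run configuration: every threshold and constant of the workflow in one
place, loadable from a flat YAML file with CLI overrides on top.

Defaults reproduce the standard study conditions: the 5x5x5 parameter
grid, linkage cut 0.16, lysogen growth ratios 0.7, E0 = 0.02, MOI = 2e-4,
lowess window 0.1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .clustering import DEFAULT_LINKAGE_CUT
from .curves import DEFAULT_WINDOW_FRAC
from .model import DEFAULT_E0, DEFAULT_MOI, DEFAULT_N_OUT, DEFAULT_TAU_END
from .study import (
    CLEARANCE_FRACTION,
    DEFAULT_B_VALUES,
    DEFAULT_F_VALUES,
    DEFAULT_KI_VALUES,
    NO_EFFECT_THRESHOLD,
)


@dataclass
class RunConfig:
    # model
    k_i: float = 1.0          # dimensionless group k_i K / mu
    b: float = 28.0
    f: float = 0.75
    mu_ratio: float = 0.7
    K_ratio: float = 0.7
    sigma: float = 0.0
    moi: float = DEFAULT_MOI
    E0: float = DEFAULT_E0
    tau_end: float = DEFAULT_TAU_END
    n_out: int = DEFAULT_N_OUT
    # grid
    k_i_values: tuple = DEFAULT_KI_VALUES
    f_values: tuple = DEFAULT_F_VALUES
    b_values: tuple = DEFAULT_B_VALUES
    # pipeline thresholds
    linkage_cut: float = DEFAULT_LINKAGE_CUT
    window_frac: float = DEFAULT_WINDOW_FRAC
    none_threshold: float = NO_EFFECT_THRESHOLD
    clearance_fraction: float = CLEARANCE_FRACTION
    n_profile_grid: int = 100
    # generator / reproducibility
    seed: int = 0
    verbose: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict({**data, **overrides})

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("k_i_values", "f_values", "b_values"):
            if key in kwargs:
                kwargs[key] = tuple(float(v) for v in kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("k_i_values", "f_values", "b_values"):
            d[key] = list(d[key])
        return d

    def write_provenance(self, outdir: str | Path, command: str) -> Path:
        """Record the exact configuration and seed that produced a run's
        outputs, sufficient to reproduce them."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / f"{command}_provenance.json"
        path.write_text(json.dumps(
            {"command": command, "config": self.to_dict()}, indent=2,
        ) + "\n")
        return path
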