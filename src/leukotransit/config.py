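"""Layered run configuration for the full study pipeline.

A :class:`RunConfig` bundles everything needed to reproduce a study run:
physical parameters, sweep grid, exclusion mode, table options, per-target
network specifications and seeds.  Configurations are plain data — fully
serializable to YAML — and every artifact the pipeline writes embeds the
configuration hash, so a run can be traced back to its exact settings.

Three named profiles ship with the package:

* ``default`` — the study's physical parameters on the literal 11 x 10
  (Re, AR) grid at production resolution (12 grid cells per cell diameter).
* ``paper-compat`` — adds the AR = 1.0 column (11 x 11 = 121 cases, whose
  count minus the six canonical impaction pairs is 115) and uses the
  canonical exclusion list instead of detected outcomes.
* ``coarse-ci`` — desk-scale protocol: 6 x 6 grid, 8 cells per diameter,
  shorter cutoff time; a full sweep plus all four trainings runs on one
  CPU in minutes.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bpnn import NetworkSpec
from .fsi_sim import SimulationParams
from .sweep_dataset import (
    PAPER_COMPAT_AR_VALUES,
    STUDY_AR_VALUES,
    STUDY_RE_VALUES,
    build_grid,
)

__all__ = ["RunConfig", "load_config", "PROFILES", "network_spec_for", "TARGET_NAMES"]

# surrogate targets: short CLI name -> table target column
TARGET_NAMES = {
    "time": "transit_time",
    "rmax": "R_max",
    "vy": "V_y",
    "lift": "F_l",
    "drag": "F_d",
}

# per-target network settings: hidden sizes sized by the combinatorial
# node-count rule (15 -> (5, 10) for the 2-input time model, 50 -> (20, 30)
# for the 3-input motion models), training goals per target
_NETWORK_DEFAULTS = {
    "time": dict(layer_sizes=[2, 5, 10, 1], goal=1e-5),
    "rmax": dict(layer_sizes=[3, 20, 30, 1], goal=1e-3),
    "vy": dict(layer_sizes=[3, 20, 30, 1], goal=1e-10),
    "lift": dict(layer_sizes=[3, 20, 30, 1], goal=1e-13, min_grad=1e-10),
    "drag": dict(layer_sizes=[3, 20, 30, 1], goal=1e-14, min_grad=1e-12),
}

_COMMON_NET = dict(
    hidden_activation="tansig",
    output_activation="purelin",
    trainer="trainlm",
    learning_rate=0.03,
    max_epochs=1000,
    max_fail=6,
)


@dataclass
class RunConfig:
    """Complete, hashable description of one study run."""

    profile: str = "default"
    re_values: tuple = STUDY_RE_VALUES
    ar_values: tuple = STUDY_AR_VALUES
    exclusion_mode: str = "detected"  # or "canonical"
    physical: dict = field(default_factory=dict)  # SimulationParams overrides
    split_fractions: tuple = (0.6, 0.2, 0.2)
    networks: dict = field(default_factory=dict)  # per-target NetworkSpec overrides
    seed: int = 0
    output_dir: str = "runs"

    def __post_init__(self) -> None:
        if self.exclusion_mode not in ("detected", "canonical"):
            raise ValueError(f"unknown exclusion_mode {self.exclusion_mode!r}")
        self.re_values = tuple(float(v) for v in self.re_values)
        self.ar_values = tuple(float(v) for v in self.ar_values)
        self.split_fractions = tuple(float(f) for f in self.split_fractions)

    # -- derived ------------------------------------------------------------

    def grid(self):
        return build_grid(self.re_values, self.ar_values)

    def sim_params(self, Re: float, AR: float) -> SimulationParams:
        return SimulationParams(Re=Re, AR=AR, seed=self.seed, **self.physical)

    def network_spec(self, target: str, seed: int | None = None) -> NetworkSpec:
        return network_spec_for(target, overrides=self.networks.get(target), seed=seed)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "profile": self.profile,
            "re_values": list(self.re_values),
            "ar_values": list(self.ar_values),
            "exclusion_mode": self.exclusion_mode,
            "physical": dict(self.physical),
            "split_fractions": list(self.split_fractions),
            "networks": {k: dict(v) for k, v in self.networks.items()},
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    def hash(self) -> str:
        """Short hash of the canonical serialization (provenance tag)."""
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def with_overrides(self, **kw) -> "RunConfig":
        d = self.to_dict()
        for k, v in kw.items():
            if v is None:
                continue
            if k in ("physical", "networks"):
                d[k] = {**d[k], **v}
            else:
                d[k] = v
        return RunConfig(**d)


def network_spec_for(target: str, overrides: dict | None = None, seed: int | None = None) -> NetworkSpec:
    """NetworkSpec for one surrogate target with optional overrides."""
    if target not in _NETWORK_DEFAULTS:
        raise ValueError(f"unknown target {target!r}; expected one of {sorted(_NETWORK_DEFAULTS)}")
    kw = {**_COMMON_NET, **_NETWORK_DEFAULTS[target]}
    kw["layer_sizes"] = list(kw["layer_sizes"])
    if overrides:
        kw.update(overrides)
    if seed is not None:
        kw["seed"] = seed
    return NetworkSpec(**kw)


def _coarse_ci() -> RunConfig:
    import numpy as np

    return RunConfig(
        profile="coarse-ci",
        re_values=tuple(round(v, 3) for v in np.linspace(0.1, 0.2, 6)),
        ar_values=tuple(round(v, 3) for v in np.linspace(0.5, 0.95, 6)),
        physical={
            "grid_cells_per_diameter": 8,
            "max_sim_time": 0.25,
            "output_interval": 2e-4,
        },
    )


PROFILES = {
    "default": lambda: RunConfig(profile="default"),
    "paper-compat": lambda: RunConfig(
        profile="paper-compat",
        ar_values=PAPER_COMPAT_AR_VALUES,
        exclusion_mode="canonical",
    ),
    "coarse-ci": _coarse_ci,
}


def load_config(path=None, profile: str = "default", **overrides) -> RunConfig:
    """Layered configuration: profile defaults < YAML file < overrides."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {sorted(PROFILES)}")
    cfg = PROFILES[profile]()
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        base = cfg.to_dict()
        for k, v in data.items():
            if k not in base:
                raise ValueError(f"unknown config key {k!r} in {path}")
            if k in ("physical", "networks"):
                base[k] = {**base[k], **v}
            else:
                base[k] = v
        cfg = RunConfig(**base)
    if overrides:
        cfg = cfg.with_overrides(**overrides)
    return cfg
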