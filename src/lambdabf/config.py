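"""Run configuration: YAML schema, validation and canonical hashing.

Every stochastic stage carries an explicit seed; the canonical config
hash (order-independent) is stamped into output manifests so any result
file can be traced back to the exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FixtureSpec(_Strict):
    kind: str = "host_guest"            # host_guest | mini_complex | two_particle
    seed: int
    n_site: int = 8
    arm_length: int = 3
    guest_charge: int = 2
    add_counterions: bool = False


class LangevinSpec(_Strict):
    temperature: float = 300.0
    friction: float = 2.0
    timestep: float = 1.0
    n_steps: int = 10000
    seed: int
    save_stride: int = 10


class RestraintSpec(_Strict):
    dbc_r0: float = 1.0
    dbc_k: float = 100.0
    positional_k: float = 1.0


class LegSpec(_Strict):
    phase: str                          # complex | solvent
    leg: str                            # ELE | VDW
    n_walkers: int = 4
    n_bins: int = 100
    n_full: int = 200
    sync_interval: int = 500
    dynamics: LangevinSpec


class OpesSpec(_Strict):
    sigma: float
    barrier: float
    pace: int = 500
    seed: int
    dynamics: LangevinSpec


class DeepLdaSpec(_Strict):
    hidden: list[int] = Field(default_factory=lambda: [24, 12])
    epochs: int = 500
    seed: int
    regularization: float | None = None


class CalibrationSpec(_Strict):
    dataset: str | None = None          # None -> embedded dataset
    include_ids: list[int] | None = None


class RunConfig(_Strict):
    fixture: FixtureSpec | None = None
    legs: list[LegSpec] = Field(default_factory=list)
    restraints: RestraintSpec | None = None
    opes: OpesSpec | None = None
    deep_lda: DeepLdaSpec | None = None
    calibration: CalibrationSpec | None = None
    output_dir: str = "runs"


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Unknown keys are rejected with their location; every stochastic
    stage must carry a seed (enforced by the schema: seeds have no
    default).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        locs = "; ".join(
            "->".join(str(x) for x in e["loc"]) + f": {e['msg']}"
            for e in err.errors())
        raise ConfigError(f"invalid config {path}: {locs}") from err


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    """Canonical (key-order-independent) SHA-256 of the configuration."""
    canon = json.dumps(config.model_dump(), sort_keys=True,
                       separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
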