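"""Run configuration: schema, defaults, YAML/JSON loading."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
import hashlib
import json
from pathlib import Path

import yaml

from .dose import BeamModel
from .objective import ObjectiveTerm
from .optimizer import GAParams
from .phantom import Phantom, reference_phantom


class ConfigError(ValueError):
    """A configuration file violates the schema."""


def default_objective_terms(prescription: float = 50.0) -> list[ObjectiveTerm]:
    """Planning goals for the reference case: uniform target coverage at
    prescription, sparing of the 10 mm ring, brainstem, healthy brain and
    skin.  Penalty weights are per-structure-mean quadratic weights."""
    return [
        ObjectiveTerm("target", d_under=prescription, beta_under=100.0,
                      d_over=1.05 * prescription, beta_over=100.0),
        ObjectiveTerm("ring10mm", d_over=0.5 * prescription, beta_over=10.0),
        ObjectiveTerm("brainstem", d_over=0.4 * prescription, beta_over=10.0),
        ObjectiveTerm("brain", d_over=0.3 * prescription, beta_over=2.0),
        ObjectiveTerm("skin", d_over=0.4 * prescription, beta_over=2.0),
    ]


@dataclass
class RunConfig:
    """Validated plan-run configuration with defaults filled in.

    The reference arc starts at the patient's lateral right (-90 deg) and
    wraps 140 deg posteriorly.
    """

    phantom: str = "reference"
    arc_start: float = -90.0
    arc_stop: float = -230.0
    stages: int = 5
    spot_pitch: float = 4.0
    layer_spacing: float = 0.5
    prescription: float = 50.0
    normalization_level: float = 95.0
    collimated: bool = False
    seed: int = 0
    output_dir: str = "."
    ga: GAParams = field(default_factory=GAParams)
    beam_model: BeamModel = field(default_factory=BeamModel)
    objectives: list[ObjectiveTerm] | None = None

    def __post_init__(self) -> None:
        if self.spot_pitch <= 0:
            raise ConfigError("spot_pitch must be positive")
        if self.layer_spacing <= 0:
            raise ConfigError("layer_spacing must be positive")
        if self.prescription <= 0:
            raise ConfigError("prescription must be positive")
        if not (0 < self.normalization_level <= 100):
            raise ConfigError("normalization_level must lie in (0, 100]")
        if self.stages < 1:
            raise ConfigError("stages must be >= 1")
        self.ga.stages = self.stages
        self.ga.validate()
        if self.objectives is None:
            self.objectives = default_objective_terms(self.prescription)

    def build_phantom(self) -> Phantom:
        if self.phantom == "reference":
            return reference_phantom()
        raise ConfigError(f"unknown phantom {self.phantom!r} "
                          "(only 'reference' is built in; pass a Phantom "
                          "object through the library API for custom cases)")

    def to_dict(self) -> dict:
        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [plain(v) for v in x]
            return x
        return plain(asdict(self))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str)
            .encode()).hexdigest()[:12]


_NESTED = {"ga": GAParams, "beam_model": BeamModel}


def _build(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {path}")
    kwargs = {}
    for k, v in data.items():
        if k in _NESTED and isinstance(v, dict):
            kwargs[k] = _build(_NESTED[k], v, f"{path}.{k}")
        elif k == "objectives" and v is not None:
            kwargs[k] = [_build_term(t, f"{path}.objectives[{i}]")
                         for i, t in enumerate(v)]
        else:
            kwargs[k] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{path}: {e}") from e


def _build_term(data: dict, path: str) -> ObjectiveTerm:
    allowed = {f.name for f in fields(ObjectiveTerm)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {path}")
    try:
        return ObjectiveTerm(**data)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{path}: {e}") from e


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    return _build(RunConfig, data, "config")


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
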