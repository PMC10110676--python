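"""Declarative run configuration for the command-line interface.

A single YAML document holds every tunable parameter of the pipeline, with
strict schema validation (unknown keys are rejected).  Defaults are the
study-design values: probe 1.4 Å, monomer window ±0.5 kcal/mol, complex
threshold 2 kcal/mol, 5 Å anchor distance, 20 Å docking restraint,
10 replicates, 29 controls, the 24-probe ISG panel.
"""

from __future__ import annotations

import hashlib
import json

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigError

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SasaSection(_Strict):
    probe_radius: float = 1.4
    points_per_atom: int = 960


class InterfaceSection(_Strict):
    min_delta: float = 1.0


class RulesSection(_Strict):
    monomer_window: tuple[float, float] = (-0.5, 0.5)
    full_threshold: float = 2.0
    anchor_max_distance: float = 5.0
    require_all_anchors: bool = False


class RestraintSection(_Strict):
    max_distance: float = 20.0
    ca_only: bool = False


class SignatureSection(_Strict):
    sd_mode: str = "sd"  # or "sem"
    baseline: str = "median"  # or "mean"


class SimulateSection(_Strict):
    n_controls: int = 29
    case_elevation: float = 10.0
    n_replicates: int = 10


class RunConfig(_Strict):
    sasa: SasaSection = SasaSection()
    interface: InterfaceSection = InterfaceSection()
    rules: RulesSection = RulesSection()
    restraint: RestraintSection = RestraintSection()
    signature: SignatureSection = SignatureSection()
    simulate: SimulateSection = SimulateSection()
    seed: int = 0
    verbosity: int = 0

    def digest(self) -> str:
        """Stable hash of the full configuration, for the run log."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path=None, **overrides) -> RunConfig:
    """Load (or default) a RunConfig; unknown keys raise ``ConfigError``."""
    data: dict = {}
    if path is not None:
        try:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must be a mapping")
    data.update(overrides)
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
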