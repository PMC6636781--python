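"""Run configuration: plain-text (YAML) key-value files, strict validation.

Unknown keys are rejected (fail-fast), out-of-range values raise a
configuration error naming the key, and a fully resolved configuration can be
echoed back into the output directory for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .core import InvalidParameterError
from .lattice import SimulationParams
from .scenarios import SCENARIO_IDS, ScenarioConfig, scenario_config


class ConfigError(ValueError):
    """Malformed or out-of-range run configuration."""


_SCENARIO_KEYS = {f.name for f in dataclasses.fields(ScenarioConfig)} - {
    "scenario_id",
    "params",
}
_PARAM_KEYS = {f.name for f in dataclasses.fields(SimulationParams)}


@dataclass(frozen=True)
class RunConfig:
    """A complete, validated run request."""

    scenario: str = "S1_temperate_GT"
    seed: int = 0
    replicates: int = 1
    output_dir: Optional[str] = None
    verbosity: int = 1
    overrides: dict = field(default_factory=dict)  # ScenarioConfig fields
    params: dict = field(default_factory=dict)  # SimulationParams fields

    def resolved(self) -> ScenarioConfig:
        """Merge defaults and overrides into the scenario configuration."""
        sim_params = SimulationParams(**self.params)
        return scenario_config(self.scenario, params=sim_params, **self.overrides)

    def to_mapping(self) -> dict:
        return {
            "scenario": self.scenario,
            "seed": self.seed,
            "replicates": self.replicates,
            "output_dir": self.output_dir,
            "verbosity": self.verbosity,
            "overrides": dict(self.overrides),
            "params": dict(self.params),
        }


def _validate(raw: Mapping[str, Any]) -> RunConfig:
    known_top = {
        "scenario",
        "seed",
        "replicates",
        "output_dir",
        "verbosity",
        "overrides",
        "params",
    }
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    scenario = raw.get("scenario", "S1_temperate_GT")
    if scenario not in SCENARIO_IDS:
        raise ConfigError(
            f"unknown scenario {scenario!r}; choose from {SCENARIO_IDS}"
        )
    overrides = dict(raw.get("overrides") or {})
    bad = set(overrides) - _SCENARIO_KEYS
    if bad:
        raise ConfigError(f"unknown scenario override key(s): {sorted(bad)}")
    params = dict(raw.get("params") or {})
    bad = set(params) - _PARAM_KEYS
    if bad:
        raise ConfigError(f"unknown simulation parameter key(s): {sorted(bad)}")
    cfg = RunConfig(
        scenario=scenario,
        seed=int(raw.get("seed", 0)),
        replicates=int(raw.get("replicates", 1)),
        output_dir=raw.get("output_dir"),
        verbosity=int(raw.get("verbosity", 1)),
        overrides=overrides,
        params=params,
    )
    # range-check by constructing the resolved objects; re-raise naming the key
    try:
        cfg.resolved().genotype()
    except (InvalidParameterError, TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.  An empty file yields all
    defaults; unknown keys and out-of-range values raise :class:`ConfigError`
    naming the offending key."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed configuration file {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"configuration root must be a mapping, got {type(raw)}")
    return _validate(raw)


def write_config(config: RunConfig, path: str | Path) -> None:
    """Echo a resolved configuration (round-trips through load_config)."""
    Path(path).write_text(yaml.safe_dump(config.to_mapping(), sort_keys=False))
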