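"""Scenario configuration: YAML loading, validation and bundled presets.

A configuration file has four sections — ``agent``, ``tissue``,
``target``, ``regimen`` — plus an optional ``cold_agent``.  Every
quantity key carries an explicit unit suffix (``_h`` hours, ``_um``
micrometers, ``_m`` molar, ``_cm_s`` cm/s, ...) matching the dataclass
field names, so a malformed or unknown key is rejected with its path.

Bundled presets (see :data:`PRESETS`) encode the default tumor and
muscle scenarios; each preset file documents which numbers are
literature-anchored and which are package calibration defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import yaml

from .dosing import DoseRegimen, make_regimen
from .params import AgentSpec, Scenario, TargetSpec, TissueSpec, canonical_dict

_SECTION_TYPES = {
    "agent": AgentSpec,
    "tissue": TissueSpec,
    "target": TargetSpec,
    "cold_agent": AgentSpec,
}

_REGIMEN_KEYS = {"pattern", "peak_m", "half_life_h", "interval_h", "n_doses",
                 "cold_offset_h", "cold_peak_m", "half_life_cold_h"}

PRESETS = (
    "tumor_protein_noconv",
    "tumor_protein_conv",
    "tumor_peptide",
    "muscle_protein",
    "tumor_catalytic",
)


class ConfigError(ValueError):
    """A configuration file failed validation."""


def _build_section(name: str, data: dict, cls):
    if not isinstance(data, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {name}: " +
            ", ".join(f"{name}.{k}" for k in sorted(unknown)) +
            " (check unit suffixes)")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {name} section: {exc}") from exc


def _build_regimen(data: dict, agent: AgentSpec) -> DoseRegimen:
    if not isinstance(data, dict):
        raise ConfigError("section 'regimen' must be a mapping")
    unknown = set(data) - _REGIMEN_KEYS
    if unknown:
        raise ConfigError("unknown key(s) in regimen: " +
                          ", ".join(f"regimen.{k}" for k in sorted(unknown)))
    data = dict(data)
    data.setdefault("half_life_h", agent.plasma_half_life_h)
    try:
        return make_regimen(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid regimen section: {exc}") from exc


def scenario_from_dict(doc: dict) -> Scenario:
    """Validate a configuration mapping and assemble a Scenario."""
    if not isinstance(doc, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(doc) - set(_SECTION_TYPES) - {"regimen"}
    if unknown:
        raise ConfigError("unknown section(s): " + ", ".join(sorted(unknown)))
    agent = _build_section("agent", doc.get("agent", {}), AgentSpec)
    tissue = _build_section("tissue", doc.get("tissue", {}), TissueSpec)
    target = _build_section("target", doc.get("target", {}), TargetSpec)
    regimen = _build_regimen(doc.get("regimen", {}), agent)
    cold = None
    if "cold_agent" in doc:
        cold = _build_section("cold_agent", doc["cold_agent"], AgentSpec)
    return Scenario(agent=agent, tissue=tissue, target=target,
                    regimen=regimen, cold_agent=cold)


def load_config(path: str | Path) -> Scenario:
    """Load and validate a scenario configuration file."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return scenario_from_dict(doc or {})


def load_preset(name: str) -> Scenario:
    """Load one of the bundled scenario presets by name."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(PRESETS)}")
    ref = resources.files("cytodel").joinpath(f"presets/{name}.yaml")
    doc = yaml.safe_load(ref.read_text())
    return scenario_from_dict(doc)


def dump_config(scenario: Scenario) -> str:
    """Serialize a scenario to canonical YAML (round-trips through
    :func:`load_config`)."""
    doc: dict = {
        "agent": canonical_dict(scenario.agent),
        "tissue": canonical_dict(scenario.tissue),
        "target": canonical_dict(scenario.target),
        "regimen": _regimen_to_dict(scenario.regimen),
    }
    if scenario.cold_agent is not None:
        doc["cold_agent"] = canonical_dict(scenario.cold_agent)
    return yaml.safe_dump(doc, sort_keys=True)


def _regimen_to_dict(regimen: DoseRegimen) -> dict:
    from .dosing import DoseSpecies

    warm = regimen.events_for(DoseSpecies.WARM)
    cold = regimen.events_for(DoseSpecies.COLD)
    out: dict = {"half_life_h": regimen.half_life_warm_h,
                 "peak_m": warm[0].peak_plasma_concentration_m if warm else 0.0,
                 "n_doses": len(warm)}
    if len(warm) > 1:
        out["pattern"] = "repeated"
        out["interval_h"] = warm[1].time_h - warm[0].time_h
    else:
        out["pattern"] = "single"
    if cold:
        out["cold_offset_h"] = cold[0].time_h - (warm[0].time_h if warm else 0.0)
        out["cold_peak_m"] = cold[0].peak_plasma_concentration_m
    return out


@dataclass(frozen=True)
class RunManifest:
    """Provenance record of one run: resolved parameters, software
    version and a content hash.  Re-running from the manifest's
    parameters reproduces outputs deterministically."""

    parameters: dict
    version: str
    config_hash: str
    created_at: str

    @classmethod
    def for_scenario(cls, scenario: Scenario, **extra) -> "RunManifest":
        from . import __version__

        params = {"scenario": canonical_dict(scenario), **extra}
        digest = hashlib.sha256(
            json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()
        return cls(parameters=params, version=__version__, config_hash=digest,
                   created_at=datetime.now(timezone.utc).isoformat())

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=str)
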