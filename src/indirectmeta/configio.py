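"""Load and dump scenario configurations as YAML or JSON.

A scenario file is either a single mapping of :class:`ScenarioConfig`
fields, a list of such mappings, or a mapping with a ``scenarios`` list.
Unknown keys are rejected so that typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .trial_simulator import ScenarioConfig

__all__ = ["load_scenarios", "dump_scenarios", "scenario_from_dict"]

_FIELDS = {f.name for f in dataclasses.fields(ScenarioConfig)}


def scenario_from_dict(raw: dict) -> ScenarioConfig:
    unknown = set(raw) - _FIELDS
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    if "n_total_range" in raw:
        raw = dict(raw, n_total_range=tuple(raw["n_total_range"]))
    return ScenarioConfig(**raw)


def load_scenarios(path: str | Path) -> list[ScenarioConfig]:
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if isinstance(data, dict) and "scenarios" in data:
        data = data["scenarios"]
    if isinstance(data, dict):
        data = [data]
    if not isinstance(data, list) or not data:
        raise ValueError(f"{path}: expected one scenario mapping or a list of them")
    return [scenario_from_dict(d) for d in data]


def dump_scenarios(scenarios, path: str | Path) -> None:
    payload = [dataclasses.asdict(s) for s in scenarios]
    for d in payload:
        d["n_total_range"] = list(d["n_total_range"])
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps({"scenarios": payload}, indent=2))
    else:
        path.write_text(yaml.safe_dump({"scenarios": payload}, sort_keys=False))
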