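"""Load experiment configurations from YAML or JSON files.

Schema (all keys optional; omitted keys fall back to package defaults)::

    simulation:
      n_applicants: 1000000
      k_latents: 4
      seed: 1
      sufficiency_mean: -1.0
      sufficiency_sd: 1.0
    scenarios:                  # names, or full scenario mappings
      - invalid_test
      - name: my_scenario
        loadings:
          Test:      [1, 0, 0, 0]
          Grades:    [0.58, 0.71, 0.41, 0]
          Letters:   [0, 0.41, 0.71, 0.58]
          Statement: [0, 0, 0, 1]
        invalid: [Test]
        noise_sd: 1.0
        test_weight: 1.0
    policies:                   # omit for the canonical three columns
      - {type: weighted_sum, weights: {Test: 1, Grades: 1, Letters: 1,
         Statement: 1}, fraction: 0.10}
    acceptance_fraction: 0.10
    sweep_fractions: [1.0, 0.95, ...]
    sweep_n_applicants: 200000
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .admissions import AdmissionsPolicy
from .errors import ConfigurationError
from .experiments import ExperimentConfig
from .population import SimulationConfig
from .predictors import DEFAULT_PREDICTORS, FactorLoadings, GroundTruthScenario

__all__ = ["load_config", "parse_config", "parse_scenario"]


def load_config(path) -> ExperimentConfig:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError("config file must contain a mapping")
    return parse_config(data)


def parse_scenario(entry) -> GroundTruthScenario:
    if isinstance(entry, str):
        return GroundTruthScenario.from_name(entry)
    if not isinstance(entry, dict):
        raise ConfigurationError(f"bad scenario entry: {entry!r}")
    name = entry.get("name", "custom")
    if "loadings" in entry:
        rows = entry["loadings"]
        names = tuple(rows.keys()) if isinstance(rows, dict) else DEFAULT_PREDICTORS
        matrix = np.array(
            [rows[p] for p in names] if isinstance(rows, dict) else rows, dtype=float
        )
        loadings = FactorLoadings(matrix, names)
    else:
        loadings = FactorLoadings.identity()
    return GroundTruthScenario(
        name=name,
        loadings=loadings,
        invalid_predictors=frozenset(entry.get("invalid", ())),
        noise_sd=float(entry.get("noise_sd", 1.0)),
        default_test_weight=float(entry.get("test_weight", 1.0)),
    )


def _parse_policy(entry: dict) -> AdmissionsPolicy:
    return AdmissionsPolicy(
        policy_type=entry.get("type", "weighted_sum"),
        weights=dict(entry.get("weights", {})),
        acceptance_fraction=float(entry.get("fraction", 1.0)),
        test_cutoff=entry.get("test_cutoff"),
        name=entry.get("name"),
    )


def parse_config(data: dict) -> ExperimentConfig:
    sim = SimulationConfig(**data.get("simulation", {}))
    kwargs: dict = {"simulation": sim}
    if "scenarios" in data:
        kwargs["scenarios"] = tuple(parse_scenario(s) for s in data["scenarios"])
    if data.get("policies") not in (None, "default"):
        kwargs["policies"] = tuple(_parse_policy(p) for p in data["policies"])
    if "acceptance_fraction" in data:
        kwargs["acceptance_fraction"] = float(data["acceptance_fraction"])
    if "sweep_fractions" in data:
        kwargs["sweep_fractions"] = tuple(float(f) for f in data["sweep_fractions"])
    if "sweep_n_applicants" in data:
        v = data["sweep_n_applicants"]
        kwargs["sweep_n_applicants"] = None if v is None else int(v)
    return ExperimentConfig(**kwargs)
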