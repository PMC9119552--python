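"""End-to-end experiment runners.

Two canonical experiments:

* the **policy grid** — every ground-truth scenario crossed with three
  admissions policies (accept everyone; top-10% on the weighted predictor
  sum including Test; top-10% excluding Test), each cell summarised by a
  :class:`~compsel.metrics.MetricsReport`;
* the **selectivity sweep** — for each scenario, the with-Test policy run
  at acceptance fractions from 100% down to 5% in 5% steps, reporting the
  completion-curve regression slope per point.

Within a scenario every policy (and every sweep fraction) is applied to the
same simulated cohort, so differences between cells reflect the policy alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .admissions import AcceptanceMask, AdmissionsPolicy, apply_policy, composite_score
from .cohort import Cohort, simulate_cohort
from .errors import ConfigurationError
from .metrics import (
    CompletionCurve,
    MetricsReport,
    compute_report,
    regression_slope_with_se,
)
from .population import SimulationConfig
from .predictors import GroundTruthScenario
from .rng import RngStreams

__all__ = [
    "DEFAULT_SCENARIOS",
    "ExperimentConfig",
    "GridCell",
    "GridResult",
    "SweepResult",
    "run_policy_grid",
    "run_selectivity_sweep",
    "write_results",
]

logger = logging.getLogger("compsel")

DEFAULT_SCENARIOS = (
    "invalid_test",
    "valid_uncorrelated",
    "valid_uncorrelated_overweighted",
    "valid_correlated",
)


def default_sweep_fractions() -> tuple[float, ...]:
    """Acceptance fractions 1.00 down to 0.05 in 0.05 steps."""
    return tuple(round(f, 2) for f in np.arange(20, 0, -1) * 0.05)


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of the grid and sweep experiments.

    ``policies=None`` means the canonical three-column set, with the Test
    weight in the with-Test column taken from each scenario's
    ``default_test_weight`` (1.3 for the over-weighted scenario).
    ``sweep_n_applicants`` lets the sweep run on smaller cohorts than the
    grid; None reuses the grid size.
    """

    simulation: SimulationConfig = SimulationConfig()
    scenarios: tuple[GroundTruthScenario, ...] = tuple(
        GroundTruthScenario.from_name(n) for n in DEFAULT_SCENARIOS
    )
    policies: tuple[AdmissionsPolicy, ...] | None = None
    acceptance_fraction: float = 0.10
    sweep_fractions: tuple[float, ...] = field(
        default_factory=default_sweep_fractions
    )
    sweep_n_applicants: int | None = 200_000

    def __post_init__(self) -> None:
        names = [s.name for s in self.scenarios]
        if len(set(names)) != len(names):
            raise ConfigurationError("scenario names must be unique")
        fr = np.asarray(self.sweep_fractions, dtype=float)
        if fr.size and (np.any(fr <= 0) or np.any(fr > 1) or np.any(np.diff(fr) >= 0)):
            raise ConfigurationError(
                "sweep fractions must lie in (0, 1] and be strictly decreasing"
            )

    def policies_for(self, scenario: GroundTruthScenario) -> tuple[AdmissionsPolicy, ...]:
        if self.policies is not None:
            return self.policies
        f = self.acceptance_fraction
        return (
            AdmissionsPolicy.accept_all(),
            AdmissionsPolicy.top_fraction(
                f, test_weight=scenario.default_test_weight, name="with_test"
            ),
            AdmissionsPolicy.top_fraction(f, test_weight=0.0, name="no_test"),
        )


@dataclass(frozen=True)
class GridCell:
    scenario: str
    policy: str
    report: MetricsReport
    curve: CompletionCurve


@dataclass(frozen=True)
class GridResult:
    cells: tuple[GridCell, ...]
    provenance: dict

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {"scenario": c.scenario, "policy": c.policy}
            row.update(c.report.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SweepResult:
    rows: pd.DataFrame  # scenario, fraction, slope, slope_se, + context columns
    provenance: dict

    def to_dataframe(self) -> pd.DataFrame:
        return self.rows


def _provenance(config: ExperimentConfig, n: int) -> dict:
    return {
        "seed": config.simulation.seed,
        "n_applicants": n,
        "version": __version__,
    }


def run_policy_grid(config: ExperimentConfig) -> GridResult:
    """Run every (scenario, policy) cell of the policy grid.

    One cohort per scenario; each policy is applied to that same cohort.
    Deterministic given the root seed.
    """
    cells: list[GridCell] = []
    streams = RngStreams(config.simulation.seed)
    for scenario in config.scenarios:
        t0 = time.perf_counter()
        cohort = simulate_cohort(scenario, config.simulation)
        for policy in config.policies_for(scenario):
            try:
                mask = apply_policy(
                    cohort.panel, policy, streams.stream(f"select:{policy.name}")
                )
                report, curve = compute_report(cohort.panel, mask, cohort.outcomes)
            except Exception as exc:
                raise RuntimeError(
                    f"grid cell ({scenario.name}, {policy.name}) failed"
                ) from exc
            dropped = int((curve.bin_counts > 0).sum() - curve.n_occupied)
            if dropped:
                logger.warning(
                    "cell (%s, %s): %d low-occupancy bins dropped from curve",
                    scenario.name, policy.name, dropped,
                )
            logger.info(
                "cell (%s, %s): n_accepted=%d completion=%.1f%% r=%.3f [%.1fs]",
                scenario.name, policy.name, report.n_accepted,
                report.completion_pct, report.curve_r, time.perf_counter() - t0,
            )
            cells.append(GridCell(scenario.name, policy.name, report, curve))
    return GridResult(tuple(cells), _provenance(config, config.simulation.n_applicants))


def run_selectivity_sweep(config: ExperimentConfig) -> SweepResult:
    """Regression slope of the completion curve vs acceptance fraction.

    Uses the with-Test weighted-sum policy per scenario (fraction 1 degrades
    to accept-all).  The cohort is simulated once per scenario and reused
    across fractions; composite scores are computed once and re-thresholded.
    """
    sim = config.simulation
    if config.sweep_n_applicants is not None:
        sim = SimulationConfig(
            n_applicants=config.sweep_n_applicants,
            k_latents=sim.k_latents,
            seed=sim.seed,
            sufficiency_mean=sim.sufficiency_mean,
            sufficiency_sd=sim.sufficiency_sd,
        )
    rows = []
    for scenario in config.scenarios:
        cohort = simulate_cohort(scenario, sim)
        policy = AdmissionsPolicy.top_fraction(
            0.10, test_weight=scenario.default_test_weight, name="with_test"
        )
        scores = composite_score(cohort.panel, policy.weights)
        order_key = RngStreams(sim.seed).stream("select:sweep").random(sim.n_applicants)
        # rank once; the top-f mask for any fraction is a threshold on this rank
        order = np.lexsort((order_key, scores))
        rank_from_top = np.empty(sim.n_applicants, dtype=np.int64)
        rank_from_top[order[::-1]] = np.arange(sim.n_applicants)
        for fraction in config.sweep_fractions:
            if fraction >= 1.0:
                mask = AcceptanceMask(np.ones(sim.n_applicants, dtype=bool))
            else:
                n_acc = int(np.floor(fraction * sim.n_applicants + 1e-9))
                mask = AcceptanceMask(rank_from_top < n_acc)
            report, curve = compute_report(cohort.panel, mask, cohort.outcomes)
            slope, se = regression_slope_with_se(curve)
            rows.append(
                {
                    "scenario": scenario.name,
                    "fraction": fraction,
                    "slope": 100.0 * slope,  # percent completion per percentile
                    "slope_se": 100.0 * se,
                    "completion_pct": report.completion_pct,
                    "curve_r": report.curve_r,
                    "n_accepted": report.n_accepted,
                }
            )
        logger.info("sweep scenario %s: %d fractions done", scenario.name,
                    len(config.sweep_fractions))
    return SweepResult(pd.DataFrame(rows), _provenance(config, sim.n_applicants))


def _config_hash(provenance: dict) -> str:
    return hashlib.sha256(
        json.dumps(provenance, sort_keys=True).encode()
    ).hexdigest()[:16]


def write_results(result, output_dir, plots: bool = False) -> list[str]:
    """Write CSV + JSON (and optional PNG) artefacts; returns the manifest.

    CSV/JSON contents are pure functions of config and seed (byte-identical
    across reruns); the wall-clock timestamp lives only in the run manifest.
    """
    from pathlib import Path

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    if isinstance(result, GridResult):
        stem = "grid"
        result.to_dataframe().to_csv(out / "grid.csv", index=False)
        written.append("grid.csv")
        payload = {
            "provenance": result.provenance,
            "cells": [
                {
                    "scenario": c.scenario,
                    "policy": c.policy,
                    "report": c.report.to_dict(),
                    "curve": {
                        "bin": c.curve.bin_centers.tolist(),
                        "acceptance_rate": _nanlist(c.curve.acceptance_rate),
                        "completion_rate": _nanlist(c.curve.completion_rate),
                        "count": c.curve.bin_counts.tolist(),
                    },
                }
                for c in result.cells
            ],
        }
        (out / "grid.json").write_text(json.dumps(payload, indent=1))
        written.append("grid.json")
        if plots:
            from .plotting import plot_grid

            plot_grid(result, out / "grid.png")
            written.append("grid.png")
    elif isinstance(result, SweepResult):
        stem = "sweep"
        result.rows.to_csv(out / "sweep.csv", index=False)
        written.append("sweep.csv")
        payload = {
            "provenance": result.provenance,
            "rows": result.rows.to_dict(orient="records"),
        }
        (out / "sweep.json").write_text(json.dumps(payload, indent=1))
        written.append("sweep.json")
        if plots:
            from .plotting import plot_sweep

            plot_sweep(result, out / "sweep.png")
            written.append("sweep.png")
    else:
        raise TypeError(f"cannot write result of type {type(result).__name__}")

    manifest = {
        "experiment": stem,
        "files": written,
        "provenance": result.provenance,
        "config_hash": _config_hash(result.provenance),
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    (out / f"{stem}_manifest.json").write_text(json.dumps(manifest, indent=1))
    written.append(f"{stem}_manifest.json")
    return written


def _nanlist(a: np.ndarray) -> list:
    return [None if np.isnan(x) else float(x) for x in a]
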