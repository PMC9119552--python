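"""Assemble a full simulated cohort: latents, outcomes, and predictor panel.

A cohort is the unit the experiments operate on.  Outcomes depend only on the
latents and the outcome substream, so two scenarios simulated under the same
seed share identical applicants and completion outcomes and differ only in
what the application paperwork reveals about them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .population import (
    CompletionOutcomes,
    LatentMatrix,
    SimulationConfig,
    completion_probabilities,
    sample_latents,
    sample_outcomes,
)
from .predictors import GroundTruthScenario, PredictorPanel, build_predictors
from .rng import RngStreams

__all__ = ["Cohort", "simulate_cohort"]


@dataclass(frozen=True)
class Cohort:
    config: SimulationConfig
    scenario: GroundTruthScenario
    latents: LatentMatrix
    outcomes: CompletionOutcomes
    panel: PredictorPanel

    @property
    def n(self) -> int:
        return self.config.n_applicants


def simulate_cohort(
    scenario: GroundTruthScenario, config: SimulationConfig
) -> Cohort:
    """Simulate one applicant pool under a ground-truth scenario."""
    streams = RngStreams(config.seed)
    latents = sample_latents(config, streams.stream("latents"))
    probs = completion_probabilities(latents, config)
    outcomes = sample_outcomes(probs, streams.stream("outcomes"))
    panel = build_predictors(latents, scenario, streams)
    return Cohort(config, scenario, latents, outcomes, panel)
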