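"""Latent characteristics and the degree-completion outcome model.

Each applicant carries ``k`` unobservable characteristics drawn iid from a
standard normal distribution.  For every characteristic a *sufficiency
probability* — the chance that the applicant's level on that one trait is
enough to finish the degree — is read off a normal CDF with mean ``mu`` and
standard deviation ``sigma`` (defaults -1 and 1, so the median applicant has
sufficiency Phi(1) ~= .84 per trait).  The traits act as independent hurdles:
the completion probability is the *product* of the sufficiencies, and the
observed binary outcome is a single Bernoulli flip of that probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .errors import ConfigurationError, InvalidValueError

__all__ = [
    "SimulationConfig",
    "LatentMatrix",
    "CompletionOutcomes",
    "sample_latents",
    "sufficiency_probability",
    "completion_probability",
    "completion_probabilities",
    "sample_outcomes",
    "expected_population_completion",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Population-level parameters of the generative model.

    Parameters
    ----------
    n_applicants : int
        Size of the simulated applicant pool.
    k_latents : int
        Number of latent characteristics.  Must be at least 2: compensation
        between traits requires more than one trait.
    seed : int
        Root seed; all named substreams derive from it.
    sufficiency_mean, sufficiency_sd : float
        Location and scale of the normal CDF that converts a latent value
        into a per-trait sufficiency probability.
    """

    n_applicants: int = 1_000_000
    k_latents: int = 4
    seed: int = 0
    sufficiency_mean: float = -1.0
    sufficiency_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_applicants < 1:
            raise ConfigurationError("n_applicants must be >= 1")
        if self.k_latents < 2:
            raise ConfigurationError(
                "k_latents must be >= 2: compensatory selection needs at "
                "least two latent characteristics"
            )
        if self.sufficiency_sd <= 0:
            raise ConfigurationError("sufficiency_sd must be > 0")


@dataclass(frozen=True)
class LatentMatrix:
    """n_applicants x k_latents matrix of standard-normal latent traits."""

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise InvalidValueError("latent matrix must be 2-D")
        if not np.isfinite(v).all():
            raise InvalidValueError("latent matrix must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_applicants(self) -> int:
        return self.values.shape[0]

    @property
    def k_latents(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CompletionOutcomes:
    """Per-applicant completion probability and its Bernoulli realisation."""

    probability: np.ndarray = field(repr=False)
    outcome: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probability, dtype=float)
        y = np.asarray(self.outcome)
        if p.shape != y.shape:
            raise InvalidValueError("probability and outcome shapes differ")
        if np.any((p < 0) | (p > 1)):
            raise InvalidValueError("completion probabilities must lie in [0, 1]")
        if not np.isin(y, (0, 1)).all():
            raise InvalidValueError("outcomes must be 0 or 1")
        object.__setattr__(self, "probability", p)
        object.__setattr__(self, "outcome", np.asarray(y, dtype=np.int8))

    @property
    def n(self) -> int:
        return self.probability.shape[0]


def sample_latents(config: SimulationConfig, rng: np.random.Generator) -> LatentMatrix:
    """Draw the n x k matrix of iid standard-normal latent characteristics."""
    values = rng.standard_normal((config.n_applicants, config.k_latents))
    return LatentMatrix(values)


def sufficiency_probability(
    latent_value, mean: float = -1.0, sd: float = 1.0
) -> np.ndarray | float:
    """Probability that a latent level suffices for completion.

    Evaluates ``Phi((x - mean) / sd)``; strictly increasing in ``x``.
    Vectorised over ``latent_value``.
    """
    if sd <= 0:
        raise InvalidValueError("sufficiency sd must be > 0")
    return stats.norm.cdf(latent_value, loc=mean, scale=sd)


def completion_probability(sufficiencies) -> np.ndarray | float:
    """Product of per-trait sufficiency probabilities.

    Accepts a single applicant's vector of sufficiencies or an
    ``n x k`` matrix (product taken along the last axis).  A zero anywhere
    makes failure certain; all ones make completion certain.
    """
    s = np.asarray(sufficiencies, dtype=float)
    if np.any((s < 0) | (s > 1)) or not np.isfinite(s).all():
        raise InvalidValueError("sufficiency probabilities must lie in [0, 1]")
    return s.prod(axis=-1)


def sample_outcomes(probabilities, rng: np.random.Generator) -> CompletionOutcomes:
    """Bernoulli-realise completion for each applicant."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise InvalidValueError("probabilities must lie in [0, 1]")
    outcome = (rng.random(p.shape) < p).astype(np.int8)
    return CompletionOutcomes(probability=p, outcome=outcome)


def completion_probabilities(
    latents: LatentMatrix, config: SimulationConfig
) -> np.ndarray:
    """Per-applicant completion probability from the latent matrix."""
    suff = sufficiency_probability(
        latents.values, config.sufficiency_mean, config.sufficiency_sd
    )
    return completion_probability(suff)


def expected_population_completion(config: SimulationConfig) -> float:
    """Analytic population-mean completion probability.

    For iid standard-normal latents the per-trait expectation is
    ``E[Phi((L - mu)/sigma)]``, computed here by 1-D quadrature of
    ``Phi((x - mu)/sigma) * phi(x)``; by independence the population mean is
    that value raised to the k-th power.  (For the defaults mu=-1, sigma=1 the
    closed form is ``Phi(1/sqrt(2))**4`` ~= 0.334.)
    """
    mu, sd = config.sufficiency_mean, config.sufficiency_sd

    def integrand(x: float) -> float:
        return stats.norm.cdf(x, loc=mu, scale=sd) * stats.norm.pdf(x)

    per_trait, _ = integrate.quad(integrand, -np.inf, np.inf)
    return float(per_trait**config.k_latents)
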