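"""The observable application: predictors built from latents by factor loadings.

Each observed predictor (Test, Grades, Letters, Statement) is a linear
combination of the latent characteristics, plus standard-normal measurement
error, rank-ordered across all applicants into a percentile score on
(0, 100].  Rows of the loading matrix are constrained to (approximately) unit
sum of squares so every predictor has the same signal variance.  An *invalid*
predictor measures nothing: its percentiles are drawn Uniform(0, 100]
independently of the latents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InvalidValueError
from .population import LatentMatrix
from .rng import RngStreams

__all__ = [
    "DEFAULT_PREDICTORS",
    "CORRELATED_LOADINGS",
    "FactorLoadings",
    "GroundTruthScenario",
    "PredictorPanel",
    "linear_combination",
    "add_measurement_noise",
    "percentile_transform",
    "build_predictors",
    "validate_loadings",
    "expected_percentile_correlation",
]

DEFAULT_PREDICTORS = ("Test", "Grades", "Letters", "Statement")

#: Loading matrix of the valid-correlated scenario: Grades and Letters each
#: mix three neighbouring latents so that adjacent predictors correlate ~.28
#: after unit noise and rank transformation.
CORRELATED_LOADINGS = np.array(
    [
        [1.00, 0.00, 0.00, 0.00],  # Test
        [0.58, 0.71, 0.41, 0.00],  # Grades
        [0.00, 0.41, 0.71, 0.58],  # Letters
        [0.00, 0.00, 0.00, 1.00],  # Statement
    ]
)

#: Row sum-of-squares may deviate from 1 by this much before being flagged;
#: accommodates loadings printed to two decimals (e.g. .58^2+.71^2+.41^2 = 1.0086).
ROW_NORM_TOL = 0.02


@dataclass(frozen=True)
class FactorLoadings:
    """k_predictors x k_latents weight matrix mapping latents to raw scores."""

    matrix: np.ndarray = field(repr=False)
    predictor_names: tuple[str, ...] = DEFAULT_PREDICTORS

    def __post_init__(self) -> None:
        m = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if m.shape[0] != len(self.predictor_names):
            raise ConfigurationError(
                f"{m.shape[0]} loading rows but "
                f"{len(self.predictor_names)} predictor names"
            )
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "predictor_names", tuple(self.predictor_names))

    @classmethod
    def identity(
        cls, names: tuple[str, ...] = DEFAULT_PREDICTORS
    ) -> "FactorLoadings":
        """One-to-one loadings: each predictor measures exactly one latent."""
        return cls(np.eye(len(names)), names)

    @classmethod
    def correlated(cls) -> "FactorLoadings":
        """The valid-correlated scenario's loading matrix, as printed."""
        return cls(CORRELATED_LOADINGS.copy(), DEFAULT_PREDICTORS)

    @property
    def k_predictors(self) -> int:
        return self.matrix.shape[0]

    @property
    def k_latents(self) -> int:
        return self.matrix.shape[1]

    def row(self, name: str) -> np.ndarray:
        return self.matrix[self.predictor_names.index(name)]


@dataclass(frozen=True)
class GroundTruthScenario:
    """A generative configuration for the applicant pool.

    ``invalid_predictors`` lists predictors whose percentiles are replaced by
    uniform draws (they measure nothing).  ``default_test_weight`` is the Test
    weight the canonical with-Test admissions policy uses under this scenario
    (1.3 when the scenario is about over-weighting, else 1).
    """

    name: str
    loadings: FactorLoadings
    invalid_predictors: frozenset[str] = frozenset()
    noise_sd: float = 1.0
    default_test_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        unknown = set(self.invalid_predictors) - set(self.loadings.predictor_names)
        if unknown:
            raise ConfigurationError(f"unknown invalid predictors: {sorted(unknown)}")
        object.__setattr__(
            self, "invalid_predictors", frozenset(self.invalid_predictors)
        )

    @classmethod
    def from_name(cls, name: str) -> "GroundTruthScenario":
        """Construct one of the four named scenarios.

        ``invalid_test``
            Test percentiles uniform and independent of the latents; the
            other predictors each measure their own latent.
        ``valid_uncorrelated``
            Identity loadings: each predictor measures its own latent.
        ``valid_uncorrelated_overweighted``
            Same pool as ``valid_uncorrelated``; the canonical with-Test
            policy over-weights Test at 1.3.
        ``valid_correlated``
            The correlated loading matrix (adjacent predictors share latents).
        """
        if name == "invalid_test":
            return cls(name, FactorLoadings.identity(), frozenset({"Test"}))
        if name == "valid_uncorrelated":
            return cls(name, FactorLoadings.identity())
        if name == "valid_uncorrelated_overweighted":
            return cls(name, FactorLoadings.identity(), default_test_weight=1.3)
        if name == "valid_correlated":
            return cls(name, FactorLoadings.correlated())
        raise ConfigurationError(f"unknown scenario name: {name!r}")


@dataclass(frozen=True)
class PredictorPanel:
    """Percentile scores (and pre-rank raw scores) for every predictor.

    ``percentiles`` is n x k with values in (0, 100].  ``raw`` holds the
    noisy pre-rank scores for diagnostics; NaN for invalid predictors, whose
    percentiles are drawn directly.
    """

    percentiles: np.ndarray = field(repr=False)
    raw: np.ndarray = field(repr=False)
    predictor_names: tuple[str, ...] = DEFAULT_PREDICTORS

    def __post_init__(self) -> None:
        object.__setattr__(self, "predictor_names", tuple(self.predictor_names))

    @property
    def n_applicants(self) -> int:
        return self.percentiles.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.percentiles[:, self.predictor_names.index(name)]


def linear_combination(latents: LatentMatrix, loadings: FactorLoadings) -> np.ndarray:
    """Raw predictor scores: raw[i, p] = sum_j loadings[p, j] * latents[i, j]."""
    lat = latents.values
    if lat.shape[1] != loadings.k_latents:
        raise InvalidValueError(
            f"latents have {lat.shape[1]} columns, loadings expect "
            f"{loadings.k_latents}"
        )
    return lat @ loadings.matrix.T


def add_measurement_noise(
    raw: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Add iid Normal(0, noise_sd) to every cell; noise_sd=0 is a no-op."""
    if noise_sd < 0:
        raise InvalidValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return np.array(raw, dtype=float, copy=True)
    return raw + noise_sd * rng.standard_normal(np.shape(raw))


def percentile_transform(
    values, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Rank-order values across applicants into percentiles 100*rank/n.

    Ranks run 1..n so the output lies in (0, 100]; the transform is strictly
    monotone in the input up to tie-breaking.  Ties are broken by a random
    key from ``rng`` when given (the pipeline passes a dedicated substream),
    otherwise by stable input order.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise InvalidValueError("percentile_transform needs a non-empty 1-D vector")
    n = v.size
    if rng is None:
        order = np.argsort(v, kind="stable")
    else:
        order = np.lexsort((rng.random(n), v))
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    return 100.0 * ranks / n


def build_predictors(
    latents: LatentMatrix, scenario: GroundTruthScenario, streams: RngStreams
) -> PredictorPanel:
    """Assemble the full percentile panel for a scenario.

    Valid predictors follow loading -> noise -> rank; invalid predictors get
    Uniform(0, 100] percentiles.  Each predictor consumes its own named noise
    and tie-break substreams, so one predictor's construction never perturbs
    another's draws.
    """
    names = scenario.loadings.predictor_names
    n = latents.n_applicants
    raw_all = linear_combination(latents, scenario.loadings)
    percentiles = np.empty((n, len(names)))
    raw_out = np.full((n, len(names)), np.nan)
    for j, name in enumerate(names):
        if name in scenario.invalid_predictors:
            # uniform on (0, 100]: random() is [0, 1), so flip the interval
            u = streams.stream(f"invalid:{name}").random(n)
            percentiles[:, j] = 100.0 * (1.0 - u)
        else:
            noisy = add_measurement_noise(
                raw_all[:, j], scenario.noise_sd, streams.stream(f"noise:{name}")
            )
            raw_out[:, j] = noisy
            percentiles[:, j] = percentile_transform(
                noisy, streams.stream(f"ties:{name}")
            )
    return PredictorPanel(percentiles, raw_out, names)


def validate_loadings(loadings: FactorLoadings) -> dict[str, dict]:
    """Report-only check that each row's sum of squares is ~1.

    Returns ``{predictor: {"sum_sq": float, "ok": bool}}``; rows deviating
    from 1 by more than ``ROW_NORM_TOL`` are flagged, the input is never
    mutated or rejected.
    """
    report = {}
    for name, row in zip(loadings.predictor_names, loadings.matrix):
        ss = float(np.sum(row**2))
        report[name] = {"sum_sq": ss, "ok": abs(ss - 1.0) <= ROW_NORM_TOL}
    return report


def expected_percentile_correlation(
    loadings: FactorLoadings,
    noise_sd: float,
    p: str,
    q: str,
    invalid_predictors: frozenset[str] = frozenset(),
) -> tuple[float, bool]:
    """Analytic Pearson correlation between two percentile columns.

    The raw scores are jointly normal with covariance ``(L L^T)_pq`` and
    per-predictor variance ``|L_p|^2 + noise_sd^2``; the rank (percentile)
    correlation of a bivariate normal is ``(6/pi) * arcsin(rho/2)``.  Returns
    ``(correlation, valid_flag)``; an invalid predictor has no association
    with anything, so the pair yields ``(0.0, False)``.
    """
    if p in invalid_predictors or q in invalid_predictors:
        return 0.0, False
    row_p, row_q = loadings.row(p), loadings.row(q)
    var_p = float(row_p @ row_p) + noise_sd**2
    var_q = float(row_q @ row_q) + noise_sd**2
    rho_raw = float(row_p @ row_q) / np.sqrt(var_p * var_q)
    rank_rho = (6.0 / np.pi) * np.arcsin(rho_raw / 2.0)
    return float(rank_rho), True


def ks_distance_from_uniform(percentiles: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance of a percentile column from Uniform(0, 100)."""
    return float(stats.kstest(percentiles, stats.uniform(0, 100).cdf).statistic)
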