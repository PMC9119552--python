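"""Admissions policies: who gets accepted from a predictor panel.

The canonical policy is compensatory: a weighted sum of the four percentile
scores, accepting the top fraction.  Weight 1.3 on Test models over-weighting;
weight 0 models dropping the Test.  Two cutoff variants model a strict Test
threshold, with the committee either blind to Test scores beyond the threshold
or able to see them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InfeasiblePolicyError, InvalidValueError
from .predictors import PredictorPanel

__all__ = [
    "POLICY_TYPES",
    "AdmissionsPolicy",
    "AcceptanceMask",
    "composite_score",
    "select_top_fraction",
    "apply_policy",
]

POLICY_TYPES = ("accept_all", "weighted_sum", "cutoff_blind", "cutoff_visible")


@dataclass(frozen=True)
class AdmissionsPolicy:
    """A selection rule over predictor percentiles.

    ``weights`` maps each predictor name to a non-negative weight (missing
    names are an error at application time, not construction).  The cutoff
    policies first eliminate applicants at or below ``test_cutoff`` on the
    Test percentile, then rank survivors by a weighted sum that excludes
    (``cutoff_blind``) or includes (``cutoff_visible``) the Test.
    """

    policy_type: str
    weights: dict[str, float] = field(default_factory=dict)
    acceptance_fraction: float = 1.0
    test_cutoff: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.policy_type not in POLICY_TYPES:
            raise ConfigurationError(f"unknown policy type {self.policy_type!r}")
        if not (0 < self.acceptance_fraction <= 1):
            raise ConfigurationError("acceptance_fraction must be in (0, 1]")
        if any(w < 0 for w in self.weights.values()):
            raise ConfigurationError("weights must be non-negative")
        if self.policy_type.startswith("cutoff"):
            if self.test_cutoff is None or not (0 <= self.test_cutoff <= 100):
                raise ConfigurationError(
                    "cutoff policies need a test_cutoff in [0, 100]"
                )
        if self.name is None:
            object.__setattr__(self, "name", self.policy_type)

    @classmethod
    def accept_all(cls) -> "AdmissionsPolicy":
        return cls("accept_all", name="accept_all")

    @classmethod
    def top_fraction(
        cls,
        fraction: float = 0.10,
        test_weight: float = 1.0,
        predictor_names=("Test", "Grades", "Letters", "Statement"),
        name: str | None = None,
    ) -> "AdmissionsPolicy":
        """Weighted-sum policy with unit weights except Test."""
        weights = {p: 1.0 for p in predictor_names}
        weights["Test"] = test_weight
        if name is None:
            pct = round(100 * fraction)
            tag = {0.0: "no_test", 1.0: "with_test"}.get(
                test_weight, f"test_weight_{test_weight:g}"
            )
            name = f"top{pct}_{tag}"
        return cls("weighted_sum", weights, fraction, name=name)


@dataclass(frozen=True)
class AcceptanceMask:
    """Boolean accepted indicator per applicant."""

    accepted: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "accepted", np.asarray(self.accepted, dtype=bool))

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())

    @property
    def n(self) -> int:
        return self.accepted.shape[0]


def composite_score(panel: PredictorPanel, weights: dict[str, float]) -> np.ndarray:
    """Weighted sum of percentile scores: score[i] = sum_p w_p * pct[i, p]."""
    missing = [p for p in panel.predictor_names if p not in weights]
    if missing:
        raise ConfigurationError(f"no weight given for predictors: {missing}")
    w = np.array([weights[p] for p in panel.predictor_names])
    return panel.percentiles @ w


def select_top_fraction(
    scores: np.ndarray,
    fraction: float,
    rng: np.random.Generator | None = None,
    eligible: np.ndarray | None = None,
    n_accept: int | None = None,
) -> AcceptanceMask:
    """Accept the floor(fraction * n) highest scores.

    Boundary ties are broken by a random key from ``rng`` (stable order if
    None).  ``eligible`` restricts the candidate set while keeping the mask
    full-length; ``n_accept`` overrides the count (used by cutoff policies,
    whose fraction refers to the whole pool, not the survivors).
    """
    if not (0 < fraction <= 1):
        raise InvalidValueError("fraction must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if eligible is None:
        eligible = np.ones(n, dtype=bool)
    candidates = np.flatnonzero(eligible)
    if n_accept is None:
        n_accept = int(np.floor(fraction * n + 1e-9))
    if n_accept > candidates.size:
        raise InfeasiblePolicyError(
            f"policy needs {n_accept} acceptances but only "
            f"{candidates.size} applicants are eligible"
        )
    cand_scores = scores[candidates]
    key = rng.random(candidates.size) if rng is not None else np.zeros(candidates.size)
    order = np.lexsort((key, cand_scores))  # ascending; take the top tail
    chosen = candidates[order[candidates.size - n_accept :]]
    accepted = np.zeros(n, dtype=bool)
    accepted[chosen] = True
    return AcceptanceMask(accepted)


def apply_policy(
    panel: PredictorPanel,
    policy: AdmissionsPolicy,
    rng: np.random.Generator | None = None,
) -> AcceptanceMask:
    """Evaluate a policy on a panel and return the acceptance mask."""
    n = panel.n_applicants
    if policy.policy_type == "accept_all":
        return AcceptanceMask(np.ones(n, dtype=bool))

    if policy.policy_type == "weighted_sum":
        scores = composite_score(panel, policy.weights)
        return select_top_fraction(scores, policy.acceptance_fraction, rng)

    # cutoff variants: eliminate at/below the Test threshold, then rank the
    # survivors; total accepted is still a fraction of the whole pool
    survivors = panel.column("Test") > policy.test_cutoff
    weights = dict(policy.weights) or {p: 1.0 for p in panel.predictor_names}
    weights.setdefault("Test", 1.0)
    for p in panel.predictor_names:
        weights.setdefault(p, 1.0)
    if policy.policy_type == "cutoff_blind":
        weights["Test"] = 0.0
    scores = composite_score(panel, weights)
    n_accept = int(np.floor(policy.acceptance_fraction * n + 1e-9))
    return select_top_fraction(
        scores, policy.acceptance_fraction, rng, eligible=survivors, n_accept=n_accept
    )
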