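"""Summary statistics of a selected cohort.

The headline quantities mirror what an institutional-research analysis of
admissions data would compute: the completion rate among accepted students,
the acceptance/completion curves over integer Test-percentile bins, the
Pearson correlation and OLS slope of the binned completion curve (ρ_{T,S} =
COV(T,S) / (σ_T σ_S) on the per-bin series), the correlation among accepted
students between the Test and the other predictors, and the test-retest
reliability implied by the measurement-noise level.

All metrics are deterministic functions of the cohort and the acceptance
mask; only :func:`test_retest_reliability` simulates (it estimates a design
property of the measurement model, not of a particular cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .admissions import AcceptanceMask
from .errors import InvalidValueError, UndefinedMetricError
from .population import CompletionOutcomes
from .predictors import PredictorPanel, percentile_transform

__all__ = [
    "CompletionCurve",
    "MetricsReport",
    "completion_rate",
    "completion_curve",
    "curve_correlation",
    "regression_slope",
    "test_vs_rest_correlation",
    "test_retest_reliability",
    "compute_report",
]

#: minimum accepted students in a percentile bin for it to enter the curve
DEFAULT_MIN_COUNT = 10

#: minimum within-bin acceptance probability for the bin to enter curve
#: statistics.  Bins where acceptance is rarer than this hold only the most
#: extreme compensation cases; including them makes the curve r depend on the
#: simulated population size (deeper tail bins keep appearing as n grows).
#: A fixed rate threshold keeps the statistic scale-invariant and matches the
#: span of the plotted curves (acceptance visibly above zero).
DEFAULT_MIN_RATE = 0.01


@dataclass(frozen=True)
class CompletionCurve:
    """Acceptance and completion rates over integer Test-percentile bins.

    Bins 1..100 are assigned by ceiling of the continuous percentile.
    ``completion_rate`` is NaN (missing, not zero) for bins with fewer than
    ``min_count`` accepted students or an acceptance rate below ``min_rate``;
    ``acceptance_rate`` is NaN for bins with no applicants at all.
    ``bin_counts`` counts *accepted* students per bin.
    """

    bin_centers: np.ndarray = field(repr=False)
    acceptance_rate: np.ndarray = field(repr=False)
    completion_rate: np.ndarray = field(repr=False)
    bin_counts: np.ndarray = field(repr=False)
    min_count: int = DEFAULT_MIN_COUNT
    min_rate: float = DEFAULT_MIN_RATE

    @property
    def occupied(self) -> np.ndarray:
        """Bins that contribute to curve statistics."""
        return ~np.isnan(self.completion_rate)

    @property
    def n_occupied(self) -> int:
        return int(self.occupied.sum())


@dataclass(frozen=True)
class MetricsReport:
    """Per-cell summary of a (scenario, policy) run."""

    completion_pct: float
    curve_r: float
    curve_p: float
    slope: float  # completion proportion per Test percentile
    r_squared: float
    test_vs_rest_r: float
    test_vs_rest_r_pairwise: float
    n_accepted: int
    n_bins: int

    @property
    def slope_pct(self) -> float:
        """Slope in percent completion per Test percentile (plot units)."""
        return 100.0 * self.slope

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["slope_pct"] = self.slope_pct
        return d


def _accepted_bool(mask: AcceptanceMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, AcceptanceMask):
        return mask.accepted
    return np.asarray(mask, dtype=bool)


def _outcome_vec(outcomes: CompletionOutcomes | np.ndarray) -> np.ndarray:
    if isinstance(outcomes, CompletionOutcomes):
        return outcomes.outcome
    return np.asarray(outcomes)


def completion_rate(
    mask: AcceptanceMask, outcomes: CompletionOutcomes
) -> float:
    """Mean completion among accepted students, in percent."""
    acc = _accepted_bool(mask)
    if not acc.any():
        raise UndefinedMetricError("completion rate undefined: nobody accepted")
    return 100.0 * float(_outcome_vec(outcomes)[acc].mean())


def completion_curve(
    test_percentiles: np.ndarray,
    mask: AcceptanceMask,
    outcomes: CompletionOutcomes,
    min_count: int = DEFAULT_MIN_COUNT,
    min_rate: float = DEFAULT_MIN_RATE,
) -> CompletionCurve:
    """Bin applicants by integer Test percentile; rates per bin.

    The acceptance rate in a bin is accepted/total over *all* applicants in
    the bin; the completion rate averages outcomes over *accepted* students
    only.  A bin is flagged missing when it holds fewer than ``min_count``
    accepted students or its acceptance rate falls below ``min_rate`` — such
    bins contain only extreme-compensation admits, and whether they appear
    at all is an artefact of the simulated population size.
    """
    pct = np.asarray(test_percentiles, dtype=float)
    acc = _accepted_bool(mask)
    y = _outcome_vec(outcomes)
    bins = np.ceil(pct).astype(np.int64)
    np.clip(bins, 1, 100, out=bins)
    total = np.bincount(bins, minlength=101)[1:]
    n_acc = np.bincount(bins[acc], minlength=101)[1:]
    n_done = np.bincount(bins[acc & (y == 1)], minlength=101)[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        acc_rate = np.where(total > 0, n_acc / np.maximum(total, 1), np.nan)
        keep = (n_acc >= max(min_count, 1)) & (
            n_acc >= min_rate * np.maximum(total, 1)
        )
        comp_rate = np.where(keep, n_done / np.maximum(n_acc, 1), np.nan)
    return CompletionCurve(
        bin_centers=np.arange(1, 101),
        acceptance_rate=acc_rate,
        completion_rate=comp_rate,
        bin_counts=n_acc,
        min_count=min_count,
        min_rate=min_rate,
    )


def _occupied_series(curve: CompletionCurve) -> tuple[np.ndarray, np.ndarray]:
    occ = curve.occupied
    if occ.sum() < 3:
        raise UndefinedMetricError(
            f"curve statistics need >= 3 occupied bins, got {int(occ.sum())}"
        )
    return curve.bin_centers[occ].astype(float), curve.completion_rate[occ]


def curve_correlation(curve: CompletionCurve) -> tuple[float, float]:
    """Pearson r (and two-sided p, df = bins - 2) of rate vs bin center.

    Each occupied bin is one unweighted observation — the statistic describes
    the plotted per-percentile series, not the individual-level outcomes.
    """
    x, y = _occupied_series(curve)
    if np.ptp(y) == 0:  # constant curve: r undefined, report 0 association
        return 0.0, 1.0
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def regression_slope(curve: CompletionCurve) -> float:
    """OLS slope of per-bin completion proportion on bin center.

    Units: completion-proportion change per Test percentile (multiply by 100
    for the percent-per-percentile scale used when plotting).
    """
    slope, _ = regression_slope_with_se(curve)
    return slope


def regression_slope_with_se(curve: CompletionCurve) -> tuple[float, float]:
    x, y = _occupied_series(curve)
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.stderr)


def test_vs_rest_correlation(
    panel: PredictorPanel,
    mask: AcceptanceMask,
    test_name: str = "Test",
    method: str = "sum",
) -> float:
    """Correlation, among accepted students, of Test vs the other predictors.

    ``method="sum"`` (primary): Pearson r between the Test percentile and the
    unweighted sum of the remaining predictors' percentiles.
    ``method="pairwise"``: mean of the pairwise correlations of Test with
    each remaining predictor.
    """
    acc = _accepted_bool(mask)
    if acc.sum() < 3:
        raise UndefinedMetricError("need >= 3 accepted students")
    others = [p for p in panel.predictor_names if p != test_name]
    test = panel.column(test_name)[acc]
    if np.ptp(test) == 0:
        raise UndefinedMetricError("degenerate Test variance among accepted")
    if method == "sum":
        rest = sum(panel.column(p)[acc] for p in others)
        return float(stats.pearsonr(test, rest).statistic)
    if method == "pairwise":
        rs = [
            float(stats.pearsonr(test, panel.column(p)[acc]).statistic)
            for p in others
        ]
        return float(np.mean(rs))
    raise InvalidValueError(f"unknown method {method!r}")


def test_retest_reliability(
    loading_row: np.ndarray,
    noise_sd: float,
    n: int,
    rng: np.random.Generator,
) -> float:
    """Simulated reliability of the percentile score under repeat testing.

    One latent draw per individual, two independent noisy measurements, each
    percentile-transformed across individuals; returns the Pearson r of the
    two percentile vectors.  For a unit loading the raw-score correlation is
    1 / (1 + noise_sd^2) and the rank-scale value follows the bivariate-normal
    identity (6/pi) * arcsin(rho/2) — ~0.48 at unit noise.
    """
    if n < 100:
        raise InvalidValueError("reliability estimate needs n >= 100")
    w = np.atleast_1d(np.asarray(loading_row, dtype=float))
    latents = rng.standard_normal((n, w.size))
    signal = latents @ w
    p1 = percentile_transform(signal + noise_sd * rng.standard_normal(n), rng)
    p2 = percentile_transform(signal + noise_sd * rng.standard_normal(n), rng)
    return float(stats.pearsonr(p1, p2).statistic)


def compute_report(
    panel: PredictorPanel,
    mask: AcceptanceMask,
    outcomes: CompletionOutcomes,
    min_count: int = DEFAULT_MIN_COUNT,
    min_rate: float = DEFAULT_MIN_RATE,
) -> tuple[MetricsReport, CompletionCurve]:
    """Full per-cell summary plus the underlying completion curve."""
    curve = completion_curve(
        panel.column("Test"), mask, outcomes, min_count, min_rate
    )
    r, p = curve_correlation(curve)
    slope = regression_slope(curve)
    report = MetricsReport(
        completion_pct=completion_rate(mask, outcomes),
        curve_r=r,
        curve_p=p,
        slope=slope,
        r_squared=r * r,
        test_vs_rest_r=test_vs_rest_correlation(panel, mask, method="sum"),
        test_vs_rest_r_pairwise=test_vs_rest_correlation(
            panel, mask, method="pairwise"
        ),
        n_accepted=mask.n_accepted if isinstance(mask, AcceptanceMask) else int(
            np.asarray(mask).sum()
        ),
        n_bins=curve.n_occupied,
    )
    return report, curve
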