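"""Bootstrap confidence intervals and convergence diagnostics.

Reliability of a tail-based P-value estimate is assessed by resampling the
permutation values with replacement and re-running the full estimator on
each resample.  Two heuristic criteria together declare convergence:

(a) the coefficient of variation of the estimate on the log10 scale,

        CV = (1/2) |log10 P^(16) - log10 P^(84)| / (-log10 P_est),

    where P^(16) and P^(84) are the 16th and 84th bootstrap percentiles
    (one standard deviation either side of the mean under normality),
    must be smaller than one; and

(b) bootstrap estimates from all permutation values and from 10% of them
    must not differ in median — a two-sided Wilcoxon rank-sum test on the
    two sets of 500 log10 estimates, rejecting at P < 0.001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

from .config import EstimatorConfig, RunConfig
from .estimator import EstimateResult, PermutationColumn, estimate

__all__ = [
    "BootstrapSet",
    "ConvergenceReport",
    "BootstrapError",
    "bootstrap_estimates",
    "confidence_interval",
    "cv_criterion",
    "median_criterion",
    "convergence",
]


class BootstrapError(RuntimeError):
    """Too many bootstrap replicates failed to produce an estimate."""


@dataclass(frozen=True)
class BootstrapSet:
    """Bootstrap P-value estimates from resampled permutation values."""

    estimates: np.ndarray
    source_fraction: float
    replicates: int
    n_failed: int = 0

    def __post_init__(self) -> None:
        e = np.asarray(self.estimates, dtype=float)
        if np.any((e < 0) | (e > 1)):
            raise ValueError("bootstrap estimates must lie in [0, 1]")
        object.__setattr__(self, "estimates", e)


@dataclass(frozen=True)
class ConvergenceReport:
    cv: float
    cv_pass: bool
    median_test_p: float
    median_pass: bool
    converged: bool
    full: BootstrapSet | None = None
    sub: BootstrapSet | None = None
    notes: tuple[str, ...] = field(default_factory=tuple)


def bootstrap_estimates(
    column: PermutationColumn,
    config: EstimatorConfig | None = None,
    fraction: float = 1.0,
    replicates: int = 500,
    rng: np.random.Generator | None = None,
    power: float = 1.0,
) -> BootstrapSet:
    """Re-run the estimator on ``replicates`` resamples of the column.

    Each replicate draws ``ceil(fraction * N)`` values with replacement.
    Replicates where the estimator fails (tail rejected everywhere) are
    dropped and counted; more than 50% failures raises BootstrapError.
    The >= 1000-value input gate is not applied to internal resamples.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    config = (config or EstimatorConfig()).without_tail_minimum()
    rng = rng or np.random.default_rng()
    n_values = column.n
    m = math.ceil(fraction * n_values)
    idx = rng.integers(0, n_values, size=(replicates, m))
    estimates = []
    failed = 0
    for row in idx:
        try:
            res = estimate(
                PermutationColumn(x0=column.x0, values=column.values[row]),
                config, power=power,
            )
        except ValueError:
            failed += 1
            continue
        if res.ok:
            estimates.append(res.p_value)
        else:
            failed += 1
    if failed > replicates // 2:
        raise BootstrapError(
            f"{failed}/{replicates} bootstrap replicates failed to produce an estimate"
        )
    return BootstrapSet(
        estimates=np.asarray(estimates), source_fraction=fraction,
        replicates=replicates, n_failed=failed,
    )


def confidence_interval(
    boot: BootstrapSet, level: float = 95, point_estimate: float | None = None
) -> tuple[float, float]:
    """Percentile bootstrap interval at the given confidence level (percent).

    The level must lie in [10, 99].  Percentiles use linear interpolation
    between order statistics; if a point estimate is supplied the interval
    is widened, if necessary, to bracket it.
    """
    if not 10 <= level <= 99:
        raise ValueError("confidence level must be between 10 and 99")
    if boot.estimates.size == 0:
        raise ValueError("empty bootstrap set")
    alpha = (100.0 - level) / 2.0
    lower, upper = np.percentile(boot.estimates, [alpha, 100.0 - alpha])
    if point_estimate is not None and np.isfinite(point_estimate):
        lower = min(lower, point_estimate)
        upper = max(upper, point_estimate)
    return float(lower), float(upper)


def cv_criterion(boot: BootstrapSet, p_est: float) -> tuple[float, bool]:
    """Coefficient of variation of the estimate on the log10 scale.

    Passes when CV < 1.  Undefined for p_est of 0 or 1 (log10 p_est is 0
    or infinite); raises ValueError in that case.
    """
    if not 0 < p_est < 1:
        raise ValueError("CV is undefined for a P-value estimate of exactly 0 or 1")
    if boot.estimates.size == 0:
        raise ValueError("empty bootstrap set")
    q16, q84 = np.percentile(boot.estimates, [16.0, 84.0])
    with np.errstate(divide="ignore"):
        spread = abs(np.log10(q16) - np.log10(q84))
    cv = float(0.5 * spread / (-math.log10(p_est)))
    return cv, cv < 1.0


def median_criterion(full: BootstrapSet, sub: BootstrapSet) -> tuple[float, bool]:
    """Wilcoxon rank-sum comparison of full-sample and subsample bootstraps.

    Two-sided test on the log10 estimates (normal approximation with tie
    and continuity corrections); medians are declared different — the
    criterion fails — when P < 0.001.
    """
    if full.estimates.size == 0 or sub.estimates.size == 0:
        raise ValueError("both bootstrap sets must be nonempty")
    with np.errstate(divide="ignore"):
        a = np.log10(full.estimates)
        b = np.log10(sub.estimates)
    if np.array_equal(a, b):
        return 1.0, True
    _, p = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    p = float(p)
    return p, p >= 0.001


def convergence(
    column: PermutationColumn,
    config: RunConfig | None = None,
    rng: np.random.Generator | None = None,
    point_estimate: EstimateResult | None = None,
    power: float = 1.0,
) -> ConvergenceReport:
    """Run both convergence criteria for one column.

    Uses ``config.bootstrap_replicates`` (default 500) full-sample
    resamples and the same number at ``config.subsample_fraction``
    (default 10%).  ``converged`` is the conjunction of the CV criterion
    and the median-comparison criterion.
    """
    config = config or RunConfig()
    rng = rng or np.random.default_rng()
    notes: list[str] = []
    est = point_estimate if point_estimate is not None else estimate(
        column, config.estimator, power=power
    )
    if not est.ok:
        return ConvergenceReport(
            cv=math.inf, cv_pass=False, median_test_p=math.nan, median_pass=False,
            converged=False, notes=("estimator failed; convergence undefined",),
        )
    try:
        full = bootstrap_estimates(
            column, config.estimator, fraction=1.0,
            replicates=config.bootstrap_replicates, rng=rng, power=power,
        )
        sub = bootstrap_estimates(
            column, config.estimator, fraction=config.subsample_fraction,
            replicates=config.bootstrap_replicates, rng=rng, power=power,
        )
    except BootstrapError as err:
        return ConvergenceReport(
            cv=math.inf, cv_pass=False, median_test_p=math.nan, median_pass=False,
            converged=False, notes=(str(err),),
        )
    try:
        cv, cv_pass = cv_criterion(full, est.p_value)
    except ValueError as err:
        cv, cv_pass = math.inf, False
        notes.append(f"CV criterion undefined: {err}")
    med_p, med_pass = median_criterion(full, sub)
    return ConvergenceReport(
        cv=cv, cv_pass=cv_pass, median_test_p=med_p, median_pass=med_pass,
        converged=bool(cv_pass and med_pass), full=full, sub=sub, notes=tuple(notes),
    )
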