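"""Permutation-test P-value estimation with a generalized Pareto tail.

The empirical estimator ``P_ecdf`` — the fraction of the N permutation
values at least as extreme as the test statistic ``x0`` — cannot resolve
P-values below 1/N.  When fewer than ten permutation values reach ``x0``,
the estimator here instead models the upper tail of the permutation-value
distribution: the exceedances over a threshold ``t`` are fitted with a
generalized Pareto distribution F, a goodness-of-fit gate checks that they
look like a tail, and the P-value is

    P_gpd = (N_exc / N) * (1 - F(x0 - t)).

All P-values follow the upper-tail convention: ties with ``x0`` count as
exceedances, and two-sided tests are the caller's responsibility (submit
absolute statistics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .config import EstimatorConfig
from .gpd import FitError, GPDParams, fit_gpd, gof_test, gpd_sf

__all__ = [
    "PermutationColumn",
    "TailFit",
    "EstimateResult",
    "p_ecdf",
    "select_threshold",
    "p_gpd",
    "estimate",
    "optimize_transform",
]


@dataclass(frozen=True)
class PermutationColumn:
    """One tested event: a test statistic plus its permutation values.

    Non-finite permutation values are dropped on construction, mirroring
    the ignore rule applied when tables are parsed.
    """

    x0: float
    values: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError("a permutation column needs at least one finite value")
        if not np.isfinite(self.x0):
            raise ValueError("test statistic must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class TailFit:
    """Accepted tail model: threshold, exceedance count, GPD, transform power."""

    threshold: float
    n_exc: int
    params: GPDParams
    power: float = 1.0

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("transform power must be positive")


@dataclass(frozen=True)
class EstimateResult:
    """P-value estimate with provenance and diagnostics.

    ``estimator`` is 'empirical', 'gpd', or 'none' when the tail could not
    be modeled (all thresholds rejected by the goodness-of-fit gate); in
    that case ``p_value`` is NaN and ``notes`` explain the failure.
    """

    p_value: float
    estimator: str
    label: str | None = None
    n_values: int = 0
    n_above_x0: int = 0
    ci_lower: float | None = None
    ci_upper: float | None = None
    converged: bool | None = None
    tail_fit: TailFit | None = None
    variance_log10: float | None = None
    notes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def ok(self) -> bool:
        return self.estimator != "none" and np.isfinite(self.p_value)

    def with_ci(self, lower: float, upper: float) -> "EstimateResult":
        return replace(self, ci_lower=float(lower), ci_upper=float(upper))


def p_ecdf(x0: float, values) -> float:
    """Empirical P-value: fraction of permutation values >= x0."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty permutation-value sequence")
    return float(np.count_nonzero(v >= x0) / v.size)


def _slide_for_ties(sorted_desc: np.ndarray, n_exc: int) -> int:
    """Largest m <= n_exc such that the m-th and (m+1)-th largest values differ."""
    m = min(n_exc, sorted_desc.size - 1)
    while m >= 1 and sorted_desc[m - 1] == sorted_desc[m]:
        m -= 1
    return m


def select_threshold(values, n_exc: int) -> tuple[float, int]:
    """Threshold at the midpoint of the n_exc-th and (n_exc+1)-th largest values.

    If those two order statistics are tied, the exceedance count slides
    down to the largest count that gives a strict threshold.  Returns
    ``(threshold, actual_n_exc)``; exactly ``actual_n_exc`` values strictly
    exceed the threshold.
    """
    v = np.asarray(values, dtype=float)
    if not 1 <= n_exc < v.size:
        raise ValueError(f"n_exc must be in [1, {v.size - 1}], got {n_exc}")
    sorted_desc = np.sort(v)[::-1]
    m = _slide_for_ties(sorted_desc, n_exc)
    if m < 1:
        raise ValueError("all candidate order statistics are tied; no strict threshold exists")
    t = 0.5 * (sorted_desc[m - 1] + sorted_desc[m])
    return float(t), int(m)


def p_gpd(x0: float, tail: TailFit, n_values: int) -> float:
    """Tail-based P-value (N_exc / N) * (1 - F((x0 - t)^power)).

    For a negative fitted shape the GPD support is bounded; a statistic
    beyond the upper endpoint gets survival probability 0.
    """
    if x0 <= tail.threshold:
        raise ValueError("x0 must exceed the threshold; use the empirical estimator instead")
    z = (x0 - tail.threshold) ** tail.power
    return float(tail.n_exc / n_values * gpd_sf(z, tail.params))


def estimate(
    column: PermutationColumn,
    config: EstimatorConfig | None = None,
    power: float = 1.0,
) -> EstimateResult:
    """Estimate the P-value of one permutation column.

    With at least ``config.min_exceedances`` (default 10) permutation
    values at or above ``x0`` the empirical fraction is returned directly.
    Otherwise the GPD tail path runs: starting from
    ``min(initial_exceedances, N // 4)`` exceedances, fit the configured
    estimator and apply the Anderson–Darling gate; on rejection shrink the
    exceedance set by ``exceedance_step`` and retry.  If no threshold is
    accepted before the exceedance count falls below the minimum, a
    failure result (``estimator='none'``, NaN P-value) is returned rather
    than an exception.

    ``power`` applies the order-preserving transform: exceedances and
    ``x0 - t`` are raised to that power before fitting and evaluation.
    """
    config = config or EstimatorConfig()
    if power <= 0:
        raise ValueError("power must be positive")
    values = column.values
    n_values = values.size
    k = int(np.count_nonzero(values >= column.x0))

    if k >= config.min_exceedances:
        return EstimateResult(
            p_value=k / n_values, estimator="empirical",
            label=column.label, n_values=n_values, n_above_x0=k,
        )

    if config.enforce_tail_minimum and n_values < config.min_values_for_tail:
        raise ValueError(
            f"tail estimation requires at least {config.min_values_for_tail} "
            f"permutation values per column; column "
            f"{column.label or '<unnamed>'} has {n_values}"
        )

    notes: list[str] = []
    sorted_desc = np.sort(values)[::-1]
    n_exc = min(config.initial_exceedances, n_values // 4)
    while n_exc >= config.min_exceedances:
        m = _slide_for_ties(sorted_desc, n_exc)
        if m < config.min_exceedances:
            notes.append(f"ties collapse exceedance set below {config.min_exceedances}")
            break
        t = 0.5 * (sorted_desc[m - 1] + sorted_desc[m])
        z = sorted_desc[:m] - t
        if power != 1.0:
            z = z**power
        try:
            params = fit_gpd(z, config.method)
        except FitError as err:
            notes.append(f"fit failed at n_exc={m}: {err}")
            n_exc = m - config.exceedance_step
            continue
        gof = gof_test(z, params, config.gof_level)
        if gof.rejected:
            n_exc = m - config.exceedance_step
            continue
        tail = TailFit(threshold=t, n_exc=m, params=params, power=power)
        p = p_gpd(column.x0, tail, n_values)
        if p == 0.0 and params.shape < 0:
            notes.append(
                "statistic lies beyond the upper endpoint of the fitted "
                "bounded-support tail; point estimate 0"
            )
        return EstimateResult(
            p_value=p, estimator="gpd", label=column.label,
            n_values=n_values, n_above_x0=k, tail_fit=tail, notes=tuple(notes),
        )

    notes.append(
        "no threshold produced an acceptable generalized Pareto tail; "
        "no P-value estimate returned"
    )
    return EstimateResult(
        p_value=math.nan, estimator="none", label=column.label,
        n_values=n_values, n_above_x0=k, notes=tuple(notes),
    )


def optimize_transform(
    x0: float,
    values,
    config: EstimatorConfig | None = None,
    rng: np.random.Generator | None = None,
    n_boot: int = 200,
    label: str | None = None,
) -> tuple[float, EstimateResult]:
    """Pick the order-preserving power transform minimizing bootstrap variance.

    For each exponent ``n`` in ``config.power_grid`` the exceedances and
    ``x0 - t`` are raised to the n-th power (an order-preserving map on
    positives), the tail is re-fitted and the P-value re-estimated, and the
    variance of the log10 estimate over ``n_boot`` bootstrap resamples is
    measured.  The same resample indices are shared across all grid
    members, so the argmin is well-defined under a fixed seed.  Returns
    ``(best_power, result)`` with ``variance_log10`` filled in; if every
    grid member fails the gate, a failure result is returned.
    """
    config = config or EstimatorConfig()
    rng = rng or np.random.default_rng()
    column = PermutationColumn(x0=x0, values=values, label=label)
    k = int(np.count_nonzero(column.values >= x0))
    if k >= config.min_exceedances:
        raise ValueError(
            "transform optimization applies only on the tail path "
            f"(fewer than {config.min_exceedances} exceedances of x0)"
        )
    n_values = column.n
    idx = rng.integers(0, n_values, size=(n_boot, n_values))
    boot_cfg = config.without_tail_minimum()

    best: tuple[float, float, EstimateResult] | None = None  # (var, power, result)
    notes: list[str] = []
    for n in config.power_grid:
        res = estimate(column, config, power=n)
        if not res.ok:
            notes.append(f"power {n:g}: tail fit rejected")
            continue
        logs = []
        failed = 0
        for row in idx:
            r = estimate(
                PermutationColumn(x0=x0, values=column.values[row]), boot_cfg, power=n
            )
            if r.ok and r.p_value > 0:
                logs.append(math.log10(r.p_value))
            else:
                failed += 1
        if failed > n_boot // 2:
            notes.append(f"power {n:g}: {failed}/{n_boot} bootstrap replicates failed")
            continue
        var = float(np.var(logs))
        if best is None or var < best[0]:
            best = (var, n, res)

    if best is None:
        notes.append("no transform exponent produced an acceptable tail")
        fail = EstimateResult(
            p_value=math.nan, estimator="none", label=label,
            n_values=n_values, n_above_x0=k, notes=tuple(notes),
        )
        return 1.0, fail
    var, power, res = best
    res = replace(
        res, variance_log10=var,
        notes=res.notes + tuple(notes) + (f"selected transform power {power:g}",),
    )
    return power, res
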