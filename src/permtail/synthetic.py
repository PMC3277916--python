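"""Synthetic permutation-value generators and exact-enumeration oracles.

Two kinds of ground truth for validating the tail estimator:

* continuous null families (normal, exponential, GPD, Student t,
  lognormal) whose upper-tail probability has a closed form, so a test
  statistic can be planted at any true P-value; and
* tiny two-group datasets (total size <= 14) for which the exact
  permutation P-value is computable by exhaustive enumeration of all
  label assignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .estimator import PermutationColumn

__all__ = [
    "SyntheticSpec",
    "ExactPermCase",
    "rng_from_seed",
    "gen_column",
    "true_tail_p",
    "tail_quantile",
    "exhaustive_perm_test",
    "make_perm_column",
]

MAX_SEED = 1_000_000


def rng_from_seed(seed: int) -> np.random.Generator:
    """Seed semantics of the estimation tool: 0 means arbitrary entropy,
    1..1,000,000 means a reproducible stream."""
    seed = int(seed)
    if not 0 <= seed <= MAX_SEED:
        raise ValueError(f"seed must be between 0 and {MAX_SEED:,}")
    return np.random.default_rng() if seed == 0 else np.random.default_rng(seed)


def _frozen(family: str, params: dict):
    try:
        if family == "normal":
            return stats.norm(loc=params.get("mu", 0.0), scale=params.get("sigma", 1.0))
        if family == "exponential":
            return stats.expon(scale=params.get("scale", 1.0))
        if family == "gpd":
            return stats.genpareto(params["shape"], scale=params.get("scale", 1.0))
        if family == "student_t":
            return stats.t(params["df"])
        if family == "lognormal":
            return stats.lognorm(params.get("sigma", 1.0), scale=math.exp(params.get("mu", 0.0)))
    except (KeyError, TypeError) as err:
        raise ValueError(f"invalid parameters for family {family!r}: {err}") from err
    raise ValueError(f"unknown family {family!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Null-distribution family + parameters with a closed-form tail."""

    family: str
    params: dict = field(default_factory=dict)
    n: int = 1000
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        _frozen(self.family, self.params)  # validates family and params


def true_tail_p(family: str, params: dict, x: float) -> float:
    """Exact upper-tail probability P(X >= x) for the named family."""
    return float(_frozen(family, params).sf(x))


def tail_quantile(family: str, params: dict, tail_p: float) -> float:
    """Point whose true upper-tail probability equals ``tail_p``."""
    if not 0 < tail_p < 1:
        raise ValueError("tail probability must be in (0, 1)")
    return float(_frozen(family, params).isf(tail_p))


def gen_column(spec: SyntheticSpec, x0_tail_p: float, label: str | None = None) -> PermutationColumn:
    """Draw n permutation values from the family and plant the test
    statistic at the point with true upper-tail probability ``x0_tail_p``."""
    dist = _frozen(spec.family, spec.params)
    rng = rng_from_seed(spec.seed)
    values = dist.isf(rng.random(spec.n))  # inverse-CDF sampling
    x0 = tail_quantile(spec.family, spec.params, x0_tail_p)
    return PermutationColumn(x0=x0, values=values, label=label)


@dataclass(frozen=True)
class ExactPermCase:
    """A two-group dataset small enough to enumerate every label assignment.

    The statistic is the difference of group means, mean(a) - mean(b),
    upper tail.
    """

    group_a: tuple[float, ...]
    group_b: tuple[float, ...]
    statistic: str = "mean_diff"

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_a", tuple(float(v) for v in self.group_a))
        object.__setattr__(self, "group_b", tuple(float(v) for v in self.group_b))
        if len(self.group_a) == 0 or len(self.group_b) == 0:
            raise ValueError("both groups must be nonempty")
        if self.statistic != "mean_diff":
            raise ValueError("only the difference-of-means statistic is built in")

    @property
    def observed(self) -> float:
        return float(np.mean(self.group_a) - np.mean(self.group_b))

    @property
    def p_exact(self) -> float:
        return exhaustive_perm_test(self)


def exhaustive_perm_test(case: ExactPermCase) -> float:
    """Exact permutation P-value over all distinct group assignments.

    Enumerates every way of assigning the pooled observations to the two
    groups (preserving sizes) and returns the fraction of assignments
    whose statistic is at least the observed one.  Refuses pools larger
    than 14 observations.
    """
    pool = np.array(case.group_a + case.group_b, dtype=float)
    n_total, n_a = pool.size, len(case.group_a)
    if n_total > 14:
        raise ValueError(f"pool of {n_total} observations is too large to enumerate (max 14)")
    observed = case.observed
    total_sum = pool.sum()
    count = total = 0
    # tolerance guards float ties between arithmetically equal assignments
    tol = 1e-12 * max(1.0, abs(observed))
    for idx in combinations(range(n_total), n_a):
        sum_a = pool[list(idx)].sum()
        stat = sum_a / n_a - (total_sum - sum_a) / (n_total - n_a)
        total += 1
        if stat >= observed - tol:
            count += 1
    return count / total


def make_perm_column(case: ExactPermCase, n_perms: int, seed: int = 1) -> PermutationColumn:
    """Monte-Carlo permutation values for an exact case.

    Returns a column whose x0 is the observed statistic and whose values
    are the statistic under ``n_perms`` uniformly random label
    rearrangements; the estimator run on it targets ``case.p_exact``.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    pool = np.array(case.group_a + case.group_b, dtype=float)
    n_total, n_a = pool.size, len(case.group_a)
    rng = rng_from_seed(seed)
    # random assignments via argsort of uniforms: first n_a columns form group a
    order = np.argsort(rng.random((n_perms, n_total)), axis=1)
    sum_a = pool[order[:, :n_a]].sum(axis=1)
    stats_ = sum_a / n_a - (pool.sum() - sum_a) / (n_total - n_a)
    return PermutationColumn(x0=case.observed, values=stats_, label=None)
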