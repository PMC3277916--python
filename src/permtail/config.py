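"""Run configuration and validation for tail-based P-value estimation."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

METHODS = ("pwm", "ml", "mom")

#: power-transform exponents tried when the optimal transform is requested
DEFAULT_POWER_GRID = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass(frozen=True)
class EstimatorConfig:
    """Knobs of the tail estimator itself.

    The empirical estimator is used whenever at least ``min_exceedances``
    permutation values reach the test statistic; otherwise the GPD tail is
    fitted to the largest ``initial_exceedances`` values (capped at a
    quarter of the sample), shrinking by ``exceedance_step`` until the
    goodness-of-fit gate accepts.
    """

    method: str = "pwm"
    gof_level: float = 0.05
    min_exceedances: int = 10
    initial_exceedances: int = 250
    exceedance_step: int = 10
    min_values_for_tail: int = 1000
    enforce_tail_minimum: bool = True
    power_grid: tuple[float, ...] = DEFAULT_POWER_GRID

    def __post_init__(self) -> None:
        if self.method.lower() not in METHODS:
            raise ValueError(f"unknown estimation method {self.method!r}")
        object.__setattr__(self, "method", self.method.lower())
        if not 0 < self.gof_level < 1:
            raise ValueError("gof_level must be in (0, 1)")
        if self.min_exceedances < 1 or self.exceedance_step < 1:
            raise ValueError("exceedance counts must be positive")
        if any(p <= 0 for p in self.power_grid):
            raise ValueError("power-transform exponents must be positive")

    def without_tail_minimum(self) -> "EstimatorConfig":
        """Copy with the >= 1000 permutation-value input gate disabled.

        Used for internal bootstrap resamples, where deliberately small
        subsamples are part of the convergence diagnostic.
        """
        return replace(self, enforce_tail_minimum=False)


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one estimation run (CLI surface).

    Defaults mirror the tool's documented option defaults: PWM estimation,
    95% confidence level with the interval computed, transform and
    convergence diagnostics off, seed 0 (arbitrary entropy).
    """

    method: str = "pwm"
    confidence_level: int = 95
    ci: bool = True
    transform: bool = False
    convergence: bool = False
    seed: int = 0
    bootstrap_replicates: int = 500
    subsample_fraction: float = 0.1
    estimator: EstimatorConfig = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.method.lower() not in METHODS:
            raise ValueError(f"unknown estimation method {self.method!r}")
        object.__setattr__(self, "method", self.method.lower())
        if not 10 <= int(self.confidence_level) <= 99:
            raise ValueError("confidence level must be between 10 and 99")
        if not 0 <= int(self.seed) <= 1_000_000:
            raise ValueError("seed must be between 0 and 1,000,000")
        if self.bootstrap_replicates < 2:
            raise ValueError("bootstrap_replicates must be >= 2")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.estimator is None:
            object.__setattr__(self, "estimator", EstimatorConfig(method=self.method))
        elif self.estimator.method != self.method:
            object.__setattr__(self, "estimator", replace(self.estimator, method=self.method))


def validate_config(raw: dict | None = None, **kwargs) -> RunConfig:
    """Build a RunConfig from raw option values, applying defaults.

    Unknown keys raise; out-of-range values raise ValueError with the same
    bounds the web tool documents (confidence in [10, 99], seed in
    [0, 1,000,000], method one of pwm/ml/mom).
    """
    options = dict(raw or {})
    options.update(kwargs)
    allowed = {
        "method", "confidence_level", "ci", "transform", "convergence",
        "seed", "bootstrap_replicates", "subsample_fraction", "estimator",
    }
    unknown = set(options) - allowed
    if unknown:
        raise ValueError(f"unknown options: {sorted(unknown)}")
    return RunConfig(**options)
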