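"""Sample-size / detection-rate simulation for two-group assays.

For each response variable, a pool of draws is simulated per plant line from
a normal distribution with the line's mean and standard deviation; draws
below the variable's minimum (zero, or the minimum duration of the probe
category) or above the maximum recording duration are rejected and redrawn.
Each Monte-Carlo iteration subsamples ``n`` replicates per line without
replacement and applies a two-sample Student's t-test per variable; an
iteration is significant when any variable's p-value falls below the
Bonferroni-corrected per-test alpha.  The detection rate is the percentage
of significant iterations.

Shipped presets parameterize the two case-study contrasts (M. persicae on
Arabidopsis Co-2 vs Sanna-2; N. ribisnigri biotype Nr:0 on lettuce Corbana
vs Terlana) from group means and standard errors of 8-h video assays; the
SDs are derived as SE * sqrt(n) from the printed per-variable sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSpec",
    "VariablePair",
    "PowerConfig",
    "PowerResult",
    "simulate_group",
    "detection_rate",
    "type1_rate",
    "duration_rescale",
    "RESCALE_POLICIES",
    "ARABIDOPSIS_VIDEO",
    "LETTUCE_VIDEO",
]

DEFAULT_LEVELS = (10, 15, 20, 25, 30, 35, 40)


@dataclass(frozen=True)
class GroupSpec:
    """Truncated-normal specification of one response variable in one line.

    ``mean``/``sd`` are in the units of the response variable (minutes for
    durations); ``lower_bound`` is the variable-specific minimum (0, or the
    category's minimum duration), ``upper_bound`` the maximum recording
    duration.
    """

    label: str
    mean: float
    sd: float
    lower_bound: float = 0.0
    upper_bound: float = 480.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if not self.lower_bound < self.upper_bound:
            raise ValueError("require lower_bound < upper_bound")

    @classmethod
    def from_se(
        cls, label: str, mean: float, se: float, n: int,
        lower_bound: float = 0.0, upper_bound: float = 480.0,
    ) -> "GroupSpec":
        """Build a spec from a group mean, its standard error, and n."""
        return cls(label, mean, se * math.sqrt(n), lower_bound, upper_bound)

    @property
    def acceptance_probability(self) -> float:
        a = stats.norm.cdf(self.lower_bound, self.mean, self.sd)
        b = stats.norm.cdf(self.upper_bound, self.mean, self.sd)
        return float(b - a)


@dataclass(frozen=True)
class VariablePair:
    """One response variable, specified for both plant lines."""

    name: str
    group_a: GroupSpec
    group_b: GroupSpec


@dataclass
class PowerConfig:
    variables: list[VariablePair]
    n_draws: int = 10_000
    iterations: int = 1000
    replicate_levels: tuple[int, ...] = DEFAULT_LEVELS
    alpha_per_test: float = 0.025
    equal_var: bool = True  # Student's t; False gives Welch
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha_per_test < 1):
            raise ValueError("alpha_per_test must be in (0, 1)")
        if max(self.replicate_levels) > self.n_draws:
            raise ValueError("replicate levels must not exceed the pool size")
        if not self.variables:
            raise ValueError("at least one variable pair required")


@dataclass
class PowerResult:
    """Detection rates per replicate level, with Monte-Carlo SEs and
    per-variable marginal rates, as a tidy frame."""

    table: pd.DataFrame
    config: PowerConfig

    def rate(self, level: int) -> float:
        row = self.table.loc[self.table["n"] == level]
        if row.empty:
            raise KeyError(f"replicate level {level} not simulated")
        return float(row["detection_rate"].iloc[0])

    def mc_se(self, level: int) -> float:
        row = self.table.loc[self.table["n"] == level]
        return float(row["mc_se"].iloc[0])


def simulate_group(
    spec: GroupSpec, n_draws: int = 10_000, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Rejection-sample ``n_draws`` accepted values from the truncated normal.

    Out-of-bounds draws are redrawn (the pool keeps its full size).  A
    degenerate spec whose acceptance probability is below 1% is refused.
    """
    if spec.acceptance_probability < 0.01:
        raise ValueError(
            f"acceptance probability {spec.acceptance_probability:.4f} < 1% "
            f"for spec {spec.label!r}"
        )
    rng = np.random.default_rng(rng)
    out = np.empty(n_draws)
    filled = 0
    while filled < n_draws:
        need = n_draws - filled
        batch = rng.normal(spec.mean, spec.sd, size=max(need * 2, 100))
        ok = batch[(batch >= spec.lower_bound) & (batch <= spec.upper_bound)]
        take = min(len(ok), need)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _ttest_matrix(a: np.ndarray, b: np.ndarray, equal_var: bool) -> np.ndarray:
    """Row-wise two-sample t-test p-values for (iterations, n) matrices."""
    return stats.ttest_ind(a, b, axis=1, equal_var=equal_var).pvalue


def _subsample(pool: np.ndarray, n: int, iterations: int, rng: np.random.Generator) -> np.ndarray:
    return np.stack(
        [pool[rng.choice(len(pool), size=n, replace=False)] for _ in range(iterations)]
    )


def detection_rate(config: PowerConfig, rng: np.random.Generator | None = None) -> PowerResult:
    """Monte-Carlo detection rate of the group contrast per replicate level."""
    rng = rng or np.random.default_rng(config.seed)
    pools = [
        (simulate_group(v.group_a, config.n_draws, rng),
         simulate_group(v.group_b, config.n_draws, rng))
        for v in config.variables
    ]
    rows = []
    for n in config.replicate_levels:
        any_sig = np.zeros(config.iterations, dtype=bool)
        marginals = {}
        for v, (pa, pb) in zip(config.variables, pools):
            a = _subsample(pa, n, config.iterations, rng)
            b = _subsample(pb, n, config.iterations, rng)
            p = _ttest_matrix(a, b, config.equal_var)
            sig = p < config.alpha_per_test
            any_sig |= sig
            marginals[f"rate_{v.name}"] = 100.0 * sig.mean()
        phat = any_sig.mean()
        rows.append(
            dict(
                n=n,
                detection_rate=100.0 * phat,
                mc_se=100.0 * math.sqrt(phat * (1 - phat) / config.iterations),
                **marginals,
            )
        )
    return PowerResult(table=pd.DataFrame(rows), config=config)


def type1_rate(
    specs: list[GroupSpec], config: PowerConfig | None = None, **kwargs
) -> PowerResult:
    """Detection rate under the null: both groups share one pool per variable.

    Each iteration draws 2n values without replacement from the variable's
    single pool and splits them into the two groups, so the null hypothesis
    holds exactly (exchangeability).  ``specs`` gives one GroupSpec per
    simulated variable.
    """
    if config is None:
        config = PowerConfig(
            variables=[VariablePair(s.label, s, s) for s in specs], **kwargs
        )
    rng = np.random.default_rng(config.seed)
    pools = [simulate_group(s, config.n_draws, rng) for s in specs]
    rows = []
    for n in config.replicate_levels:
        any_sig = np.zeros(config.iterations, dtype=bool)
        marginals = {}
        for i, (s, pool) in enumerate(zip(specs, pools)):
            both = _subsample(pool, 2 * n, config.iterations, rng)
            p = _ttest_matrix(both[:, :n], both[:, n:], config.equal_var)
            sig = p < config.alpha_per_test
            any_sig |= sig
            marginals[f"rate_{i}_{s.label}"] = 100.0 * sig.mean()
        phat = any_sig.mean()
        rows.append(
            dict(
                n=n,
                detection_rate=100.0 * phat,
                mc_se=100.0 * math.sqrt(phat * (1 - phat) / config.iterations),
                **marginals,
            )
        )
    return PowerResult(table=pd.DataFrame(rows), config=config)


# ---------------------------------------------------------------------------
# observation-duration rescaling


def _proportional(spec: GroupSpec, ratio: float) -> GroupSpec:
    return replace(
        spec,
        mean=spec.mean * ratio,
        sd=spec.sd * ratio,
        upper_bound=spec.upper_bound * ratio,
    )


def _sqrt_sd(spec: GroupSpec, ratio: float) -> GroupSpec:
    """Alternative policy: totals scale with time but their dispersion with
    sqrt(time), as for sums of roughly independent bout contributions."""
    return replace(
        spec,
        mean=spec.mean * ratio,
        sd=spec.sd * math.sqrt(ratio),
        upper_bound=spec.upper_bound * ratio,
    )


RESCALE_POLICIES = {"proportional": _proportional, "sqrt_sd": _sqrt_sd}


def duration_rescale(
    spec: GroupSpec,
    target_duration: float,
    source_duration: float,
    policy: str = "proportional",
) -> GroupSpec:
    """Rescale a spec from ``source_duration`` to a shorter observation.

    The default policy scales mean, sd and upper bound by
    target/source; the lower bound (a category minimum) is untouched.
    """
    if target_duration > source_duration:
        raise ValueError("target duration must not exceed the source duration")
    ratio = target_duration / source_duration
    out = RESCALE_POLICIES[policy](spec, ratio)
    if not out.lower_bound < out.upper_bound:
        raise ValueError("rescaled upper bound fell below the lower bound")
    return out


# ---------------------------------------------------------------------------
# presets: case-study video response variables (8-h observations, minutes)

ARABIDOPSIS_VIDEO = [
    VariablePair(
        "mean_long_probe_duration",
        GroupSpec.from_se("Co-2", 62.8, 7.0, 20, lower_bound=25.0, upper_bound=480.0),
        GroupSpec.from_se("Sanna-2", 90.0, 9.8, 17, lower_bound=25.0, upper_bound=480.0),
    ),
    VariablePair(
        "sustained_probe_total",
        GroupSpec.from_se("Co-2", 276.0, 27.0, 20, lower_bound=0.0, upper_bound=480.0),
        GroupSpec.from_se("Sanna-2", 353.0, 19.0, 17, lower_bound=0.0, upper_bound=480.0),
    ),
]

LETTUCE_VIDEO = [
    VariablePair(
        "sustained_probe_total",
        GroupSpec.from_se("Corbana", 132.0, 24.0, 27, lower_bound=0.0, upper_bound=480.0),
        GroupSpec.from_se("Terlana", 260.0, 25.0, 28, lower_bound=0.0, upper_bound=480.0),
    ),
    VariablePair(
        "mean_long_probe_duration",
        GroupSpec.from_se("Corbana", 72.4, 9.5, 21, lower_bound=25.0, upper_bound=480.0),
        GroupSpec.from_se("Terlana", 99.8, 11.2, 26, lower_bound=25.0, upper_bound=480.0),
    ),
]
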