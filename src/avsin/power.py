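"""Paired-design power analysis via the noncentral t distribution.

For a two-tailed paired t test on n participants with standardized mean
difference d, the test statistic under the alternative follows a noncentral
t distribution with df = n - 1 and noncentrality delta = d * sqrt(n);
achieved power is the probability that |T'| exceeds the two-tailed critical
value. ``required_n`` searches upward for the smallest n meeting a target
power (G*Power's "difference between two dependent means" calculation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """Specification for a paired two-dependent-means power calculation."""

    effect_size_d: float
    alpha: float = 0.05
    target_power: float = 0.90

    def __post_init__(self):
        if self.effect_size_d <= 0:
            raise ValueError("effect size d must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target power must be in (0, 1)")


def paired_t_power(n: int, spec: PowerSpec) -> float:
    """Achieved power of a two-tailed paired t test with ``n`` participants."""
    if n < 2:
        raise ValueError("need at least 2 participants")
    df = n - 1
    t_crit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    nc = spec.effect_size_d * np.sqrt(n)
    return float(
        stats.nct.sf(t_crit, df, nc) + stats.nct.cdf(-t_crit, df, nc)
    )


def required_n(spec: PowerSpec, n_max: int = 1_000_000) -> int:
    """Smallest n >= 2 with achieved power >= the target, by increment-and-check."""
    n = 2
    while paired_t_power(n, spec) < spec.target_power:
        n += 1
        if n > n_max:
            raise RuntimeError("sample-size search exceeded n_max")
    return n


def simulate_paired_t_power(
    n: int, spec: PowerSpec, n_reps: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo check of :func:`paired_t_power`.

    Draws ``n_reps`` samples of n standard-normal paired differences shifted
    by d and reports the two-tailed rejection rate. Used as an independent
    oracle in tests, not in the analytic path.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_reps, n)) + spec.effect_size_d
    t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
    t_crit = stats.t.ppf(1.0 - spec.alpha / 2.0, n - 1)
    return float(np.mean(np.abs(t) > t_crit))
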