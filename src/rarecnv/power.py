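"""Burden power calculations.

Converts a multiplicative case effect on a Poisson-distributed burden
metric (mean genes affected per rare CNV) into a standardized mean
difference using the control-group SD, and evaluates two-sample
normal-approximation power at a given case/control split.  The reference
calculation: a control mean of 2.2 genes per CNV with a case odds ratio of
1.21 gives 2.2 x 0.21 / sqrt(2.2) ~= 0.31 SD — the burden effect size
reported for schizophrenia, which a 7414/5044 study detects with power
1.0000, while a 0.05 SD difference is still detected with > 80% power at
alpha = 0.05 (one-sided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass
class PowerSpec:
    n_cases: int
    n_controls: int
    effect_sd: float
    alpha: float = 0.05
    sided: str = "one"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.effect_sd < 0:
            raise ValueError("effect_sd must be non-negative")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")


def poisson_effect_sd(control_mean: float, ratio: float) -> float:
    """Standardized difference implied by a multiplicative effect on a
    Poisson mean, using the control-group SD: m(r - 1) / sqrt(m)."""
    if control_mean <= 0 or ratio <= 0:
        raise ValueError("control_mean and ratio must be positive")
    return control_mean * (ratio - 1.0) / np.sqrt(control_mean)


def two_sample_power(spec: PowerSpec) -> float:
    """Normal-approximation power of the two-sample test of a standardized
    mean difference: Phi(delta / sqrt(1/n1 + 1/n2) - z_alpha)."""
    se = np.sqrt(1.0 / spec.n_cases + 1.0 / spec.n_controls)
    z_alpha = norm.ppf(1.0 - (spec.alpha / 2 if spec.sided == "two" else spec.alpha))
    return float(norm.cdf(spec.effect_sd / se - z_alpha))


def monte_carlo_power(spec: PowerSpec, n_sims: int = 100_000,
                      seed: int = 0) -> float:
    """Simulation check of :func:`two_sample_power` via two-sample z-tests on
    unit-variance normal samples."""
    rng = np.random.default_rng(seed)
    se = np.sqrt(1.0 / spec.n_cases + 1.0 / spec.n_controls)
    # the two-sample mean difference is sufficient; simulate it directly
    diff = rng.normal(spec.effect_sd, se, size=n_sims)
    z = diff / se
    if spec.sided == "one":
        rejected = z > norm.ppf(1.0 - spec.alpha)
    else:
        rejected = np.abs(z) > norm.ppf(1.0 - spec.alpha / 2)
    return float(rejected.mean())


def power_grid(n_cases: int = 7414, n_controls: int = 5044,
               effects=(0.05, 0.1, 0.2, 0.3), alpha: float = 0.05,
               sided: str = "one"):
    """Analytic power over a grid of standardized effects (rows of dicts)."""
    rows = []
    for eff in effects:
        spec = PowerSpec(n_cases, n_controls, eff, alpha, sided)
        rows.append({"n_cases": n_cases, "n_controls": n_controls,
                     "effect_sd": eff, "alpha": alpha, "sided": sided,
                     "power": two_sample_power(spec)})
    return rows
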