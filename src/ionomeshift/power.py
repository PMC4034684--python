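"""Prospective and post-hoc statistical power for small-effect detection.

Post-hoc power is what separates "no effect" from "no power to see the
effect": a 5% concentration change standardized against a 25% SD gives
Cohen's d = 0.2, and a t test at the replicate counts typical of CO2
experiments (3-5 per group) then has power below 0.10.  Two safeguards are
implemented: an SD floor for small samples (the sample SD of a small slice
underestimates the population SD, inflating d and the apparent power), and
a non-parametric bootstrap power that mirrors the bootstrap CI test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .effects import EffectSize

__all__ = [
    "PowerSpec",
    "PowerResult",
    "conservative_sd",
    "analytic_power",
    "bootstrap_power",
    "power_curve",
    "SD_FLOOR",
    "SD_FLOOR_THRESHOLD",
]

#: Dataset-wide SD of mineral log effects, used as the conservative floor.
SD_FLOOR = 0.21
#: Sample sizes below this use the SD floor.
SD_FLOOR_THRESHOLD = 20


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a power calculation.

    ``effect`` is the absolute effect size on the proportion scale
    (default 0.05 = a 5% concentration change); ``sample_size`` is m for
    the one-sample test or n per group for the two-sample test.
    """

    sd: float
    sample_size: int
    effect: float = 0.05
    alpha: float = 0.05
    test: str = "two_sample_t"   # "one_sample_t" | "two_sample_t"
    sides: str = "two"           # "one" | "two"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2")
        if self.test not in ("one_sample_t", "two_sample_t"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.sides not in ("one", "two"):
            raise ValueError(f"sides must be 'one' or 'two'")


@dataclass(frozen=True)
class PowerResult:
    power: float
    d: float
    sd_used: float
    floored: bool
    method: str  # "noncentral_t" | "bootstrap_mc"
    flags: tuple[str, ...] = ()


def conservative_sd(sample_sd: float, m: int, floor: float = SD_FLOOR,
                    threshold: int = SD_FLOOR_THRESHOLD) -> tuple[float, bool]:
    """SD with the small-sample floor applied.

    For m below *threshold* the sample SD of a slice can badly
    underestimate the population SD, overstating Cohen's d and the power;
    the floor substitutes the dataset-wide SD when it is larger.  Returns
    ``(sd_used, floored)``.
    """
    if sample_sd < 0:
        raise ValueError("sample_sd must be non-negative")
    if m < threshold and sample_sd < floor:
        return floor, True
    return sample_sd, False


def analytic_power(spec: PowerSpec, floored: bool = False) -> PowerResult:
    """Power of the t test from the noncentral t distribution.

    One-sample: ncp = d*sqrt(m), df = m - 1.  Two-sample (equal groups of
    n): ncp = d*sqrt(n/2), df = 2n - 2.  Two-sided power sums both
    rejection tails.
    """
    d = spec.effect / spec.sd
    n = spec.sample_size
    if spec.test == "one_sample_t":
        df = n - 1
        ncp = d * math.sqrt(n)
    else:
        df = 2 * n - 2
        ncp = d * math.sqrt(n / 2.0)
    def ncdf(x):
        # scipy's noncentral-t cdf can go NaN deep in the tails; the
        # shifted-normal value is exact enough there
        v = stats.nct.cdf(x, df, ncp)
        return float(v) if np.isfinite(v) else float(stats.norm.cdf(x - ncp))

    if spec.sides == "two":
        tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
        power = (1.0 - ncdf(tcrit)) + ncdf(-tcrit)
    else:
        tcrit = stats.t.ppf(1.0 - spec.alpha, df)
        power = 1.0 - ncdf(tcrit)
    return PowerResult(power=float(np.clip(power, 0.0, 1.0)), d=d,
                       sd_used=spec.sd, floored=floored,
                       method="noncentral_t")


def bootstrap_power(effects: Sequence[EffectSize], effect: float = 0.05,
                    B_outer: int = 500, B_inner: int = 999,
                    seed: int | np.random.Generator | None = None,
                    alpha: float = 0.05,
                    sd_floor: float | None = SD_FLOOR,
                    floor_threshold: int = SD_FLOOR_THRESHOLD) -> PowerResult:
    """Monte-Carlo power of the percentile-bootstrap test of mean = 0.

    The observed log effects are re-centred so their mean equals *effect*
    (the alternative to detect); when the SD floor applies (m below
    *floor_threshold* and sample SD below *sd_floor*) the residuals are
    rescaled to the floor SD first.  Each outer replicate resamples m
    values with replacement and rejects when the inner percentile-bootstrap
    CI of the mean excludes zero; the returned power is the rejection
    fraction.  Seed-reproducible.
    """
    x = np.array([e.log_ratio for e in effects], dtype=float)
    m = len(x)
    if m < 2:
        raise ValueError("bootstrap power needs m >= 2")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    sample_sd = float(x.std(ddof=1))
    if np.ptp(x) == 0.0:
        sample_sd = 0.0
    if sample_sd == 0.0:
        # degenerate slice: every resample equals `effect`, so the test
        # rejects whenever the alternative is non-zero
        power = 1.0 if abs(effect) > 0 else alpha
        sd_used = sd_floor if (sd_floor is not None and m < floor_threshold) \
            else sample_sd
        d = float("inf") if sample_sd == 0 and abs(effect) > 0 else 0.0
        if sd_used and sd_used > 0:
            d = effect / sd_used
        return PowerResult(power=power, d=d, sd_used=sd_used or 0.0,
                           floored=sd_used != sample_sd,
                           method="bootstrap_mc", flags=("degenerate",))
    resid = x - x.mean()
    floored = False
    sd_used = sample_sd
    if sd_floor is not None:
        sd_used, floored = conservative_sd(sample_sd, m, sd_floor,
                                           floor_threshold)
        if floored:
            resid = resid * (sd_used / sample_sd)
    pop = resid + effect

    rejections = 0
    chunk = max(1, int(2_000_000 // max(1, B_inner * m)))
    done = 0
    while done < B_outer:
        k = min(chunk, B_outer - done)
        samples = pop[rng.integers(0, m, size=(k, m))]
        inner_idx = rng.integers(0, m, size=(k, B_inner, m))
        boot_means = np.take_along_axis(
            samples[:, None, :], inner_idx, axis=2).mean(axis=2)
        lo = np.quantile(boot_means, alpha / 2.0, axis=1)
        hi = np.quantile(boot_means, 1.0 - alpha / 2.0, axis=1)
        rejections += int(np.sum((lo > 0) | (hi < 0)))
        done += k
    return PowerResult(power=rejections / B_outer, d=effect / sd_used,
                       sd_used=sd_used, floored=floored,
                       method="bootstrap_mc")


def power_curve(effect_grid: Sequence[float], spec_template: PowerSpec):
    """Elementwise analytic power over a grid of effect sizes.

    Returns a list of ``(effect, PowerResult)`` pairs; power is monotone
    non-decreasing in ``|effect|`` and in sample size.
    """
    out = []
    for eff in effect_grid:
        spec = replace(spec_template, effect=abs(float(eff)))
        out.append((float(eff), analytic_power(spec)))
    return out
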