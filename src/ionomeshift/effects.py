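"""Effect sizes and pooled estimates with t and bootstrap confidence intervals.

The effect-size metric is the natural log of the response ratio,
``ln r`` with ``r = E/A = 1 + (E - A)/A``: symmetric between declines and
increases, which removes the bias toward increases that a raw percentage
scale carries (a decline is bounded at -100% while an increase is not).
All pooling happens on the log scale; only final reporting back-transforms
to ordinary percent change via ``100 * (exp(mean_log) - 1)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectSize",
    "PooledMean",
    "CategorySummary",
    "to_effect",
    "to_effects",
    "back_transform",
    "pooled_mean",
    "t_interval",
    "bootstrap_interval",
    "summaries_to_frame",
    "export_summaries",
]


@dataclass(frozen=True)
class EffectSize:
    """A log response ratio with its replicate count."""

    log_ratio: float
    n_replicates: int = 1
    source_id: str = ""

    def __post_init__(self):
        if not math.isfinite(self.log_ratio):
            raise ValueError(f"log_ratio must be finite, got {self.log_ratio}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class PooledMean:
    mean_log: float
    se_log: float
    m: int
    weighted: bool


@dataclass
class CategorySummary:
    """Pooled result for one data slice, reported on the percent scale.

    ``m`` counts mean observations (one per study x element); ``n_total``
    additionally counts within-study replicates.
    """

    label: str
    m: int
    n_total: int
    mean_pct_change: float
    ci_low: float
    ci_high: float
    ci_method: str  # "t" | "bootstrap"
    p_value: float | None = None
    power: float | None = None
    weighted: bool = False
    t_ci_low: float | None = None
    t_ci_high: float | None = None
    mean_log: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.m >= 1 and not (
            self.ci_low - 1e-9 <= self.mean_pct_change <= self.ci_high + 1e-9
        ):
            raise ValueError("CI must bracket the mean percent change")


def to_effect(record) -> EffectSize:
    """Convert an observation's relative change to a log response ratio."""
    rc = record.relative_change
    if rc is None or not rc > -1:
        raise ValueError(
            f"relative_change must exceed -1, got {rc!r} "
            f"(study {getattr(record, 'study_id', '?')})"
        )
    return EffectSize(
        log_ratio=math.log1p(rc),
        n_replicates=int(record.n_replicates),
        source_id=str(record.study_id),
    )


def to_effects(data) -> list[EffectSize]:
    """Vectorised :func:`to_effect` over a Dataset or canonical DataFrame."""
    frame = data.frame if hasattr(data, "frame") else data
    rc = frame["relative_change"].to_numpy(dtype=float)
    if np.any(rc <= -1):
        bad = np.nonzero(rc <= -1)[0]
        raise ValueError(f"relative_change <= -1 at rows {bad.tolist()}")
    logs = np.log1p(rc)
    ns = frame["n_replicates"].to_numpy()
    ids = frame["study_id"].astype(str).to_numpy()
    return [EffectSize(float(l), int(n), s) for l, n, s in zip(logs, ns, ids)]


def back_transform(mean_log: float) -> float:
    """Convert a mean log response ratio to an ordinary percent change."""
    return 100.0 * math.expm1(mean_log)


def _arrays(effects: Sequence[EffectSize]):
    x = np.array([e.log_ratio for e in effects], dtype=float)
    n = np.array([e.n_replicates for e in effects], dtype=float)
    return x, n


def pooled_mean(effects: Sequence[EffectSize], weighted: bool = False) -> PooledMean:
    """Pooled mean log effect with its standard error.

    Unweighted: arithmetic mean, SE = sd / sqrt(m).  Weighted: replicate
    weights w_i = n_i / sum(n), mean = sum(w x); SE from the normalized
    reliability-weights variance s_w^2 = sum(w (x - xbar_w)^2) / (1 - sum w^2),
    SE = s_w * sqrt(sum w^2).  Replicate weighting is used instead of
    inverse-variance weighting because many primary studies report no
    variance measure.
    """
    if len(effects) == 0:
        raise ValueError("cannot pool an empty collection of effects")
    x, n = _arrays(effects)
    m = len(x)
    if not weighted:
        mean = float(x.mean())
        se = float(x.std(ddof=1) / math.sqrt(m)) if m > 1 else float("nan")
        return PooledMean(mean, se, m, weighted=False)
    w = n / n.sum()
    mean = float(np.sum(w * x))
    sumw2 = float(np.sum(w ** 2))
    if m > 1 and sumw2 < 1.0:
        s2 = float(np.sum(w * (x - mean) ** 2) / (1.0 - sumw2))
        se = math.sqrt(s2 * sumw2)
    else:
        se = float("nan")
    return PooledMean(mean, se, m, weighted=True)


def t_interval(effects: Sequence[EffectSize], confidence: float = 0.95,
               label: str = "", weighted: bool = False) -> CategorySummary:
    """Parametric (one-sample t) CI on the mean log effect, in percent.

    The p-value is the two-sided one-sample t test of mean log effect = 0.
    """
    if len(effects) < 2:
        raise ValueError("t interval needs m >= 2 (no variance estimate)")
    pm = pooled_mean(effects, weighted=weighted)
    x, n = _arrays(effects)
    df = pm.m - 1
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df)
    lo = pm.mean_log - tcrit * pm.se_log
    hi = pm.mean_log + tcrit * pm.se_log
    if pm.se_log > 0:
        tstat = pm.mean_log / pm.se_log
        p = float(2 * stats.t.sf(abs(tstat), df))
    else:
        p = 0.0 if pm.mean_log != 0 else 1.0
    return CategorySummary(
        label=label, m=pm.m, n_total=int(n.sum()),
        mean_pct_change=back_transform(pm.mean_log),
        ci_low=back_transform(lo), ci_high=back_transform(hi),
        ci_method="t", p_value=p, weighted=weighted, mean_log=pm.mean_log,
    )


def bootstrap_interval(effects: Sequence[EffectSize], B: int = 10_000,
                       seed: int | np.random.Generator | None = None,
                       confidence: float = 0.95, label: str = "",
                       weighted: bool = False) -> CategorySummary:
    """Percentile-bootstrap CI of the mean log effect (B resamples).

    The p-value is the smallest two-sided level at which the percentile
    interval excludes zero, on the 1/B grid.  Identical seed and inputs
    give identical output.
    """
    if len(effects) < 2:
        raise ValueError("bootstrap interval needs m >= 2")
    if B < 100:
        import warnings

        warnings.warn(f"B = {B} < 100 resamples violates the resampling "
                      "contract; results will be unstable", stacklevel=2)
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    x, n = _arrays(effects)
    m = len(x)
    idx = rng.integers(0, m, size=(B, m))
    if weighted:
        wts = n[idx]
        boots = np.sum(wts * x[idx], axis=1) / wts.sum(axis=1)
    else:
        boots = x[idx].mean(axis=1)
    alpha = 1.0 - confidence
    lo, hi = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])
    pm = pooled_mean(effects, weighted=weighted)
    flags = ()
    if np.ptp(x) == 0:
        lo = hi = pm.mean_log
        flags = ("degenerate",)
    # smallest alpha on the 1/B grid whose percentile CI excludes 0
    frac_le = np.mean(boots <= 0)
    frac_ge = np.mean(boots >= 0)
    p = min(1.0, max(2.0 * min(frac_le, frac_ge), 1.0 / B))
    return CategorySummary(
        label=label, m=m, n_total=int(n.sum()),
        mean_pct_change=back_transform(pm.mean_log),
        ci_low=back_transform(float(lo)), ci_high=back_transform(float(hi)),
        ci_method="bootstrap", p_value=float(p), weighted=weighted,
        mean_log=pm.mean_log, flags=flags,
    )


def summaries_to_frame(summaries: Iterable[CategorySummary]) -> pd.DataFrame:
    """Tabulate summaries in the figure source-data layout."""
    rows = []
    for s in summaries:
        rows.append({
            "label": s.label, "m": s.m, "n_total": s.n_total,
            "mean_pct_change": s.mean_pct_change,
            "ci_low": s.ci_low, "ci_high": s.ci_high,
            "ci_method": s.ci_method, "p_value": s.p_value,
            "power": s.power, "weighted": s.weighted,
            "t_ci_low": s.t_ci_low, "t_ci_high": s.t_ci_high,
            "flags": ";".join(s.flags),
        })
    return pd.DataFrame(rows)


def export_summaries(summaries: Iterable[CategorySummary], path,
                     fmt: str = "csv") -> None:
    frame = summaries_to_frame(summaries)
    if fmt == "csv":
        frame.to_csv(path, index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(frame.to_dict(orient="records"), fh, indent=1)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
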