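"""Publication-bias ("file drawer") diagnostics via the funnel construction.

Effect sizes are plotted against their replicate counts: with no selective
publication the cloud is funnel-shaped — wide at small n, narrowing toward
large n — and symmetric about the mean effect.  The visual check is
supplemented here by two quantitative diagnostics, clearly labelled as
additions to the original visual assessment: a two-sided sign test on the
counts above/below the mean line, and a Begg-style rank correlation between
the absolute deviation from the mean and 1/n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import effects as eff
from .dataset import Dataset, NON_MINERALS
from .effects import EffectSize

__all__ = ["FunnelPoint", "FunnelResult", "AsymmetryReport",
           "funnel_data", "asymmetry_check"]

#: Minimum number of points for the rank correlation to be reported.
MIN_POINTS_FOR_CORRELATION = 10


@dataclass(frozen=True)
class FunnelPoint:
    effect: float          # log response ratio
    n_replicates: int
    label: str = ""

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class FunnelResult:
    points: list[FunnelPoint]
    mean_log: float        # the mean line, on the log scale
    mean_pct: float        # the same, back-transformed to percent

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"effect": p.effect, "n_replicates": p.n_replicates,
              "label": p.label} for p in self.points]
        )


@dataclass
class AsymmetryReport:
    """Quantitative funnel diagnostics (supplements to the visual check)."""

    above_count: int
    below_count: int
    sign_test_p: float | None = None
    rank_corr: float | None = None
    rank_corr_p: float | None = None
    note: str = ("sign test and rank correlation are quantitative "
                 "supplements to the visual funnel evaluation")

    def as_dict(self) -> dict:
        return {
            "above_count": self.above_count,
            "below_count": self.below_count,
            "sign_test_p": self.sign_test_p,
            "rank_corr": self.rank_corr,
            "rank_corr_p": self.rank_corr_p,
            "note": self.note,
        }


def _default_scope(frame: pd.DataFrame) -> pd.Series:
    """Minerals in C3 plants — the scope of the published funnel."""
    return (~frame["element"].isin(list(NON_MINERALS))) & \
        (frame["pathway"].fillna("C3") != "C4")


def funnel_data(data: Dataset | pd.DataFrame,
                scope: Callable[[pd.DataFrame], pd.Series] | None = None
                ) -> FunnelResult:
    """Build funnel points (one per study x mineral) and the mean line.

    The mean line is the grand unweighted mean log effect over the scope,
    identical by construction to the unweighted pooled mean; it is also
    reported back-transformed to percent.
    """
    frame = data.frame if isinstance(data, Dataset) else data
    mask = scope(frame) if scope is not None else _default_scope(frame)
    sub = frame[mask]
    if len(sub) < 2:
        raise ValueError("funnel scope must select at least 2 records")
    effs = eff.to_effects(sub)
    labels = (sub["study_id"].astype(str) + ":" + sub["element"].astype(str))
    points = [FunnelPoint(e.log_ratio, e.n_replicates, lab)
              for e, lab in zip(effs, labels)]
    mean_log = eff.pooled_mean(effs, weighted=False).mean_log
    return FunnelResult(points=points, mean_log=mean_log,
                        mean_pct=eff.back_transform(mean_log))


def asymmetry_check(points: Sequence[FunnelPoint]) -> AsymmetryReport:
    """Quantify funnel asymmetry about the mean line.

    Counts points above/below the mean effect and, when at least
    10 points are available, runs a two-sided sign test on those counts
    and a Begg-style Kendall rank correlation between the standardized
    deviations ``(effect - mean) * sqrt(n)`` and ``1/n`` (with variances
    unavailable, 1/n proxies the sampling variance; standardizing removes
    the funnel's own spread-vs-n dependence, so a symmetric funnel gives
    tau ~ 0 while small-study effects push tau away from zero).
    Invariant under adding a constant to every effect.
    """
    x = np.array([p.effect for p in points], dtype=float)
    n = np.array([p.n_replicates for p in points], dtype=float)
    mean = x.mean()
    above = int(np.sum(x > mean))
    below = int(np.sum(x < mean))
    report = AsymmetryReport(above_count=above, below_count=below)
    if len(points) < MIN_POINTS_FOR_CORRELATION:
        return report
    report.sign_test_p = float(
        stats.binomtest(above, above + below, 0.5).pvalue
    ) if (above + below) > 0 else None
    tau = stats.kendalltau((x - mean) * np.sqrt(n), 1.0 / n)
    report.rank_corr = float(tau.statistic)
    report.rank_corr_p = float(tau.pvalue)
    return report
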