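"""Category fragmentation, per-slice summaries, and the power gate.

Fragmenting the compiled observations into categories (element, tissue,
plant group, experiment type, crop, country, latitude band) is only
informative where the resulting slice retains adequate statistical power;
slices are therefore summarised together with their post-hoc power for a
5% effect, and headline reporting is gated at power > 0.40.  The gate
affects reporting only — every computed summary is retained in the full
export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import effects as eff
from . import power as pw
from .dataset import Dataset, NON_MINERALS
from .effects import CategorySummary, EffectSize

__all__ = [
    "DIMENSIONS",
    "CategoryKey",
    "GateReport",
    "assign_region",
    "slice_effects",
    "summarize_category",
    "gate_by_power",
    "CROP_NAME_REGISTRY",
]

#: Latitude boundary (degrees) between tropics/subtropics and temperate.
REGION_BOUNDARY = 35.0

DIMENSIONS = (
    "element", "tissue", "plant_group", "experiment_type", "crop_name",
    "country", "region", "ionome",
)

#: Cultivar-to-common-name registry for crop grouping (e.g. every
#: Oryza sativa cultivar is "rice").  Extend as needed.
CROP_NAME_REGISTRY = {
    "Oryza sativa": "rice",
    "Triticum aestivum": "wheat",
    "Hordeum vulgare": "barley",
    "Solanum tuberosum": "potato",
    "Glycine max": "soybean",
    "Zea mays": "maize",
    "Lactuca sativa": "lettuce",
    "Raphanus sativus": "radish",
    "Brassica napus": "rapeseed",
    "Lycopersicon esculentum": "tomato",
    "Solanum lycopersicum": "tomato",
}

_PLANT_GROUPS = ("woody", "herbaceous", "wild", "crop", "C3", "C4")


@dataclass(frozen=True)
class CategoryKey:
    """A slicing instruction: which dimension, which value.

    The "ionome" dimension aggregates every mineral (all elements except
    C and N) and takes no value.
    """

    dimension: str
    value: str | None = None

    def __post_init__(self):
        if self.dimension not in DIMENSIONS:
            raise ValueError(
                f"unknown dimension {self.dimension!r}; valid: "
                f"{', '.join(DIMENSIONS)}"
            )


@dataclass
class GateReport:
    """Partition of summaries into power-gated included/excluded sets."""

    included: list[CategorySummary] = field(default_factory=list)
    excluded: list[CategorySummary] = field(default_factory=list)
    threshold: float = 0.40

    @property
    def all_summaries(self) -> list[CategorySummary]:
        return list(self.included) + list(self.excluded)


def assign_region(latitude: float | None,
                  boundary: float = REGION_BOUNDARY) -> str:
    """Classify a latitude as tropical/subtropical or temperate.

    The boundary (35 degrees N/S) is inclusive on the tropical side.
    Missing latitude -> "unclassified".
    """
    if latitude is None or (isinstance(latitude, float) and np.isnan(latitude)):
        return "unclassified"
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    return "tropical_subtropical" if abs(latitude) <= boundary else "temperate"


def _common_name(frame: pd.DataFrame) -> pd.Series:
    mapped = frame["species"].map(CROP_NAME_REGISTRY)
    return mapped.fillna(frame["common_name"])


def _mask_for(frame: pd.DataFrame, key: CategoryKey) -> pd.Series:
    d, v = key.dimension, key.value
    if d == "element":
        return frame["element"] == v
    if d == "ionome":
        return ~frame["element"].isin(["C", "N"])
    if d == "tissue":
        return frame["tissue"] == v
    if d == "experiment_type":
        if v == "FACE":
            return frame["facility"] == "FACE"
        if v in ("non_FACE", "non-FACE"):
            return frame["facility"] != "FACE"
        return frame["facility"] == v
    if d == "crop_name":
        return _common_name(frame) == v
    if d == "country":
        return frame["country"] == v
    if d == "region":
        regions = frame["latitude"].map(lambda x: assign_region(
            None if pd.isna(x) else float(x)))
        return regions == v
    if d == "plant_group":
        if v in ("woody", "herbaceous"):
            return frame["growth_form"] == v
        if v in ("wild", "crop"):
            return frame["wild_or_crop"] == v
        if v in ("C3", "C4"):
            return frame["pathway"] == v
        raise ValueError(f"unknown plant_group value {v!r}; "
                         f"valid: {', '.join(_PLANT_GROUPS)}")
    raise ValueError(f"unknown dimension {d!r}")


def slice_effects(data: Dataset | pd.DataFrame, key: CategoryKey,
                  filters: Iterable[Callable[[pd.DataFrame], pd.Series]] | None = None,
                  minerals_only: bool = False) -> list[EffectSize]:
    """Select the effect sizes belonging to one category slice.

    Conventions baked in: summaries are for C3 plants, so C4 records are
    excluded from every slice except an explicit plant_group=C4 slice;
    geographic slices (country, region) keep only FACE and OTC facilities,
    which reflect the local environment, dropping complete enclosures;
    crop-group, country and region slices pool minerals only (set
    ``minerals_only`` for other dimensions as needed).
    """
    frame = data.frame if isinstance(data, Dataset) else data
    mask = _mask_for(frame, key)
    if not (key.dimension == "plant_group" and key.value == "C4"):
        mask &= frame["pathway"].fillna("C3") != "C4"
    if key.dimension in ("region", "country"):
        mask &= frame["facility"].isin(["FACE", "OTC"])
    if minerals_only or key.dimension in ("crop_name", "country", "region"):
        mask &= ~frame["element"].isin(list(NON_MINERALS))
    sub = frame[mask]
    if filters:
        for f in filters:
            sub = sub[f(sub)]
    return eff.to_effects(sub)


def summarize_category(effects: Sequence[EffectSize],
                       seed: int | np.random.Generator | None = None,
                       label: str = "", B: int = 10_000,
                       power_effect: float = 0.05,
                       B_outer: int = 500, B_inner: int = 999) -> CategorySummary:
    """Full per-slice summary: bootstrap CI, t CI, and bootstrap power.

    The reported CI and p-value come from the percentile bootstrap (the
    non-parametric route); the t-interval endpoints ride along for
    comparison.  Power is the bootstrap Monte-Carlo power for a 5% effect
    with the small-sample SD floor.  Slices with m < 2 are flagged
    "insufficient" instead of raising.
    """
    m = len(effects)
    if m < 2:
        n_total = sum(e.n_replicates for e in effects)
        mean = eff.back_transform(effects[0].log_ratio) if m == 1 else 0.0
        return CategorySummary(
            label=label, m=m, n_total=n_total, mean_pct_change=mean,
            ci_low=mean, ci_high=mean, ci_method="bootstrap",
            flags=("insufficient",),
        )
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    boot = eff.bootstrap_interval(effects, B=B, seed=rng, label=label)
    tsum = eff.t_interval(effects, label=label)
    presult = pw.bootstrap_power(effects, effect=power_effect,
                                 B_outer=B_outer, B_inner=B_inner, seed=rng)
    boot.t_ci_low = tsum.ci_low
    boot.t_ci_high = tsum.ci_high
    boot.power = presult.power
    if presult.floored:
        boot.flags = boot.flags + ("sd_floored",)
    if "degenerate" in presult.flags and "degenerate" not in boot.flags:
        boot.flags = boot.flags + ("degenerate",)
    return boot


def gate_by_power(summaries: Iterable[CategorySummary],
                  threshold: float = 0.40) -> GateReport:
    """Partition summaries by post-hoc power > *threshold*.

    Included and excluded are disjoint and their union is the input;
    excluded summaries stay available for the full (ungated) export.
    """
    report = GateReport(threshold=threshold)
    for s in summaries:
        if s.power is not None and s.power > threshold:
            report.included.append(s)
        else:
            report.excluded.append(s)
    return report
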