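"""Canonical observation schema, CSV I/O, validation and data-inclusion rules.

One row of the dataset is one study x element measurement: the relative
change in the mean concentration of a chemical element between plants grown
at ambient and at elevated CO2, together with the replicate count and the
category metadata (tissue, facility type, photosynthetic pathway, location)
that the downstream fragmentation analysis slices on.

The stored effect quantity is the dimensionless relative change
``(E - A) / A`` where ``A`` and ``E`` are the mean concentrations at ambient
and elevated CO2.  Paired absolute concentrations are optional and, when
present, are cross-checked against the stored relative change.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ELEMENT_REGISTRY",
    "MINERAL_ELEMENTS",
    "NON_MINERALS",
    "CANONICAL_COLUMNS",
    "MANDATORY_COLUMNS",
    "ObservationRecord",
    "Dataset",
    "RowDiagnostic",
    "SchemaError",
    "UnresolvedGroupError",
    "CheckLine",
    "ValidationReport",
    "read_dataset",
    "write_dataset",
    "validate_frame",
    "validate_against_printed_counts",
    "apply_inclusion_rules",
    "is_mineral",
]

# Elements C and N plus the 25 minerals tracked by the analysis.  "Mineral"
# is operationally every element except C, H, O and N.
NON_MINERALS = frozenset({"C", "H", "O", "N"})
MINERAL_ELEMENTS = (
    "P", "K", "Ca", "S", "Mg", "Fe", "Zn", "Cu", "Mn", "Na", "B", "Mo",
    "Ni", "Co", "Al", "Si", "Se", "Cd", "Cr", "Sr", "Ba", "V", "Pb", "I",
    "Li",
)
ELEMENT_REGISTRY = frozenset({"C", "N", *MINERAL_ELEMENTS})

TISSUES = ("foliar", "edible")
TISSUE_SUBTYPES = (
    "leaf", "needle", "shoot", "aboveground", "grain", "tuber", "fruit",
    "vegetable", "other",
)
FACILITIES = ("FACE", "OTC", "chamber", "greenhouse", "other_enclosure")
PATHWAYS = ("C3", "C4")
GROWTH_FORMS = ("woody", "herbaceous")
WILD_OR_CROP = ("wild", "crop")

#: Column order of the canonical CSV layout.
CANONICAL_COLUMNS = (
    "study_id", "species", "cultivar", "common_name", "is_crop", "pathway",
    "growth_form", "wild_or_crop", "tissue", "tissue_subtype", "element",
    "facility", "country", "latitude", "longitude", "co2_ambient",
    "co2_elevated", "n_replicates", "relative_change", "conc_ambient",
    "conc_elevated", "cofactor", "time_point_index", "n_time_points",
    "nutrient_regime", "leaf_age", "notes",
)

MANDATORY_COLUMNS = (
    "study_id", "species", "tissue", "element", "facility",
    "co2_ambient", "co2_elevated", "n_replicates", "relative_change",
)

_NUMERIC_COLUMNS = (
    "latitude", "longitude", "co2_ambient", "co2_elevated",
    "relative_change", "conc_ambient", "conc_elevated",
)
_INT_COLUMNS = ("n_replicates", "time_point_index", "n_time_points",
                "nutrient_regime", "leaf_age")


def is_mineral(element: str) -> bool:
    """True when *element* counts as a mineral (not C, H, O or N)."""
    return element not in NON_MINERALS


class SchemaError(ValueError):
    """A mandatory column is missing or unmappable."""


class UnresolvedGroupError(ValueError):
    """A co-dependent group cannot be resolved: an annotation is missing."""

    def __init__(self, group_key, missing_field: str):
        self.group_key = group_key
        self.missing_field = missing_field
        super().__init__(
            f"group {group_key!r} cannot be resolved: missing annotation "
            f"{missing_field!r}"
        )


@dataclass(frozen=True)
class RowDiagnostic:
    """A row-level validation failure (row index + human-readable message)."""

    row: int
    message: str


@dataclass
class ObservationRecord:
    """One study x element observation of a CO2 response.

    ``relative_change`` is (E - A)/A on the concentration scale; it must
    exceed -1 because a concentration cannot decline by 100% or more.
    """

    study_id: str
    species: str
    tissue: str
    element: str
    facility: str
    co2_ambient: float
    co2_elevated: float
    n_replicates: int
    relative_change: float
    cultivar: str | None = None
    common_name: str | None = None
    is_crop: bool | None = None
    pathway: str | None = None
    growth_form: str | None = None
    wild_or_crop: str | None = None
    tissue_subtype: str | None = None
    country: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    conc_ambient: float | None = None
    conc_elevated: float | None = None
    cofactor: str | None = None
    time_point_index: int | None = None
    n_time_points: int | None = None
    nutrient_regime: int | None = None
    leaf_age: int | None = None
    notes: str | None = None


def _record_to_row(rec: ObservationRecord) -> dict:
    return {c: getattr(rec, c) for c in CANONICAL_COLUMNS}


def _row_to_record(row: pd.Series) -> ObservationRecord:
    kwargs = {}
    for c in CANONICAL_COLUMNS:
        v = row.get(c)
        if v is None or (isinstance(v, float) and math.isnan(v)) or (
            isinstance(v, str) and v == ""
        ) or v is pd.NA:
            v = None
        kwargs[c] = v
    for c in _INT_COLUMNS:
        if kwargs[c] is not None:
            kwargs[c] = int(kwargs[c])
    for c in _NUMERIC_COLUMNS:
        if kwargs[c] is not None:
            kwargs[c] = float(kwargs[c])
    if kwargs["is_crop"] is not None:
        kwargs["is_crop"] = _as_bool(kwargs["is_crop"])
    return ObservationRecord(**kwargs)


def _as_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in {"true", "1", "yes", "y"}


class Dataset:
    """An ordered, validated collection of observation records.

    Internally a pandas DataFrame with the canonical column layout;
    ``records`` materialises :class:`ObservationRecord` objects on demand.
    """

    schema_version = "1"

    def __init__(self, frame: pd.DataFrame, provenance: str = "loaded",
                 diagnostics: Sequence[RowDiagnostic] = ()):  # noqa: D401
        frame = frame.copy()
        for c in CANONICAL_COLUMNS:
            if c not in frame.columns:
                frame[c] = None
        self.frame = frame[list(CANONICAL_COLUMNS)].reset_index(drop=True)
        self.provenance = provenance
        self.diagnostics = list(diagnostics)

    @classmethod
    def from_records(cls, records: Iterable[ObservationRecord],
                     provenance: str = "loaded") -> "Dataset":
        rows = [_record_to_row(r) for r in records]
        frame = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
        return cls(frame, provenance=provenance)

    @property
    def records(self) -> list[ObservationRecord]:
        return [_row_to_record(row) for _, row in self.frame.iterrows()]

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.records == other.records

    def subset(self, mask) -> "Dataset":
        return Dataset(self.frame[mask], provenance=self.provenance)


def validate_frame(frame: pd.DataFrame) -> tuple[pd.DataFrame, list[RowDiagnostic]]:
    """Split *frame* into valid rows and row-indexed diagnostics.

    Checks the record invariants: CO2 ordering, relative_change > -1,
    replicate count >= 1, element membership in the registry, coordinate
    ranges, and consistency of paired concentrations with the stored
    relative change (tolerance 1e-6).
    """
    diagnostics: list[RowDiagnostic] = []
    keep = np.ones(len(frame), dtype=bool)
    for i, (_, row) in enumerate(frame.iterrows()):
        msgs = _row_problems(row)
        if msgs:
            keep[i] = False
            for m in msgs:
                diagnostics.append(RowDiagnostic(row=i, message=m))
    return frame[keep], diagnostics


def _row_problems(row: pd.Series) -> list[str]:
    msgs = []
    try:
        a = float(row["co2_ambient"])
        e = float(row["co2_elevated"])
        if not (e > a > 0):
            msgs.append(f"co2_elevated ({e}) must exceed co2_ambient ({a}) > 0")
    except (TypeError, ValueError):
        msgs.append("unparseable CO2 level")
    try:
        rc = float(row["relative_change"])
        if not rc > -1:
            msgs.append(
                f"relative_change = {rc} <= -1: a concentration cannot "
                "decline by 100% or more"
            )
    except (TypeError, ValueError):
        msgs.append("unparseable relative_change")
        rc = None
    try:
        n = int(row["n_replicates"])
        if n < 1:
            msgs.append(f"n_replicates = {n} < 1")
    except (TypeError, ValueError):
        msgs.append("unparseable n_replicates")
    elem = row.get("element")
    if elem not in ELEMENT_REGISTRY:
        msgs.append(f"unknown element symbol {elem!r}")
    for col, lo, hi in (("latitude", -90, 90), ("longitude", -180, 180)):
        v = row.get(col)
        if v is not None and not pd.isna(v):
            v = float(v)
            if not lo <= v <= hi:
                msgs.append(f"{col} = {v} outside [{lo}, {hi}]")
    ca, ce = row.get("conc_ambient"), row.get("conc_elevated")
    if rc is not None and ca is not None and ce is not None \
            and not pd.isna(ca) and not pd.isna(ce):
        implied = (float(ce) - float(ca)) / float(ca)
        if abs(rc - implied) >= 1e-6:
            msgs.append(
                f"relative_change {rc} inconsistent with concentration pair "
                f"A={ca}, E={ce} (implied {implied:.8f})"
            )
    return msgs


def read_dataset(path, column_map: Mapping[str, str] | None = None,
                 on_invalid: str = "drop") -> Dataset:
    """Read a canonical CSV (optionally renaming columns via *column_map*).

    Rows violating record invariants are rejected and reported in
    ``Dataset.diagnostics`` (``on_invalid="drop"``) or raised
    (``on_invalid="raise"``).  A missing mandatory column raises
    :class:`SchemaError` naming the column.
    """
    frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    for c in CANONICAL_COLUMNS:
        if c not in frame.columns:
            frame[c] = None
    valid, diagnostics = validate_frame(frame)
    if diagnostics and on_invalid == "raise":
        detail = "; ".join(f"row {d.row}: {d.message}" for d in diagnostics)
        raise ValueError(f"invalid rows: {detail}")
    return Dataset(valid, provenance="loaded", diagnostics=diagnostics)


def write_dataset(data: Dataset, path) -> None:
    """Write *data* as a canonical-header CSV at full numeric precision."""
    out = data.frame.copy()
    out.to_csv(path, index=False, columns=list(CANONICAL_COLUMNS))


# ---------------------------------------------------------------------------
# Validation against the published dataset summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CheckLine:
    name: str
    computed: float | None
    expected: float
    status: str  # "pass" | "fail" | "not applicable (synthetic)"

    @property
    def delta(self) -> float | None:
        if self.computed is None:
            return None
        return self.computed - self.expected


@dataclass
class ValidationReport:
    lines: list[CheckLine] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(l.status != "fail" for l in self.lines)

    def __iter__(self):
        return iter(self.lines)


#: Published summary the compiled deposit is checked against: row counts,
#: element and species/cultivar richness per slice, and mean CO2 levels.
PRINTED_COUNTS = {
    "foliar observations": 4733,
    "foliar elements": 25,
    "foliar species/cultivars": 110,
    "edible observations": 3028,
    "edible elements": 23,
    "edible species/cultivars": 41,
    "FACE observations": 2264,
    "FACE elements": 24,
    "FACE species/cultivars": 25,
    "total observations": 7761,
    "C3 species/cultivars": 125,
    "C4 species/cultivars": 5,
    "mean ambient CO2 (overall)": 368,
    "mean elevated CO2 (overall)": 689,
    "mean ambient CO2 (foliar)": 364,
    "mean elevated CO2 (foliar)": 699,
    "mean ambient CO2 (edible)": 373,
    "mean elevated CO2 (edible)": 674,
    "mean ambient CO2 (non-FACE)": 365,
    "mean elevated CO2 (non-FACE)": 732,
    "mean ambient CO2 (FACE)": 376,
    "mean elevated CO2 (FACE)": 560,
}


def _species_key(frame: pd.DataFrame) -> pd.Series:
    cult = frame["cultivar"].fillna("")
    return frame["species"].astype(str) + "|" + cult.astype(str)


def validate_against_printed_counts(data: Dataset) -> ValidationReport:
    """Compare a loaded deposit against the published summary counts.

    Observation counts are row counts (one row = one study x element
    observation).  For a synthetic dataset every line is flagged
    "not applicable (synthetic)" instead of pass/fail.
    """
    report = ValidationReport()
    synthetic = data.provenance == "synthetic"
    f = data.frame

    def add(name: str, computed):
        expected = PRINTED_COUNTS[name]
        if synthetic:
            status = "not applicable (synthetic)"
        else:
            tol = 0.5 if "CO2" not in name else 0.5  # integer / rounded-ppm
            status = "pass" if computed is not None and \
                abs(computed - expected) <= tol else "fail"
        report.lines.append(CheckLine(name, computed, expected, status))

    foliar = f[f["tissue"] == "foliar"]
    edible = f[f["tissue"] == "edible"]
    face = f[f["facility"] == "FACE"]
    nonface = f[f["facility"] != "FACE"]

    add("foliar observations", len(foliar))
    add("foliar elements", foliar["element"].nunique())
    add("foliar species/cultivars", _species_key(foliar).nunique())
    add("edible observations", len(edible))
    add("edible elements", edible["element"].nunique())
    add("edible species/cultivars", _species_key(edible).nunique())
    add("FACE observations", len(face))
    add("FACE elements", face["element"].nunique())
    add("FACE species/cultivars", _species_key(face).nunique())
    add("total observations", len(f))
    add("C3 species/cultivars", _species_key(f[f["pathway"] == "C3"]).nunique())
    add("C4 species/cultivars", _species_key(f[f["pathway"] == "C4"]).nunique())
    for label, sub in (("overall", f), ("foliar", foliar), ("edible", edible),
                       ("non-FACE", nonface), ("FACE", face)):
        amb = float(sub["co2_ambient"].mean()) if len(sub) else None
        ele = float(sub["co2_elevated"].mean()) if len(sub) else None
        add(f"mean ambient CO2 ({label})", None if amb is None else round(amb))
        add(f"mean elevated CO2 ({label})", None if ele is None else round(ele))
    return report


# ---------------------------------------------------------------------------
# Data-inclusion rules for studies with multiple co-dependent datasets
# ---------------------------------------------------------------------------

_GROUP_KEY = ["study_id", "species", "cultivar", "element"]


def apply_inclusion_rules(data: Dataset | pd.DataFrame,
                          tissue: str = "foliar") -> Dataset:
    """Resolve co-dependent observations within each study group.

    Per study x species/cultivar x element group the rules keep, in order:

    1. the lowest-ambient / highest-elevated CO2 arm when a study ran
       more than two CO2 levels;
    2. for *foliar* tissue, only arms without environmental cofactors
       (control x CO2-only); for *edible* tissue cofactor arms are kept
       because edible-tissue data are scarce;
    3. the highest nutrient regime when no unfertilised control exists;
    4. the last time point of a time series;
    5. the most mature foliage when several leaf ages are reported;
    6. if three or more separate co-dependent datasets still remain for
       the same species/cultivar, their unweighted mean as a single record
       (replicate count = rounded mean of the group's replicate counts).

    Idempotent: applying the rules to an already-resolved dataset is the
    identity.
    """
    frame = data.frame if isinstance(data, Dataset) else data
    provenance = data.provenance if isinstance(data, Dataset) else "loaded"
    frame = frame[frame["tissue"] == tissue] if "tissue" in frame else frame

    resolved_rows = []
    grouped = frame.groupby(
        [frame[c].fillna("") for c in _GROUP_KEY], sort=False, dropna=False
    )
    for key, g in grouped:
        resolved_rows.extend(_resolve_group(key, g, tissue))
    out = pd.DataFrame(resolved_rows, columns=list(CANONICAL_COLUMNS))
    return Dataset(out, provenance=provenance)


def _resolve_group(key, g: pd.DataFrame, tissue: str) -> list[dict]:
    # rule 1: extreme CO2 levels
    if g["co2_elevated"].nunique() > 1 or g["co2_ambient"].nunique() > 1:
        g = g[g["co2_ambient"] == g["co2_ambient"].min()]
        g = g[g["co2_elevated"] == g["co2_elevated"].max()]
    # rule 2: cofactor arms (foliar only)
    if tissue == "foliar":
        no_cof = g[g["cofactor"].isna() | (g["cofactor"] == "")]
        if len(no_cof):
            g = no_cof
        # when every arm carries a cofactor the group is kept as-is:
        # there is no CO2-only arm to prefer
    def keep_max(frame, col):
        # the rule applies once any record carries the annotation; a group
        # mixing annotated and unannotated records is unresolvable
        c = frame[col]
        if not c.notna().any() or (c.notna().all() and c.nunique() == 1):
            return frame
        if c.isna().any():
            raise UnresolvedGroupError(key, col)
        return frame[c == c.max()]

    g = keep_max(g, "nutrient_regime")   # rule 3: highest nutrient regime
    g = keep_max(g, "time_point_index")  # rule 4: last time point
    if tissue == "foliar":               # rule 5: most mature foliage
        g = keep_max(g, "leaf_age")
    # rule 6: >= 3 separate co-dependent datasets -> unweighted average
    if len(g) >= 3:
        base = g.iloc[0].to_dict()
        base["relative_change"] = float(g["relative_change"].mean())
        base["n_replicates"] = int(round(g["n_replicates"].mean()))
        base["conc_ambient"] = None
        base["conc_elevated"] = None
        base["notes"] = f"mean of {len(g)} co-dependent datasets"
        return [base]
    return [row.to_dict() for _, row in g.iterrows()]


def fetch_deposit(url: str, dest) -> Path:
    """Download the compiled deposit CSV (optional helper; never required).

    The compiled observations are archived at Dryad (10.5061/dryad.6356f)
    and mirrored on GitHub; pass the direct CSV URL.
    """
    import urllib.request

    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    urllib.request.urlretrieve(url, dest)  # noqa: S310 - explicit user URL
    return dest
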