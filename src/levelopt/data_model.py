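"""Core domain types for emergency-department triage cohorts.

A cohort is one row per ED visit: demographics (age band, gender, arrival
mode), five vital signs discretized into clinically meaningful categories
(each with a dedicated ``missing`` category), a single specific chief
complaint, and a binary critical-care outcome (in-hospital mortality, direct
ICU admission, or emergent surgery/catheterization).  Complaints live in a
two-level hierarchy: every specific complaint belongs to exactly one broader
complaint category.
"""
from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ReferentialIntegrityError, SchemaError, ValidationError

# --------------------------------------------------------------------------
# Label tables
# --------------------------------------------------------------------------

AGE_BANDS: tuple[str, ...] = (
    "18-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80-89", ">90",
)
# band b is [lower, upper + 1); "80-89" is [80, 90) and ">90" is [90, inf),
# so there is no gap at exactly 90
_AGE_EDGES: tuple[float, ...] = (30, 40, 50, 60, 70, 80, 90)

GENDERS: tuple[str, ...] = ("female", "male")
ARRIVAL_MODES: tuple[str, ...] = ("walk_in", "ambulance")

MISSING = "missing"

#: vital name -> (ordered bin labels low..high, interior edges).  Bins are
#: half-open [lower, upper): a printed boundary value belongs to the upper
#: bin.  The lowest bin is open below and the highest open above.  Oxygen
#: saturation is integer-valued in practice; "93-94" covers [93, 95).
VITAL_BINS: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "temperature": (
        ("<94.8", "94.8-96.1", "96.1-99.2", "99.2-100.4", ">100.4"),
        (94.8, 96.1, 99.2, 100.4),
    ),
    "pulse": (
        ("<49", "49-59", "59-105", "105-109", "109-119", "119-129", ">129"),
        (49, 59, 105, 109, 119, 129),
    ),
    "respiratory_rate": (
        ("<13", "13-14", "14-19", "19-23", ">23"),
        (13, 14, 19, 23),
    ),
    "blood_pressure": (
        ("<99", "99-106", "106-176", "176-199", ">199"),
        (99, 106, 176, 199),
    ),
    "oxygen_saturation": (
        ("<93", "93-94", ">94"),
        (93, 95),
    ),
}

VITAL_NAMES: tuple[str, ...] = tuple(VITAL_BINS)

#: cohort-frame column -> full ordered label set (vitals include "missing")
FIELD_LABELS: dict[str, tuple[str, ...]] = {
    "age_band": AGE_BANDS,
    "gender": GENDERS,
    "arrival_mode": ARRIVAL_MODES,
    **{v: VITAL_BINS[v][0] + (MISSING,) for v in VITAL_NAMES},
}

COHORT_COLUMNS: tuple[str, ...] = tuple(FIELD_LABELS) + ("complaint", "outcome")


def normalize_id(value: object) -> str:
    """Trim, collapse whitespace, lower-case, and normalize dashes."""
    s = " ".join(str(value).strip().lower().split())
    return s.replace("–", "-").replace("—", "-")


def _normalize_label(column: str, value: object) -> str:
    s = normalize_id(value)
    if column == "arrival_mode":
        s = s.replace("via ambulance", "ambulance").replace("walk in", "walk_in")
        s = s.replace("walk-in", "walk_in")
    return s


# --------------------------------------------------------------------------
# Discretization
# --------------------------------------------------------------------------

def categorize_age(age_years: float) -> str:
    """Map an adult age in years to its band label (half-open bands)."""
    if age_years is None or not math.isfinite(float(age_years)):
        raise ValidationError(f"age must be a finite number, got {age_years!r}")
    age = float(age_years)
    if age < 18:
        raise ValidationError(f"age {age:g} is below the adult ED population (>=18)")
    return AGE_BANDS[bisect_right(_AGE_EDGES, age)]


def categorize_vital(vital_name: str, raw_value: float | None) -> str:
    """Map a raw vital-sign measurement to its bin label.

    ``raw_value`` may be None or NaN, which maps to the dedicated
    ``missing`` category.  Bins are half-open [lower, upper); boundary
    values belong to the upper bin.
    """
    if vital_name not in VITAL_BINS:
        raise SchemaError(
            f"unknown vital {vital_name!r}; expected one of {sorted(VITAL_BINS)}"
        )
    if raw_value is None:
        return MISSING
    value = float(raw_value)
    if math.isnan(value):
        return MISSING
    if not math.isfinite(value):
        raise ValidationError(f"{vital_name} value must be finite, got {raw_value!r}")
    labels, edges = VITAL_BINS[vital_name]
    return labels[bisect_right(edges, value)]


# --------------------------------------------------------------------------
# Hierarchy
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplaintHierarchy:
    """Two-level partition of specific complaints into complaint categories.

    ``complaints`` fixes the canonical ordering used by specification masks:
    bit *i* of a mask refers to ``complaints[i]``.
    """

    complaints: tuple[str, ...]
    categories: tuple[str, ...]
    parent: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.complaints) < 1:
            raise ValidationError("hierarchy needs at least one complaint")
        if len(set(self.complaints)) != len(self.complaints):
            raise ValidationError("complaint identifiers must be unique")
        if len(set(self.categories)) != len(self.categories):
            raise ValidationError("category identifiers must be unique")
        overlap = set(self.complaints) & set(self.categories)
        if overlap:
            raise ValidationError(
                f"complaint and category namespaces overlap: {sorted(overlap)}"
            )
        missing = [c for c in self.complaints if c not in self.parent]
        if missing:
            raise ValidationError(f"complaints without a parent category: {missing}")
        childless = set(self.categories) - set(self.parent.values())
        if childless:
            raise ValidationError(f"categories with no child complaint: {sorted(childless)}")
        unknown = set(self.parent.values()) - set(self.categories)
        if unknown:
            raise ValidationError(f"parent map references unknown categories: {sorted(unknown)}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ComplaintHierarchy":
        """Build from (complaint, category) pairs, preserving first-seen order.

        A complaint listed under two different categories is rejected: the
        hierarchy must be a partition.
        """
        parent: dict[str, str] = {}
        complaints: list[str] = []
        categories: list[str] = []
        for raw_c, raw_g in pairs:
            c, g = normalize_id(raw_c), normalize_id(raw_g)
            if c in parent:
                if parent[c] != g:
                    raise ValidationError(
                        f"complaint {c!r} listed under two categories: "
                        f"{parent[c]!r} and {g!r}"
                    )
                continue
            parent[c] = g
            complaints.append(c)
            if g not in categories:
                categories.append(g)
        return cls(tuple(complaints), tuple(categories), parent)

    @classmethod
    def from_csv(cls, path) -> "ComplaintHierarchy":
        df = pd.read_csv(path, dtype=str)
        cols = {c.strip().lower(): c for c in df.columns}
        for required in ("complaint", "category"):
            if required not in cols:
                raise SchemaError(f"hierarchy CSV is missing column {required!r}")
        return cls.from_pairs(
            zip(df[cols["complaint"]].tolist(), df[cols["category"]].tolist())
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"complaint": self.complaints,
             "category": [self.parent[c] for c in self.complaints]}
        ).to_csv(path, index=False)

    @property
    def n(self) -> int:
        return len(self.complaints)

    def index(self, complaint: str) -> int:
        try:
            return self.complaints.index(complaint)
        except ValueError:
            raise ReferentialIntegrityError(f"unknown complaint {complaint!r}") from None

    def children(self, category: str) -> tuple[str, ...]:
        return tuple(c for c in self.complaints if self.parent[c] == category)

    @property
    def parent_codes(self) -> np.ndarray:
        """Category index (into ``categories``) of each complaint."""
        cat_index = {g: i for i, g in enumerate(self.categories)}
        return np.array([cat_index[self.parent[c]] for c in self.complaints], dtype=np.intp)


# --------------------------------------------------------------------------
# Records and cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientRecord:
    """One ED visit, fully discretized."""

    age_band: str
    gender: str
    arrival_mode: str
    temperature_cat: str
    pulse_cat: str
    resp_rate_cat: str
    bp_cat: str
    o2sat_cat: str
    complaint: str
    outcome: int


_RECORD_FIELDS = {
    "age_band": "age_band",
    "gender": "gender",
    "arrival_mode": "arrival_mode",
    "temperature": "temperature_cat",
    "pulse": "pulse_cat",
    "respiratory_rate": "resp_rate_cat",
    "blood_pressure": "bp_cat",
    "oxygen_saturation": "o2sat_cat",
}


@dataclass(eq=False)
class Cohort:
    """A validated patient table plus its complaint hierarchy.

    The table is stored column-wise (one pandas column per field, row order
    preserved); :attr:`records` materializes :class:`PatientRecord` views on
    demand.  Integer code arrays for the categorical fields are cached since
    design-matrix construction is on the hot path of the search.
    """

    frame: pd.DataFrame
    hierarchy: ComplaintHierarchy
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"cohort table is missing columns: {missing_cols}")
        df = df.loc[:, list(COHORT_COLUMNS)].reset_index(drop=True)
        for col, labels in FIELD_LABELS.items():
            bad = set(df[col]) - set(labels)
            if bad:
                raise ValidationError(
                    f"column {col!r} has values outside its label set: {sorted(bad)[:5]}"
                )
        outcome = df["outcome"].to_numpy()
        if not np.isin(outcome, (0, 1)).all():
            bad_vals = sorted(set(outcome) - {0, 1})
            raise ValidationError(f"outcome must be 0/1, found {bad_vals[:5]}")
        df["outcome"] = df["outcome"].astype(np.int8)
        unknown = sorted(set(df["complaint"]) - set(self.hierarchy.complaints))
        if unknown:
            raise ReferentialIntegrityError(
                f"complaints absent from hierarchy: {unknown[:10]}"
            )
        if outcome.min() == outcome.max():
            raise ValidationError(
                "cohort needs at least one record of each outcome class"
            )
        self.frame = df

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_records(
        cls, records: Sequence[PatientRecord], hierarchy: ComplaintHierarchy
    ) -> "Cohort":
        data = {
            col: [getattr(r, attr) for r in records]
            for col, attr in _RECORD_FIELDS.items()
        }
        data["complaint"] = [r.complaint for r in records]
        data["outcome"] = [r.outcome for r in records]
        return cls(pd.DataFrame(data), hierarchy)

    # -- accessors --------------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def outcome(self) -> np.ndarray:
        return self.frame["outcome"].to_numpy()

    @property
    def records(self) -> list[PatientRecord]:
        rows = self.frame.itertuples(index=False)
        cols = list(self.frame.columns)
        idx = {c: cols.index(c) for c in cols}
        out = []
        for row in rows:
            out.append(PatientRecord(
                **{attr: row[idx[col]] for col, attr in _RECORD_FIELDS.items()},
                complaint=row[idx["complaint"]],
                outcome=int(row[idx["outcome"]]),
            ))
        return out

    def field_codes(self, column: str) -> np.ndarray:
        """Integer codes of a categorical column against its declared labels."""
        key = ("codes", column)
        if key not in self._cache:
            labels = FIELD_LABELS.get(column)
            if column == "complaint":
                labels = self.hierarchy.complaints
            if labels is None:
                raise SchemaError(f"unknown categorical column {column!r}")
            codes = pd.Categorical(
                self.frame[column], categories=list(labels)
            ).codes.astype(np.intp)
            self._cache[key] = codes
        return self._cache[key]

    @property
    def complaint_codes(self) -> np.ndarray:
        return self.field_codes("complaint")

    @property
    def category_codes(self) -> np.ndarray:
        key = "category_codes"
        if key not in self._cache:
            self._cache[key] = self.hierarchy.parent_codes[self.complaint_codes]
        return self._cache[key]

    # -- equality & IO ----------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.hierarchy == other.hierarchy
            and self.frame.reset_index(drop=True).equals(
                other.frame.reset_index(drop=True)
            )
        )

    def to_csv(self, path) -> None:
        """Write the pre-binned external CSV dialect."""
        self.frame.to_csv(path, index=False)


def save_cohort(cohort: Cohort, cohort_path, hierarchy_path=None) -> None:
    cohort.to_csv(cohort_path)
    if hierarchy_path is not None:
        cohort.hierarchy.to_csv(hierarchy_path)


# --------------------------------------------------------------------------
# Specification masks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecificationMask:
    """Length-n binary vector; bit i selects (1) or excludes (0) complaint i."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits)
        if bits.ndim != 1 or len(bits) < 1:
            raise ValidationError("mask must be a non-empty 1-D bit vector")
        if not np.isin(bits, (0, 1)).all():
            raise ValidationError("mask bits must be 0 or 1")
        object.__setattr__(self, "bits", bits.astype(np.uint8))
        self.bits.setflags(write=False)

    @classmethod
    def zeros(cls, n: int) -> "SpecificationMask":
        return cls(np.zeros(n, dtype=np.uint8))

    @classmethod
    def ones(cls, n: int) -> "SpecificationMask":
        return cls(np.ones(n, dtype=np.uint8))

    @classmethod
    def from_string(cls, s: str) -> "SpecificationMask":
        return cls(np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"))

    @classmethod
    def from_selected(
        cls, hierarchy: ComplaintHierarchy, selected: Iterable[str]
    ) -> "SpecificationMask":
        bits = np.zeros(hierarchy.n, dtype=np.uint8)
        for c in selected:
            bits[hierarchy.index(normalize_id(c))] = 1
        return cls(bits)

    def to_string(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def selected(self, hierarchy: ComplaintHierarchy) -> tuple[str, ...]:
        return tuple(
            c for c, b in zip(hierarchy.complaints, self.bits) if b
        )

    def __len__(self) -> int:
        return len(self.bits)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpecificationMask):
            return NotImplemented
        return np.array_equal(self.bits, other.bits)

    def __hash__(self) -> int:
        return hash(self.bits.tobytes())

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


# --------------------------------------------------------------------------
# Cohort loading
# --------------------------------------------------------------------------

def _is_blank(s: str) -> bool:
    return s == "" or s.lower() in {"na", "nan", "none"}


def _parse_vital_column(col: str, values: list[str]) -> list[str]:
    """Raw numeric strings -> bin labels; label strings validated as-is."""
    numeric = True
    for v in values:
        if _is_blank(v):
            continue
        try:
            float(v)
        except ValueError:
            numeric = False
            break
    if numeric:
        return [
            MISSING if _is_blank(v) else categorize_vital(col, float(v))
            for v in values
        ]
    labels = set(FIELD_LABELS[col])
    out = []
    bad = set()
    for v in values:
        lab = MISSING if _is_blank(v) else _normalize_label(col, v)
        if lab not in labels:
            bad.add(v)
        out.append(lab)
    if bad:
        raise ValidationError(
            f"column {col!r} has values that are neither numeric nor known "
            f"bin labels: {sorted(bad)[:5]}"
        )
    return out


def load_cohort(cohort_path, hierarchy_path) -> Cohort:
    """Read and validate the cohort and hierarchy CSV files.

    The cohort CSV must contain ``age_years`` or ``age_band``, the five
    vital columns (raw numeric with blanks for missing, or pre-binned
    labels), ``gender``, ``arrival_mode``, ``complaint`` and ``outcome``.
    """
    hierarchy = ComplaintHierarchy.from_csv(hierarchy_path)
    df = pd.read_csv(cohort_path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]

    required = ["gender", "arrival_mode", "complaint", "outcome", *VITAL_NAMES]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"cohort CSV is missing columns: {missing_cols}")
    if "age_years" not in df.columns and "age_band" not in df.columns:
        raise SchemaError("cohort CSV needs an 'age_years' or 'age_band' column")

    out: dict[str, list] = {}
    if "age_years" in df.columns:
        ages = []
        for v in df["age_years"].tolist():
            try:
                ages.append(categorize_age(float(v)))
            except (TypeError, ValueError):
                raise ValidationError(f"non-numeric age_years value {v!r}") from None
        out["age_band"] = ages
    else:
        out["age_band"] = [_normalize_label("age_band", v) for v in df["age_band"]]

    for col in ("gender", "arrival_mode"):
        out[col] = [_normalize_label(col, v) for v in df[col]]
    for col in VITAL_NAMES:
        out[col] = _parse_vital_column(col, df[col].tolist())

    complaints = [normalize_id(v) for v in df["complaint"]]
    multi = sorted({c for c in complaints if ";" in c or "|" in c})
    if multi:
        raise ValidationError(
            f"records must carry a single chief complaint; offending values: {multi[:5]}"
        )
    out["complaint"] = complaints

    outcomes = []
    for v in df["outcome"].tolist():
        s = str(v).strip()
        if s not in {"0", "1"}:
            raise ValidationError(f"outcome must be 0 or 1, found {v!r}")
        outcomes.append(int(s))
    out["outcome"] = outcomes

    return Cohort(pd.DataFrame(out), hierarchy)
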