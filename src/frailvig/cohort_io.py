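"""Cohort table input/output and packaged reference tables.

A cohort file is CSV/TSV with one row per patient; columns are the
:class:`~frailvig.instrument.AssessmentRecord` field names (header
required), optionally followed by ``time_months`` and ``event`` follow-up
columns.  Booleans may be written ``0/1``, ``no/yes`` or ``false/true``;
disease items as ``0/1/2`` or ``absent/present/advanced``; empty cells are
missing values.

The package also bundles, as plain CSV data, the published validation
cohort's summary tables (n = 590 acute geriatric inpatients): per-category
alive/deceased counts at 12 and 24 months, and baseline item prevalences
with cohort descriptors.  Percentages are always recomputed from the
counts, never transcribed: the counts are internally consistent (they
reproduce the published sensitivity/specificity pair exactly) whereas a
handful of the printed percentages are not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .instrument import (
    ALL_ITEMS,
    BAND_LABELS,
    AssessmentRecord,
    CognitiveLevel,
    DepressiveStatus,
    DiseaseStatus,
    FrailVigResult,
    ValidationError,
)

__all__ = [
    "Cohort",
    "CohortReport",
    "CohortValidationError",
    "GroupedOutcomeCounts",
    "PrevalenceTable",
    "read_cohort",
    "write_results_csv",
    "write_results_json",
    "load_fixture",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("table3_12m", "table3_24m", "table2_prevalence")

_BOOL_TOKENS = {
    "0": False, "1": True,
    "no": False, "yes": True,
    "false": False, "true": True,
}
_DISEASE_TOKENS = {
    "0": DiseaseStatus.ABSENT, "absent": DiseaseStatus.ABSENT,
    "1": DiseaseStatus.PRESENT, "present": DiseaseStatus.PRESENT,
    "2": DiseaseStatus.ADVANCED, "advanced": DiseaseStatus.ADVANCED,
}
_COGNITIVE_TOKENS = {lvl.value: lvl for lvl in CognitiveLevel}
_DEPRESSIVE_TOKENS = {st.value: st for st in DepressiveStatus}

FOLLOWUP_COLUMNS = ("time_months", "event")


class CohortValidationError(ValidationError):
    """One or more rows of a cohort file failed schema validation."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        preview = "\n  ".join(self.problems[:20])
        more = "" if len(self.problems) <= 20 else f"\n  ... {len(self.problems) - 20} more"
        super().__init__(f"{len(self.problems)} cohort validation problem(s):\n  {preview}{more}")


@dataclass
class CohortReport:
    """Validation summary produced while reading a cohort file."""

    n_rows: int
    missing_fraction: dict
    has_followup: bool

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "missing_fraction": dict(self.missing_fraction),
            "has_followup": self.has_followup,
        }


@dataclass
class Cohort:
    records: list
    followup: Optional[pd.DataFrame]
    report: CohortReport


@dataclass
class GroupedOutcomeCounts:
    """Alive/deceased counts per frailty band at a fixed horizon."""

    horizon_months: int
    bands: tuple = BAND_LABELS
    alive: np.ndarray = field(default_factory=lambda: np.zeros(7, dtype=int))
    deceased: np.ndarray = field(default_factory=lambda: np.zeros(7, dtype=int))

    def __post_init__(self):
        self.alive = np.asarray(self.alive, dtype=int)
        self.deceased = np.asarray(self.deceased, dtype=int)
        if len(self.bands) != len(self.alive) or len(self.bands) != len(self.deceased):
            raise ValueError("bands, alive and deceased must have equal length")
        if (self.alive < 0).any() or (self.deceased < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> np.ndarray:
        return self.alive + self.deceased

    @property
    def grand_total(self) -> int:
        return int(self.total.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "band": list(self.bands),
                "alive": self.alive,
                "deceased": self.deceased,
                "total": self.total,
            }
        )


@dataclass
class PrevalenceTable:
    """Baseline item prevalences and cohort descriptors."""

    n: int
    counts: dict
    ordinal_counts: dict
    descriptors: dict

    @property
    def prevalence(self) -> dict:
        return {item: c / self.n for item, c in self.counts.items()}

    def ordinal_proportions(self, item: str) -> dict:
        levels = self.ordinal_counts[item]
        return {level: c / self.n for level, c in levels.items()}


def _parse_cell(column: str, raw, row_label: str):
    """Parse one typed cell; raise ValidationError with row context."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip().lower()
    if text in ("", "na", "nan"):
        return None
    try:
        if column == "barthel":
            value = float(text)
            if not value.is_integer():
                raise ValidationError(f"Barthel {raw!r} is not an integer")
            return int(value)
        if column == "cognitive":
            if text in _COGNITIVE_TOKENS:
                return _COGNITIVE_TOKENS[text]
            raise ValidationError(f"unknown cognitive level {raw!r}")
        if column == "depressive":
            if text in _DEPRESSIVE_TOKENS:
                return _DEPRESSIVE_TOKENS[text]
            raise ValidationError(f"unknown depressive status {raw!r}")
        if column.startswith("disease_"):
            if text in _DISEASE_TOKENS:
                return _DISEASE_TOKENS[text]
            raise ValidationError(f"unknown disease status {raw!r}")
        if text in _BOOL_TOKENS:
            return _BOOL_TOKENS[text]
        raise ValidationError(f"unknown boolean token {raw!r}")
    except ValidationError as exc:
        raise ValidationError(f"{row_label}, column {column!r}: {exc}") from None


def read_cohort(path, *, sep: Optional[str] = None) -> Cohort:
    """Read and validate a cohort CSV/TSV.

    Returns a :class:`Cohort` holding typed assessment records, the
    optional follow-up frame (``time_months``, ``event``) and a validation
    report.  Structural problems (unknown columns, duplicate patient ids,
    unparseable cells) are collected and raised together as
    :class:`CohortValidationError` with row numbers.
    """
    frame = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    problems: list[str] = []

    known = set(AssessmentRecord.field_names())
    extra = [c for c in frame.columns if c not in known and c not in FOLLOWUP_COLUMNS]
    for column in extra:
        problems.append(f"unknown column {column!r}")
    missing_cols = [c for c in ALL_ITEMS if c not in frame.columns]
    for column in missing_cols:
        problems.append(f"required column {column!r} absent")
    if problems:
        raise CohortValidationError(problems)

    has_followup = all(c in frame.columns for c in FOLLOWUP_COLUMNS)

    if "patient_id" in frame.columns:
        ids = frame["patient_id"].fillna("")
        dupes = ids[ids.duplicated() & (ids != "")]
        for row, pid in dupes.items():
            problems.append(f"row {row + 2}: duplicate patient_id {pid!r}")

    records: list[AssessmentRecord] = []
    for row_pos, (_, row) in enumerate(frame.iterrows()):
        row_label = f"row {row_pos + 2}"  # 1-based, after the header line
        kwargs = {"patient_id": str(row.get("patient_id", row_pos) or row_pos)}
        for column in ALL_ITEMS:
            try:
                kwargs[column] = _parse_cell(column, row[column], row_label)
            except ValidationError as exc:
                problems.append(str(exc))
        records.append(AssessmentRecord(**kwargs))

    followup = None
    if has_followup:
        followup = pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in records],
                "time_months": pd.to_numeric(frame["time_months"], errors="coerce"),
                "event": pd.to_numeric(frame["event"], errors="coerce"),
            }
        )
        bad_time = followup.index[followup["time_months"].isna() | (followup["time_months"] <= 0)]
        for row in bad_time:
            problems.append(f"row {row + 2}: time_months must be a positive number")
        bad_event = followup.index[~followup["event"].isin([0, 1])]
        for row in bad_event:
            problems.append(f"row {row + 2}: event must be 0 or 1")
        followup["event"] = followup["event"].astype("Int64")

    if problems:
        raise CohortValidationError(problems)

    missing_fraction = {
        column: (
            float(np.mean([getattr(r, column) is None for r in records]))
            if records
            else 0.0
        )
        for column in ALL_ITEMS
    }
    report = CohortReport(
        n_rows=len(records),
        missing_fraction=missing_fraction,
        has_followup=has_followup,
    )
    return Cohort(records=records, followup=followup, report=report)


def write_results_csv(results: Sequence[FrailVigResult], path) -> None:
    """Write scored results as CSV: patient_id, total_points, score, category, frail."""
    frame = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in results],
            "total_points": [r.total_points for r in results],
            "score": [r.score for r in results],
            "category": [r.category for r in results],
            "frail": [int(r.frail) for r in results],
        }
    )
    frame.to_csv(path, index=False)


def write_results_json(results: Sequence[FrailVigResult], path) -> None:
    """Write scored results as JSON including per-item and per-domain points."""
    payload = [
        {
            "patient_id": r.patient_id,
            "total_points": r.total_points,
            "score": r.score,
            "category": r.category,
            "frail": r.frail,
            "item_points": r.item_points,
            "domain_points": r.domain_points,
            "warnings": r.warnings,
        }
        for r in results
    ]
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=2, ensure_ascii=False)


def records_to_frame(records: Sequence[AssessmentRecord]) -> pd.DataFrame:
    """Render assessment records as a schema-conformant cohort frame."""

    def cell(value):
        if value is None:
            return ""
        if isinstance(value, bool):
            return int(value)
        if isinstance(value, DiseaseStatus):
            return int(value)
        if isinstance(value, (CognitiveLevel, DepressiveStatus)):
            return value.value
        return value

    columns = AssessmentRecord.field_names()
    return pd.DataFrame(
        {col: [cell(getattr(r, col)) for r in records] for col in columns}
    )


def _data_frame(name: str) -> pd.DataFrame:
    with resources.files("frailvig.data").joinpath(name).open("r", encoding="utf-8") as handle:
        return pd.read_csv(handle)


def _load_table3() -> pd.DataFrame:
    frame = _data_frame("table3.csv")
    if list(frame["band"]) != list(BAND_LABELS):
        raise ValueError("bundled outcome table bands out of order")
    for horizon in (12, 24):
        alive = frame[f"alive_{horizon}m"].to_numpy()
        deceased = frame[f"deceased_{horizon}m"].to_numpy()
        if not np.array_equal(alive + deceased, frame["total"].to_numpy()):
            raise ValueError(f"bundled outcome table inconsistent at {horizon} months")
    if (frame["deceased_12m"] > frame["deceased_24m"]).any():
        raise ValueError("mortality must accumulate between 12 and 24 months")
    return frame


def load_fixture(name: str):
    """Load a bundled reference table.

    ``table3_12m`` / ``table3_24m`` return :class:`GroupedOutcomeCounts`
    for the validation cohort; ``table2_prevalence`` returns the
    :class:`PrevalenceTable` of baseline descriptives.  Consistency
    invariants (row sums, accumulation of deaths between horizons) are
    asserted at load time.
    """
    if name in ("table3_12m", "table3_24m"):
        horizon = 12 if name.endswith("12m") else 24
        frame = _load_table3()
        return GroupedOutcomeCounts(
            horizon_months=horizon,
            bands=BAND_LABELS,
            alive=frame[f"alive_{horizon}m"].to_numpy(),
            deceased=frame[f"deceased_{horizon}m"].to_numpy(),
        )
    if name == "table2_prevalence":
        frame = _data_frame("table2.csv")
        descriptors = {
            row["item"]: float(row["value"])
            for _, row in frame[frame["kind"] == "descriptor"].iterrows()
        }
        n = int(descriptors.pop("n"))
        counts = {
            row["item"]: int(row["count"])
            for _, row in frame[frame["kind"] == "binary"].iterrows()
        }
        ordinal: dict[str, dict[str, int]] = {}
        for _, row in frame[frame["kind"] == "ordinal"].iterrows():
            ordinal.setdefault(row["item"], {})[row["level"]] = int(row["count"])
        for item, levels in ordinal.items():
            if sum(levels.values()) != n:
                raise ValueError(f"ordinal counts for {item!r} do not sum to n")
        bad = {i: c for i, c in counts.items() if not 0 <= c <= n}
        if bad:
            raise ValueError(f"counts outside [0, n]: {bad}")
        return PrevalenceTable(n=n, counts=counts, ordinal_counts=ordinal, descriptors=descriptors)
    raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
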