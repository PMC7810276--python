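"""Measurement-cohort data model and CSV/JSON I/O.

A cohort is an ordered list of per-measurement records.  Repeat infusions in
the same patient appear as separate records.  The 15-measurement validation
cohort ships with the package as a CSV resource and is exposed through
:func:`bundled_paper_cohort`.

CSV schema (header required, UTF-8, decimal point)::

    record_id,sex,age_y,weight_kg,tbw_l,infusate_volume_l,
    infusate_percent_nacl,na_initial_mmol_l,na_final_mmol_l,
    urine_osm_mosm_l,causative_condition
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import IO, Iterator

import pandas as pd

from natremia.errors import CohortParseError, InvalidInputError

#: plausibility band for plasma sodium, mmol/L; out-of-band values warn
NA_PLAUSIBLE = (80.0, 200.0)

CSV_COLUMNS = [
    "record_id",
    "sex",
    "age_y",
    "weight_kg",
    "tbw_l",
    "infusate_volume_l",
    "infusate_percent_nacl",
    "na_initial_mmol_l",
    "na_final_mmol_l",
    "urine_osm_mosm_l",
    "causative_condition",
]

_NUMERIC_COLUMNS = CSV_COLUMNS[2:10]


@dataclass(frozen=True)
class MeasurementRecord:
    """One plasma-sodium-response measurement."""

    record_id: int
    sex: str
    age_y: float
    weight_kg: float
    tbw_l: float
    infusate_volume_l: float
    infusate_percent_nacl: float
    na_initial_mmol_l: float
    na_final_mmol_l: float
    urine_osm_mosm_l: float
    causative_condition: str = ""

    def __post_init__(self) -> None:
        for name in (
            "age_y",
            "weight_kg",
            "tbw_l",
            "infusate_volume_l",
            "infusate_percent_nacl",
            "na_initial_mmol_l",
            "na_final_mmol_l",
            "urine_osm_mosm_l",
        ):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise InvalidInputError(
                    f"record {self.record_id}: {name} must be positive, got {value!r}"
                )
        lo, hi = NA_PLAUSIBLE
        for name in ("na_initial_mmol_l", "na_final_mmol_l"):
            value = getattr(self, name)
            if not lo <= value <= hi:
                warnings.warn(
                    f"record {self.record_id}: {name} = {value} mmol/L is outside "
                    f"the plausibility band [{lo:g}, {hi:g}]",
                    UserWarning,
                    stacklevel=3,
                )

    @property
    def measured_delta(self) -> float:
        """Measured sodium change, ``na_final - na_initial`` (mmol/L)."""
        return self.na_final_mmol_l - self.na_initial_mmol_l


@dataclass
class Cohort:
    """An ordered collection of measurement records with unique ids."""

    records: list[MeasurementRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortParseError(f"duplicate record_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MeasurementRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records], columns=CSV_COLUMNS)

    def to_json(self) -> str:
        return json.dumps(
            {"provenance": self.provenance, "records": [asdict(r) for r in self.records]},
            indent=2,
        )


def load_cohort(source: str | Path | IO[str], provenance: str = "") -> Cohort:
    """Read a cohort from a CSV path or text stream, validating each row.

    Raises
    ------
    CohortParseError
        On missing columns, non-numeric cells or duplicate record ids; the
        error names the offending row and column.
    """
    try:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise CohortParseError("cohort file is empty (no header)") from exc

    missing = [c for c in CSV_COLUMNS if c not in df.columns and c != "causative_condition"]
    if missing:
        raise CohortParseError(f"missing column(s): {missing}")
    if "causative_condition" not in df.columns:
        df["causative_condition"] = ""

    records: list[MeasurementRecord] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based file line, header is line 1
        try:
            record_id = int(row["record_id"])
        except ValueError as exc:
            raise CohortParseError(
                f"non-integer record_id {row['record_id']!r}", row=rownum, column="record_id"
            ) from exc
        values: dict[str, float] = {}
        for col in _NUMERIC_COLUMNS:
            try:
                values[col] = float(row[col])
            except ValueError as exc:
                raise CohortParseError(
                    f"non-numeric value {row[col]!r}", row=rownum, column=col
                ) from exc
        sex = str(row["sex"]).strip().lower()
        try:
            records.append(
                MeasurementRecord(
                    record_id=record_id,
                    sex=sex,
                    causative_condition=str(row["causative_condition"]),
                    **values,
                )
            )
        except InvalidInputError as exc:
            raise CohortParseError(str(exc), row=rownum) from exc
    return Cohort(records=records, provenance=provenance)


def write_cohort(cohort: Cohort, dest: str | Path | IO[str]) -> None:
    """Write a cohort to CSV in the canonical schema (round-trips with
    :func:`load_cohort`)."""
    cohort.to_frame().to_csv(dest, index=False)


def bundled_paper_cohort() -> Cohort:
    """The 15-measurement SIADH validation cohort shipped with the package."""
    ref = resources.files("natremia.data").joinpath("paper_cohort.csv")
    with ref.open("r", encoding="utf-8") as fh:
        text = fh.read()
    return load_cohort(io.StringIO(text), provenance="bundled 15-measurement SIADH cohort")
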