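"""Typed in-memory model of a delimited EMR extract.

Every downstream stage (cohort assembly, annual scoring, text review,
cascade accounting) consumes the :class:`EmrExtract` container built here;
no other module touches files directly.  The on-disk dialect is the
simplest portable stand-in for an EMR research extract: one UTF-8 CSV per
table, header row, ISO-8601 dates.

Units are fixed per analyte at load time (AST/ALT in IU/L, platelets in
10^9/L, albumin in g/dL, HbA1c in %); there is no unit-conversion layer
because the fibrosis score formulas assume exactly these units.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EmrExtract",
    "ExtractError",
    "InvariantError",
    "TABLE_COLUMNS",
    "QUANTITATIVE_ANALYTES",
    "SEROLOGY_ANALYTES",
    "age_on",
    "read_emr_extract",
    "write_emr_extract",
]

#: canonical column order per table; file name is "<table>.csv"
TABLE_COLUMNS: dict[str, list[str]] = {
    "patients": [
        "patient_id", "birth_date", "sex", "race_ethnicity",
        "insurance", "vital_status", "in_system",
    ],
    "labs": [
        "patient_id", "analyte", "value", "detectability",
        "collection_date", "setting",
    ],
    "diagnoses": ["patient_id", "code", "code_date", "on_problem_list"],
    "medications": ["patient_id", "drug_class", "is_antidiabetic", "active"],
    "encounters": ["patient_id", "event_type", "event_date"],
    "imaging": ["patient_id", "modality", "report_date", "report_text"],
    "bmi": ["patient_id", "bmi_value", "observation_date"],
}

DATE_COLUMNS = {
    "patients": ["birth_date"],
    "labs": ["collection_date"],
    "diagnoses": ["code_date"],
    "encounters": ["event_date"],
    "imaging": ["report_date"],
    "bmi": ["observation_date"],
}

BOOL_COLUMNS = {
    "patients": ["in_system"],
    "diagnoses": ["on_problem_list"],
    "medications": ["is_antidiabetic", "active"],
}

FLOAT_COLUMNS = {"labs": ["value"], "bmi": ["bmi_value"]}

#: analytes carrying a numeric value (conventional units, see module docstring)
QUANTITATIVE_ANALYTES = frozenset(
    {"AST", "ALT", "platelet", "albumin", "HbA1c", "HDL", "triglyceride"}
)
#: analytes carrying a detectability flag instead of a numeric value
SEROLOGY_ANALYTES = frozenset({"HBsAg", "HCV_RNA"})

SEXES = frozenset({"male", "female"})
RACES = frozenset({"White", "Black", "Latinx", "Asian", "Other"})
INSURANCES = frozenset({"public", "private", "uninsured"})
VITAL = frozenset({"alive", "deceased"})
SETTINGS = frozenset({"outpatient", "emergency", "inpatient"})
EVENT_TYPES = frozenset({"in_person_visit", "patient_message"})
MODALITIES = frozenset({"ultrasound", "CT", "MRI"})

# ICD-9 (3 digits, V/E prefixes) or ICD-10 (letter + 2 alphanumerics) with
# optional dotted extension
_ICD_RE = re.compile(
    r"^(\d{3}(\.\d{1,2})?|V\d{2}(\.\d{1,2})?|E\d{3}(\.\d)?"
    r"|[A-Z]\d[0-9A-Z](\.[0-9A-Z]{1,4})?)$"
)


class ExtractError(Exception):
    """A table file is missing or structurally unreadable."""


class InvariantError(Exception):
    """One or more rows violate a domain invariant.

    ``violations`` maps ``table -> list of (row_index, message)``.
    """

    def __init__(self, violations: dict[str, list[tuple[int, str]]]):
        self.violations = violations
        lines = []
        for table, rows in violations.items():
            for idx, msg in rows[:10]:
                lines.append(f"{table}[row {idx}]: {msg}")
            if len(rows) > 10:
                lines.append(f"{table}: ... {len(rows) - 10} more")
        super().__init__("EMR extract invariant violations:\n" + "\n".join(lines))


def age_on(birth_date: dt.date, reference_date: dt.date) -> int:
    """Completed whole years between ``birth_date`` and ``reference_date``.

    This floor convention is applied uniformly to eligibility, per-year
    score panels, age-based cutoffs and the intervention age filter.
    """
    birth_date = _as_date(birth_date)
    reference_date = _as_date(reference_date)
    if reference_date < birth_date:
        raise ValueError(
            f"reference date {reference_date} precedes birth date {birth_date}"
        )
    years = reference_date.year - birth_date.year
    if (reference_date.month, reference_date.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def _as_date(value) -> dt.date:
    if isinstance(value, pd.Timestamp):
        return value.date()
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return pd.Timestamp(value).date()


@dataclass
class EmrExtract:
    """All tables of one EMR extract, keyed by patient_id.

    Each attribute is a :class:`pandas.DataFrame` with the canonical
    columns of :data:`TABLE_COLUMNS`; date columns are datetime64,
    boolean flags are bool.
    """

    patients: pd.DataFrame
    labs: pd.DataFrame
    diagnoses: pd.DataFrame
    medications: pd.DataFrame
    encounters: pd.DataFrame
    imaging: pd.DataFrame
    bmi: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    def validate(self, anchor_date: dt.date | None = None) -> None:
        """Check every domain invariant; raise :class:`InvariantError` listing
        offending rows.  ``anchor_date`` additionally enforces adulthood
        (age >= 18) at the cohort anchor."""
        bad: dict[str, list[tuple[int, str]]] = {}

        def flag(table: str, mask: pd.Series, message: str) -> None:
            idx = np.flatnonzero(np.asarray(mask))
            if idx.size:
                bad.setdefault(table, []).extend((int(i), message) for i in idx)

        p = self.patients
        dup = p["patient_id"].duplicated(keep=False)
        flag("patients", dup, "duplicate patient_id")
        flag("patients", ~p["sex"].isin(SEXES), "sex not in {male, female}")
        flag("patients", ~p["race_ethnicity"].isin(RACES), "unknown race_ethnicity")
        flag("patients", ~p["insurance"].isin(INSURANCES), "unknown insurance")
        flag("patients", ~p["vital_status"].isin(VITAL), "unknown vital_status")
        if anchor_date is not None and len(p):
            ages = p["birth_date"].map(lambda b: age_on(b, anchor_date))
            flag("patients", ages < 18, "age < 18 at anchor date")

        lb = self.labs
        known = lb["analyte"].isin(QUANTITATIVE_ANALYTES | SEROLOGY_ANALYTES)
        flag("labs", ~known, "unknown analyte")
        quant = lb["analyte"].isin(QUANTITATIVE_ANALYTES)
        flag("labs", quant & ~(lb["value"] >= 0), "negative or missing value")
        sero = lb["analyte"].isin(SEROLOGY_ANALYTES)
        flag(
            "labs",
            sero & ~lb["detectability"].isin(["detectable", "undetectable"]),
            "serology lab without detectability flag",
        )
        flag("labs", ~lb["setting"].isin(SETTINGS), "unknown care setting")

        dx = self.diagnoses
        flag(
            "diagnoses",
            ~dx["code"].astype(str).str.match(_ICD_RE),
            "code does not match ICD-9/10 syntax",
        )

        enc = self.encounters
        flag("encounters", ~enc["event_type"].isin(EVENT_TYPES), "unknown event_type")

        im = self.imaging
        flag("imaging", ~im["modality"].isin(MODALITIES), "unknown modality")
        flag(
            "imaging",
            im["report_text"].astype(str).str.strip().eq(""),
            "empty report_text",
        )

        bm = self.bmi
        flag(
            "bmi",
            ~((bm["bmi_value"] > 10) & (bm["bmi_value"] < 100)),
            "bmi_value outside (10, 100)",
        )

        pid = set(p["patient_id"])
        for name in ("labs", "diagnoses", "medications", "encounters", "imaging", "bmi"):
            t = getattr(self, name)
            flag(name, ~t["patient_id"].isin(pid), "patient_id not in patients table")

        if bad:
            raise InvariantError(bad)

    def for_patient(self, patient_id: str) -> dict[str, pd.DataFrame]:
        """All table slices for one patient (convenience for per-patient ops)."""
        return {
            name: t[t["patient_id"] == patient_id].reset_index(drop=True)
            for name, t in self.tables().items()
        }


def _coerce(table: str, df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in DATE_COLUMNS.get(table, []):
        df[col] = pd.to_datetime(df[col], format="ISO8601")
    for col in BOOL_COLUMNS.get(table, []):
        if df[col].dtype != bool:
            df[col] = (
                df[col].astype(str).str.strip().str.lower().map(
                    {"true": True, "false": False, "1": True, "0": False}
                )
            )
            if df[col].isna().any():
                raise ExtractError(f"{table}.{col}: unparseable boolean values")
            df[col] = df[col].astype(bool)
    for col in FLOAT_COLUMNS.get(table, []):
        df[col] = pd.to_numeric(df[col])
    if table == "labs":
        df["detectability"] = df["detectability"].where(
            df["detectability"].notna() & (df["detectability"] != ""), None
        )
    return df[TABLE_COLUMNS[table]]


def read_emr_extract(
    directory_path: str | Path, validate: bool = True,
    anchor_date: dt.date | None = None,
) -> EmrExtract:
    """Load all seven tables from ``directory_path``.

    Raises :class:`ExtractError` naming the table if a file is missing or
    its header does not match the schema, and :class:`InvariantError`
    listing offending rows if ``validate`` is set.
    """
    directory_path = Path(directory_path)
    frames: dict[str, pd.DataFrame] = {}
    for table, columns in TABLE_COLUMNS.items():
        path = directory_path / f"{table}.csv"
        if not path.exists():
            raise ExtractError(f"missing table file: {path.name}")
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        raw = raw.replace({"": None}) if table == "labs" else raw
        if list(raw.columns) != columns:
            raise ExtractError(
                f"{path.name}: header {list(raw.columns)} != expected {columns}"
            )
        frames[table] = _coerce(table, raw)
    extract = EmrExtract(**frames)
    if validate:
        extract.validate(anchor_date=anchor_date)
    return extract


def write_emr_extract(extract: EmrExtract, directory_path: str | Path) -> list[Path]:
    """Write the extract as one CSV per table; lossless round-trip with
    :func:`read_emr_extract`.  Returns the paths written."""
    directory_path = Path(directory_path)
    directory_path.mkdir(parents=True, exist_ok=True)
    written = []
    for table, df in extract.tables().items():
        out = df[TABLE_COLUMNS[table]].copy()
        for col in DATE_COLUMNS.get(table, []):
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        path = directory_path / f"{table}.csv"
        out.to_csv(path, index=False)
        written.append(path)
    return written
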