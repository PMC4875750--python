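"""Register data model, CSV I/O, cleaning and derived-variable construction.

A register (cohort or hospital episodes) is held as a :class:`RecordSet`: a
pandas DataFrame with one row per record, a register label and the name of
the identifier column.  All matching variables are optional; an empty CSV
cell is a missing value.  Dates are stored as ``datetime64[ns]``, counts as
nullable ``Int64`` and categorical/text fields as strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Matching-variable fields and their storage kind.
DATE_FIELDS = (
    "date_of_birth",
    "discharge_date",
    "date_of_death",
    "mother_dob",
)
INT_FIELDS = (
    "gestational_age",
    "birth_weight",
    "birth_order",
    "n_babies",
    "n_previous_pregnancies",
    "maternal_age",
)
TEXT_FIELDS = (
    "sex",
    "delivery_method",
    "discharge_method",
    "ethnicity",
    "postcode",
    "vital_status",
)
RECORD_FIELDS = DATE_FIELDS + INT_FIELDS + TEXT_FIELDS

#: discharge_method values interpreted as in-hospital death when deriving
#: date_of_death from the discharge fields.
DEATH_METHODS = frozenset({"died", "death", "deceased", "4"})


@dataclass
class RecordSet:
    """One register: a DataFrame of records plus identifying metadata.

    Parameters
    ----------
    df:
        One row per record.  Must contain ``id_field``; any subset of
        :data:`RECORD_FIELDS` in addition.
    register_label:
        Free-text label, conventionally ``"cohort"`` or ``"episodes"``.
    id_field:
        Name of the identifier column; values must be unique after cleaning.
    """

    df: pd.DataFrame
    register_label: str
    id_field: str = "id"

    def __post_init__(self) -> None:
        if not self.register_label:
            raise ValueError("register_label must be non-empty")
        if self.id_field not in self.df.columns:
            raise ValueError(f"id column {self.id_field!r} not present")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> pd.Series:
        return self.df[self.id_field]

    def validate(self, require_unique_ids: bool = True) -> None:
        """Check record invariants; raise ``ValueError`` on violation."""
        if require_unique_ids and self.ids.duplicated().any():
            dupes = self.ids[self.ids.duplicated()].head(3).tolist()
            raise ValueError(f"duplicate ids in {self.register_label}: {dupes}")
        if "gestational_age" in self.df:
            ga = self.df["gestational_age"].dropna()
            if ((ga < 20) | (ga > 45)).any():
                raise ValueError("gestational_age outside [20, 45] weeks")
        if "birth_weight" in self.df:
            bw = self.df["birth_weight"].dropna()
            if (bw <= 0).any():
                raise ValueError("non-positive birth_weight")
        if "birth_order" in self.df and "n_babies" in self.df:
            both = self.df[["birth_order", "n_babies"]].dropna()
            if (both["birth_order"] > both["n_babies"]).any():
                raise ValueError("birth_order exceeds n_babies")

    def copy(self) -> "RecordSet":
        return RecordSet(self.df.copy(), self.register_label, self.id_field)


@dataclass
class CleaningRules:
    """Restriction and de-duplication rules applied before linkage."""

    period_start: pd.Timestamp | str | None = None
    period_end: pd.Timestamp | str | None = None
    drop_duplicates: bool = True
    retain_missing_dob: bool = True
    exclusion_categories: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.period_start is not None:
            self.period_start = pd.Timestamp(self.period_start)
        if self.period_end is not None:
            self.period_end = pd.Timestamp(self.period_end)
        if (
            self.period_start is not None
            and self.period_end is not None
            and self.period_start > self.period_end
        ):
            raise ValueError("period_start after period_end")


@dataclass
class CleaningReport:
    """Per-rule removal counts from :func:`clean_records`."""

    n_input: int
    duplicates_removed: int = 0
    out_of_period_removed: int = 0
    excluded_category_removed: int = 0
    n_output: int = 0

    @property
    def total_removed(self) -> int:
        return (
            self.duplicates_removed
            + self.out_of_period_removed
            + self.excluded_category_removed
        )


def _coerce_types(df: pd.DataFrame, dayfirst: bool = False) -> pd.DataFrame:
    df = df.copy()
    for col in DATE_FIELDS:
        if col in df.columns:
            parsed = pd.to_datetime(df[col], errors="coerce", dayfirst=dayfirst)
            bad = parsed.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
            if bad.any():
                logger.warning(
                    "%d unparseable %s value(s) set missing", int(bad.sum()), col
                )
            df[col] = parsed
    for col in INT_FIELDS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").round().astype("Int64")
    for col in TEXT_FIELDS:
        if col in df.columns:
            ser = df[col].astype("string").str.strip()
            df[col] = ser.replace("", pd.NA)
    return df


def read_records(
    path,
    register_label: str,
    id_field: str = "id",
    field_map: dict | None = None,
    dayfirst: bool = False,
) -> RecordSet:
    """Read one register from a headed CSV file.

    Unrecognised columns are dropped with a warning; empty cells become
    missing; unparseable dates become missing with the row retained.  A
    missing id column is fatal.

    ``field_map`` renames source columns to canonical field names, e.g.
    ``{"dob": "date_of_birth"}``, supporting arbitrary export dialects.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    if field_map:
        df = df.rename(columns=field_map)
    if id_field not in df.columns:
        raise ValueError(f"input {path} lacks id column {id_field!r}")
    known = {id_field, *RECORD_FIELDS}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("ignoring unrecognised column(s): %s", ", ".join(unknown))
        df = df.drop(columns=unknown)
    return RecordSet(_coerce_types(df, dayfirst=dayfirst), register_label, id_field)


def write_records(rs: RecordSet, path) -> None:
    """Write a register as CSV with ISO dates."""
    df = rs.df.copy()
    for col in DATE_FIELDS:
        if col in df.columns:
            df[col] = df[col].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def clean_records(rs: RecordSet, rules: CleaningRules) -> tuple[RecordSet, CleaningReport]:
    """Apply de-duplication, period restriction and category exclusions.

    Exact-duplicate rows (all fields equal, id included) are removed first;
    then records whose date of birth falls outside the inclusive
    [period_start, period_end] window — records with a *missing* date of
    birth are kept when ``retain_missing_dob`` is set; finally records whose
    ``vital_status`` is in ``exclusion_categories``.  Idempotent.
    """
    report = CleaningReport(n_input=len(rs))
    df = rs.df

    if rules.drop_duplicates:
        before = len(df)
        df = df.drop_duplicates(keep="first")
        report.duplicates_removed = before - len(df)

    if rules.period_start is not None or rules.period_end is not None:
        dob = df["date_of_birth"] if "date_of_birth" in df.columns else pd.Series(
            pd.NaT, index=df.index
        )
        in_period = pd.Series(True, index=df.index)
        if rules.period_start is not None:
            in_period &= dob >= rules.period_start
        if rules.period_end is not None:
            in_period &= dob <= rules.period_end
        keep = in_period | (dob.isna() & rules.retain_missing_dob)
        report.out_of_period_removed = int((~keep).sum())
        df = df[keep]

    if rules.exclusion_categories and "vital_status" in df.columns:
        excl = df["vital_status"].isin(rules.exclusion_categories)
        report.excluded_category_removed = int(excl.sum())
        df = df[~excl]

    report.n_output = len(df)
    return RecordSet(df.reset_index(drop=True), rs.register_label, rs.id_field), report


def derive_fields(rs: RecordSet, ethnicity_map: dict | None = None) -> RecordSet:
    """Construct derived matching variables in place of missing ones.

    * ``date_of_death`` ← ``discharge_date`` where the discharge method
      indicates an in-hospital death and no death date is recorded.
    * ``maternal_age`` ← completed years between the mother's and the
      baby's dates of birth where both are present.  Negative derived ages
      are set missing with a warning.
    * ``ethnicity`` recoded through ``ethnicity_map`` (unmapped values pass
      through unchanged).
    """
    df = rs.df.copy()

    if {"discharge_date", "discharge_method"}.issubset(df.columns):
        if "date_of_death" not in df.columns:
            df["date_of_death"] = pd.NaT
        method = df["discharge_method"].astype("string").str.lower()
        fill = df["date_of_death"].isna() & method.isin(DEATH_METHODS).fillna(False)
        df.loc[fill, "date_of_death"] = df.loc[fill, "discharge_date"]

    if {"mother_dob", "date_of_birth"}.issubset(df.columns):
        if "maternal_age" not in df.columns:
            df["maternal_age"] = pd.Series(pd.NA, index=df.index, dtype="Int64")
        need = df["maternal_age"].isna() & df["mother_dob"].notna() & df["date_of_birth"].notna()
        if need.any():
            age = _completed_years(df.loc[need, "mother_dob"], df.loc[need, "date_of_birth"])
            neg = age < 0
            if neg.any():
                logger.warning("%d negative derived maternal age(s) set missing", int(neg.sum()))
                age[neg] = pd.NA
            df.loc[need, "maternal_age"] = age

    if ethnicity_map and "ethnicity" in df.columns:
        df["ethnicity"] = df["ethnicity"].map(lambda v: ethnicity_map.get(v, v))

    return RecordSet(df, rs.register_label, rs.id_field)


def _completed_years(born: pd.Series, at: pd.Series) -> pd.Series:
    """Whole completed years between two date series (demographic floor)."""
    years = at.dt.year - born.dt.year
    before_birthday = (at.dt.month < born.dt.month) | (
        (at.dt.month == born.dt.month) & (at.dt.day < born.dt.day)
    )
    return (years - before_birthday.astype(int)).astype("Int64")


def missingness_summary(rs: RecordSet, fields: list[str] | None = None) -> pd.DataFrame:
    """Per-field missing counts and percentages of the register.

    Returns a DataFrame indexed by field with columns ``n_missing`` and
    ``pct_missing`` (percentage of all records, rounded to 2 dp).
    """
    if fields is None:
        fields = [c for c in rs.df.columns if c in RECORD_FIELDS]
    unknown = set(fields) - set(rs.df.columns)
    if unknown:
        raise ValueError(f"unknown field(s): {sorted(unknown)}")
    n = len(rs)
    rows = []
    for f in fields:
        miss = int(rs.df[f].isna().sum())
        pct = round(100.0 * miss / n, 2) if n else np.nan
        rows.append({"field": f, "n_missing": miss, "pct_missing": pct})
    return pd.DataFrame(rows).set_index("field")
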