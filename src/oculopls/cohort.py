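"""Cohort container and CSV readers/writers with validation.

A cohort is one row per participant: identifier, group (HC or PD), sex, age,
the seven clinical outcome scores (MoCA, SDMT, TMTA, TMTB, HVLT, COWAT, BAI)
and the oculomotor parameter columns declared by a :class:`ParameterCatalog`.
Missing entries are permitted everywhere except the demographic columns and
are written to CSV as empty cells; ``NA``/``NaN`` (any case) are also accepted
on read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import ParameterCatalog

GROUPS = ("HC", "PD")
SEXES = ("male", "female")

#: clinical outcome columns, in canonical order
OUTCOMES = ("MoCA", "SDMT", "TMTA", "TMTB", "HVLT", "COWAT", "BAI")

#: closed score ranges; None means unbounded on that side
SCORE_RANGES = {
    "MoCA": (0.0, 30.0),
    "SDMT": (0.0, 110.0),
    "BAI": (0.0, 63.0),
    "TMTA": (0.0, None),   # seconds, strictly positive
    "TMTB": (0.0, None),
    "HVLT": (0.0, None),
    "COWAT": (0.0, None),
}

#: scores where zero itself is out of range (times must be > 0)
_STRICT_LOWER = {"TMTA", "TMTB"}

_MISSING_TOKENS = {"", "na", "nan"}

_DEMOGRAPHICS = ("id", "group", "sex", "age")


class CohortError(Exception):
    """Base class for cohort I/O and schema errors."""


class DuplicateIdError(CohortError):
    pass


class NonNumericValueError(CohortError):
    pass


class UnknownTokenError(CohortError):
    pass


class SchemaError(CohortError):
    pass


@dataclass(frozen=True)
class ParticipantRecord:
    id: str
    group: str
    sex: str
    age: float
    scores: dict[str, float]  # missing outcomes absent from the map
    oculo: dict[str, float]   # missing parameters absent from the map


@dataclass
class CohortTable:
    """Participants x (demographics + scores + oculomotor parameters).

    ``frame`` holds one row per participant with columns
    ``id, group, sex, age, <outcomes...>, <parameters...>``; NaN encodes a
    missing value. The observation mask is derived from the frame so the two
    can never disagree.
    """

    frame: pd.DataFrame
    catalog: ParameterCatalog

    def __post_init__(self) -> None:
        ordered = list(_DEMOGRAPHICS) + list(OUTCOMES) + list(self.catalog.names)
        missing = [c for c in ordered if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"cohort frame lacks columns: {missing[:5]}")
        self.frame = self.frame.loc[:, ordered].reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def n_participants(self) -> int:
        return len(self.frame)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return self.catalog.names

    @property
    def ids(self) -> list[str]:
        return list(self.frame["id"])

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean participants x parameters frame; True where observed."""
        return self.frame[list(self.catalog.names)].notna()

    def oculo_matrix(self) -> np.ndarray:
        """Float matrix of the oculomotor block, NaN for missing."""
        return self.frame[list(self.catalog.names)].to_numpy(dtype=float)

    def available_n(self, outcome: str) -> int:
        if outcome == "Age":
            return int(self.frame["age"].notna().sum())
        return int(self.frame[outcome].notna().sum())

    def outcome_values(self, outcome: str) -> pd.Series:
        """Outcome column; the demographic pseudo-outcome 'Age' is allowed."""
        if outcome == "Age":
            return self.frame["age"]
        if outcome not in OUTCOMES:
            raise KeyError(f"unknown outcome {outcome!r}")
        return self.frame[outcome]

    @property
    def participants(self) -> list[ParticipantRecord]:
        records = []
        for _, row in self.frame.iterrows():
            scores = {o: float(row[o]) for o in OUTCOMES if pd.notna(row[o])}
            oculo = {
                p: float(row[p]) for p in self.catalog.names if pd.notna(row[p])
            }
            records.append(
                ParticipantRecord(
                    str(row["id"]), str(row["group"]), str(row["sex"]),
                    float(row["age"]), scores, oculo,
                )
            )
        return records

    def subset(self, row_mask) -> "CohortTable":
        return CohortTable(self.frame.loc[row_mask].reset_index(drop=True),
                           self.catalog)


def _parse_numeric(raw: pd.Series, column: str) -> pd.Series:
    stripped = raw.fillna("").str.strip()
    is_missing = stripped.str.lower().isin(_MISSING_TOKENS)
    values = pd.to_numeric(stripped.where(~is_missing), errors="coerce")
    bad = values.isna() & ~is_missing
    if bad.any():
        offender = stripped[bad].iloc[0]
        raise NonNumericValueError(
            f"non-numeric value {offender!r} in numeric column {column!r} "
            f"(row {int(np.flatnonzero(bad)[0])})"
        )
    return values


def read_cohort(path, catalog: ParameterCatalog | None = None) -> CohortTable:
    """Read a cohort CSV; infer the catalog from task prefixes if absent."""
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise CohortError(f"cannot read cohort file {path}: {exc}") from exc

    required = set(_DEMOGRAPHICS)
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"cohort file lacks required columns: {sorted(missing)}")

    param_cols = [c for c in frame.columns
                  if c not in _DEMOGRAPHICS and c not in OUTCOMES]
    if catalog is None:
        catalog = ParameterCatalog.from_columns(param_cols)
    else:
        extra = [c for c in param_cols if c not in catalog]
        if extra:
            raise SchemaError(
                f"columns not in catalog and not known outcomes: {extra[:5]}"
            )

    ids = frame["id"].str.strip()
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise DuplicateIdError(f"duplicate participant id {dup!r}")

    group = frame["group"].str.strip()
    bad_group = ~group.isin(GROUPS)
    if bad_group.any():
        raise UnknownTokenError(
            f"unknown group token {group[bad_group].iloc[0]!r}; expected "
            f"{'/'.join(GROUPS)}"
        )
    sex = frame["sex"].str.strip().str.lower()
    bad_sex = ~sex.isin(SEXES)
    if bad_sex.any():
        raise UnknownTokenError(
            f"unknown sex token {frame['sex'][bad_sex].iloc[0]!r}; expected "
            f"{'/'.join(SEXES)}"
        )

    columns = {"id": ids, "group": group, "sex": sex,
               "age": _parse_numeric(frame["age"], "age")}
    for col in (*OUTCOMES, *catalog.names):
        if col in frame.columns:
            columns[col] = _parse_numeric(frame[col], col)
        else:
            columns[col] = np.full(len(frame), np.nan)
    return CohortTable(pd.DataFrame(columns), catalog)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort CSV with stable column order and empty-cell missingness."""
    try:
        cohort.frame.to_csv(path, index=False, na_rep="")
    except OSError as exc:
        raise CohortError(f"cannot write cohort file {path}: {exc}") from exc


def validate_cohort(cohort: CohortTable) -> list[str]:
    """Check participant-level invariants; returns issues, never raises."""
    issues: list[str] = []
    frame = cohort.frame

    dup_ids = frame["id"][frame["id"].duplicated()]
    for pid in dup_ids.unique():
        issues.append(f"id {pid!r}: duplicate participant id")

    for _, row in frame.iterrows():
        pid = row["id"]
        if row["group"] not in GROUPS:
            issues.append(f"id {pid!r}: group {row['group']!r} not in {GROUPS}")
        if row["sex"] not in SEXES:
            issues.append(f"id {pid!r}: sex {row['sex']!r} not in {SEXES}")
        age = row["age"]
        if pd.isna(age) or age <= 0:
            issues.append(f"id {pid!r}: age must be a positive number, got {age}")
        for score, (lo, hi) in SCORE_RANGES.items():
            val = row[score]
            if pd.isna(val):
                continue
            strict = score in _STRICT_LOWER
            low_ok = val > lo if strict else val >= lo
            high_ok = hi is None or val <= hi
            if not (low_ok and high_ok):
                bound = f"({lo}, inf)" if strict and hi is None else (
                    f"[{lo}, inf)" if hi is None else f"[{lo:g}, {hi:g}]"
                )
                issues.append(
                    f"id {pid!r}: {score} = {val:g} outside range {bound}"
                )
    return issues
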