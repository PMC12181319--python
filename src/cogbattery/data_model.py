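"""Shared record types, tabular file schemas, and validated readers/writers.

Two delimited file formats move through the pipeline:

``trials.csv``
    One row per task trial, every task in one long table. Columns:
    ``participant_id, task, block, trial_index, condition, stimulus_id,
    response, correct, rt_ms, ssd_ms, participation_index``.

``survey.csv``
    One row per participant per participation: demographics, infection
    history, health-exclusion flags and raw questionnaire items
    (``phq9_1..phq9_9``, ``psq20_1..psq20_20``, ``gad7_1..gad7_7``,
    ``who5_1..who5_5``).

Files are comma-separated UTF-8 with a mandatory header; missing values are
empty fields. Times are milliseconds everywhere. The canonical in-memory
container is a :class:`pandas.DataFrame`; the dataclasses below define and
validate the row schema.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Enumerations (plain string sets: pandas-friendly, CSV-stable)
# ---------------------------------------------------------------------------

TASKS = (
    "mst_study",
    "mst_test",
    "alertness",
    "corsi_fwd",
    "corsi_bwd",
    "nback",
    "taskswitch",
    "gonogo",
    "sst",
)

CORSI_LENGTHS = tuple(str(k) for k in range(3, 10))

#: Valid ``condition`` values per task.
CONDITIONS = {
    "mst_study": {"study"},
    "mst_test": {"target", "lure", "foil"},
    "alertness": {"signal"},
    "corsi_fwd": set(CORSI_LENGTHS),
    "corsi_bwd": set(CORSI_LENGTHS),
    "nback": {"target", "nontarget"},
    "taskswitch": {"homogeneous", "repeat", "switch"},
    "gonogo": {"go", "nogo"},
    "sst": {"go", "stop"},
}

#: Valid ``response`` values per task. ``"none"`` encodes a nonresponse.
RESPONSES = {
    "mst_study": {"indoor", "outdoor", "none"},
    "mst_test": {"old", "similar", "new", "none"},
    "alertness": {"press", "none"},
    "corsi_fwd": {"press", "none"},
    "corsi_bwd": {"press", "none"},
    "nback": {"press", "none"},
    "taskswitch": {"x", "m", "none"},
    "gonogo": {"press", "none"},
    "sst": {"f", "j", "none"},
}

GENDERS = ("female", "male", "diverse")
INFECTION_STATUSES = ("never_positive", "previously_positive")
VACCINATION = ("yes", "no", "missing")

HEALTH_FLAGS = (
    "stroke",
    "cardiac_arrest",
    "cancer",
    "brain_surgery",
    "recent_major_surgery",
    "loss_of_consciousness_gt5min",
    "psychiatric_or_neurologic_disorder",
    "untreated_hypertension",
    "cognition_affecting_medication",
    "impaired_vision",
)

#: Questionnaire item columns: (prefix, n items, max item value)
ITEM_SPECS = (("phq9", 9, 3), ("psq20", 20, 3), ("gad7", 7, 3), ("who5", 5, 5))


def item_columns(prefix: str) -> list[str]:
    """Column names of one instrument's items, e.g. ``phq9_1..phq9_9``."""
    for p, n, _ in ITEM_SPECS:
        if p == prefix:
            return [f"{prefix}_{i}" for i in range(1, n + 1)]
    raise KeyError(prefix)


TRIAL_COLUMNS = [
    "participant_id",
    "task",
    "block",
    "trial_index",
    "condition",
    "stimulus_id",
    "response",
    "correct",
    "rt_ms",
    "ssd_ms",
    "participation_index",
]

SURVEY_COLUMNS = (
    [
        "participant_id",
        "participation_index",
        "age_years",
        "gender",
        "education_post_secondary",
        "infection_status",
        "months_since_pcr",
        "n_sequelae",
        "vaccinated_before_infection",
        "recovered_self_report",
        "health_exclusion_flags",
    ]
    + item_columns("phq9")
    + item_columns("psq20")
    + item_columns("gad7")
    + item_columns("who5")
)


# ---------------------------------------------------------------------------
# Errors and validation report
# ---------------------------------------------------------------------------


class SchemaError(ValueError):
    """A file does not match the documented schema (e.g. missing column)."""


class RowValidationError(ValueError):
    """One or more rows violate record invariants; message lists line numbers."""


class AmbiguityError(ValueError):
    """Duplicate records cannot be resolved deterministically."""


@dataclass
class ValidationReport:
    """Diagnostics attached to a read: per-rule counts of offending rows.

    ``line`` numbers in messages are 1-based file lines (header = line 1).
    """

    n_rows: int = 0
    n_dropped: int = 0
    messages: list[str] = field(default_factory=list)

    def add(self, lines: Sequence[int], rule: str) -> None:
        for ln in lines:
            self.messages.append(f"line {ln}: {rule}")


# ---------------------------------------------------------------------------
# Record dataclasses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialRecord:
    """One task trial.

    ``rt_ms`` is missing (``None``) iff ``response == "none"``; ``ssd_ms``
    is present iff the trial is a stop-signal stop trial.
    """

    participant_id: str
    task: str
    block: int
    trial_index: int
    condition: str
    stimulus_id: str
    response: str
    correct: Optional[bool]
    rt_ms: Optional[float] = None
    ssd_ms: Optional[float] = None
    participation_index: int = 0

    def validate(self) -> None:
        if self.task not in TASKS:
            raise RowValidationError(f"unknown task {self.task!r}")
        if self.condition not in CONDITIONS[self.task]:
            raise RowValidationError(
                f"invalid condition {self.condition!r} for task {self.task!r}"
            )
        if self.response not in RESPONSES[self.task]:
            raise RowValidationError(
                f"invalid response {self.response!r} for task {self.task!r}"
            )
        if self.block < 0 or self.trial_index < 0:
            raise RowValidationError("block/trial_index must be non-negative")
        has_rt = self.rt_ms is not None and not (
            isinstance(self.rt_ms, float) and math.isnan(self.rt_ms)
        )
        if has_rt != (self.response != "none"):
            raise RowValidationError("rt_ms must be present iff response != 'none'")
        if has_rt and self.rt_ms < 0:
            raise RowValidationError("rt_ms must be non-negative")
        has_ssd = self.ssd_ms is not None and not (
            isinstance(self.ssd_ms, float) and math.isnan(self.ssd_ms)
        )
        is_stop = self.task == "sst" and self.condition == "stop"
        if has_ssd != is_stop:
            raise RowValidationError("ssd_ms present iff sst stop trial")


@dataclass(frozen=True)
class SurveyRecord:
    """One participant's demographics, infection history and questionnaire items."""

    participant_id: str
    age_years: int
    gender: str
    education_post_secondary: bool
    infection_status: str
    months_since_pcr: Optional[int] = None
    n_sequelae: Optional[int] = None
    vaccinated_before_infection: str = "missing"
    recovered_self_report: Optional[bool] = None
    health_exclusion_flags: frozenset[str] = frozenset()
    phq9_items: tuple[int, ...] = ()
    psq20_items: tuple[int, ...] = ()
    gad7_items: tuple[int, ...] = ()
    who5_items: tuple[int, ...] = ()
    participation_index: int = 0

    def validate(self) -> None:
        if self.age_years < 18:
            raise RowValidationError("age_years must be >= 18")
        if self.gender not in GENDERS:
            raise RowValidationError(f"invalid gender {self.gender!r}")
        if self.infection_status not in INFECTION_STATUSES:
            raise RowValidationError(
                f"invalid infection_status {self.infection_status!r}"
            )
        if self.vaccinated_before_infection not in VACCINATION:
            raise RowValidationError("invalid vaccinated_before_infection")
        if self.infection_status == "never_positive":
            if self.months_since_pcr is not None:
                raise RowValidationError(
                    "months_since_pcr present but infection_status is never_positive"
                )
            if self.n_sequelae is not None:
                raise RowValidationError(
                    "n_sequelae present but infection_status is never_positive"
                )
        if self.months_since_pcr is not None and self.months_since_pcr < 0:
            raise RowValidationError("months_since_pcr must be >= 0")
        if self.n_sequelae is not None and self.n_sequelae < 0:
            raise RowValidationError("n_sequelae must be >= 0")
        unknown = set(self.health_exclusion_flags) - set(HEALTH_FLAGS)
        if unknown:
            raise RowValidationError(f"unknown health flags {sorted(unknown)}")
        for prefix, n, vmax in ITEM_SPECS:
            items = getattr(self, f"{prefix}_items")
            if len(items) != n:
                raise RowValidationError(f"{prefix} needs exactly {n} items")
            if any((v < 0 or v > vmax) for v in items):
                raise RowValidationError(f"{prefix} items must be in 0..{vmax}")


# ---------------------------------------------------------------------------
# Frame <-> record conversion
# ---------------------------------------------------------------------------


def trials_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["rt_ms"] = df["rt_ms"].astype(float)
    df["ssd_ms"] = df["ssd_ms"].astype(float)
    return df


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TrialRecord(
                participant_id=str(row.participant_id),
                task=row.task,
                block=int(row.block),
                trial_index=int(row.trial_index),
                condition=str(row.condition),
                stimulus_id=str(row.stimulus_id),
                response=row.response,
                correct=None if pd.isna(row.correct) else bool(row.correct),
                rt_ms=None if pd.isna(row.rt_ms) else float(row.rt_ms),
                ssd_ms=None if pd.isna(row.ssd_ms) else float(row.ssd_ms),
                participation_index=int(row.participation_index),
            )
        )
    return out


def survey_to_frame(records: Iterable[SurveyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d: dict = {
            "participant_id": r.participant_id,
            "participation_index": r.participation_index,
            "age_years": r.age_years,
            "gender": r.gender,
            "education_post_secondary": r.education_post_secondary,
            "infection_status": r.infection_status,
            "months_since_pcr": r.months_since_pcr,
            "n_sequelae": r.n_sequelae,
            "vaccinated_before_infection": r.vaccinated_before_infection,
            "recovered_self_report": r.recovered_self_report,
            "health_exclusion_flags": ";".join(sorted(r.health_exclusion_flags)),
        }
        for prefix, _, _ in ITEM_SPECS:
            for i, v in enumerate(getattr(r, f"{prefix}_items"), start=1):
                d[f"{prefix}_{i}"] = v
        rows.append(d)
    return pd.DataFrame(rows, columns=SURVEY_COLUMNS)


def frame_to_survey(df: pd.DataFrame) -> list[SurveyRecord]:
    out = []
    for _, row in df.iterrows():
        flags = row["health_exclusion_flags"]
        if pd.isna(flags) or flags == "":
            flagset: frozenset[str] = frozenset()
        else:
            flagset = frozenset(str(flags).split(";"))
        out.append(
            SurveyRecord(
                participant_id=str(row["participant_id"]),
                participation_index=int(row["participation_index"]),
                age_years=int(row["age_years"]),
                gender=row["gender"],
                education_post_secondary=bool(row["education_post_secondary"]),
                infection_status=row["infection_status"],
                months_since_pcr=(
                    None if pd.isna(row["months_since_pcr"]) else int(row["months_since_pcr"])
                ),
                n_sequelae=(
                    None if pd.isna(row["n_sequelae"]) else int(row["n_sequelae"])
                ),
                vaccinated_before_infection=row["vaccinated_before_infection"],
                recovered_self_report=(
                    None
                    if pd.isna(row["recovered_self_report"])
                    else bool(row["recovered_self_report"])
                ),
                health_exclusion_flags=flagset,
                **{
                    f"{prefix}_items": tuple(
                        int(row[c]) for c in item_columns(prefix)
                    )
                    for prefix, _, _ in ITEM_SPECS
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# Vectorized frame validation
# ---------------------------------------------------------------------------


def _bool_series(s: pd.Series) -> pd.Series:
    """Parse a CSV boolean column: true/false/1/0/empty -> boolean or NA."""
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "1.0": True, "0.0": False,
    }
    def conv(v):
        if pd.isna(v):
            return pd.NA
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        return mapping.get(str(v).strip().lower(), pd.NA)
    return s.map(conv).astype("boolean")


def validate_trials_frame(
    df: pd.DataFrame, on_invalid: str = "error"
) -> tuple[pd.DataFrame, ValidationReport]:
    """Validate a trials frame against the TrialRecord invariants.

    ``on_invalid="error"`` raises :class:`RowValidationError` naming offending
    lines; ``"drop"`` removes offending rows and counts them in the report.
    """
    report = ValidationReport(n_rows=len(df))
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df[TRIAL_COLUMNS].copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["stimulus_id"] = df["stimulus_id"].astype(str)
    df["condition"] = df["condition"].astype(str)
    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    df["ssd_ms"] = pd.to_numeric(df["ssd_ms"], errors="coerce")
    df["correct"] = _bool_series(df["correct"])
    for col in ("block", "trial_index", "participation_index"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    bad = pd.Series(False, index=df.index)

    def flag(mask: pd.Series, rule: str) -> None:
        nonlocal bad
        mask = mask.fillna(True) if mask.isna().any() else mask
        if mask.any():
            # +2: 1-based lines with header on line 1
            report.add((df.index[mask] + 2).tolist()[:20], rule)
            bad |= mask

    flag(~df["task"].isin(TASKS), "unknown task")
    cond_ok = pd.Series(False, index=df.index)
    resp_ok = pd.Series(False, index=df.index)
    for task in TASKS:
        m = df["task"] == task
        cond_ok |= m & df["condition"].isin(CONDITIONS[task])
        resp_ok |= m & df["response"].isin(RESPONSES[task])
    flag(df["task"].isin(TASKS) & ~cond_ok, "out-of-range condition for task")
    flag(df["task"].isin(TASKS) & ~resp_ok, "out-of-range response for task")
    for col in ("block", "trial_index", "participation_index"):
        flag(df[col].isna() | (df[col] < 0), f"{col} must be a non-negative integer")
    has_rt = df["rt_ms"].notna()
    flag(has_rt != (df["response"] != "none"), "rt_ms present iff response != 'none'")
    flag(has_rt & (df["rt_ms"] < 0), "rt_ms must be non-negative")
    is_stop = (df["task"] == "sst") & (df["condition"] == "stop")
    flag(df["ssd_ms"].notna() != is_stop, "ssd_ms present iff sst stop trial")

    if bad.any():
        if on_invalid == "error":
            raise RowValidationError(
                f"{int(bad.sum())} invalid trial row(s): "
                + "; ".join(report.messages[:10])
            )
        df = df.loc[~bad]
        report.n_dropped = int(bad.sum())
    for col in ("block", "trial_index", "participation_index"):
        df[col] = df[col].astype(int)
    return df.reset_index(drop=True), report


def validate_survey_frame(
    df: pd.DataFrame, on_invalid: str = "error"
) -> tuple[pd.DataFrame, ValidationReport]:
    """Validate a survey frame against the SurveyRecord invariants."""
    report = ValidationReport(n_rows=len(df))
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df[SURVEY_COLUMNS].copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["health_exclusion_flags"] = df["health_exclusion_flags"].fillna("").astype(str)
    for col in ("age_years", "participation_index", "months_since_pcr", "n_sequelae"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["education_post_secondary"] = _bool_series(df["education_post_secondary"])
    df["recovered_self_report"] = _bool_series(df["recovered_self_report"])
    df["vaccinated_before_infection"] = (
        df["vaccinated_before_infection"].fillna("missing").replace("", "missing")
    )
    item_cols = [c for p, _, _ in ITEM_SPECS for c in item_columns(p)]
    for c in item_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")

    bad = pd.Series(False, index=df.index)

    def flag(mask: pd.Series, rule: str) -> None:
        nonlocal bad
        if mask.isna().any():
            mask = mask.fillna(True)
        if mask.any():
            report.add((df.index[mask] + 2).tolist()[:20], rule)
            bad |= mask.astype(bool)

    flag(df["age_years"].isna() | (df["age_years"] < 18), "age_years must be >= 18")
    flag(~df["gender"].isin(GENDERS), "invalid gender")
    flag(~df["infection_status"].isin(INFECTION_STATUSES), "invalid infection_status")
    flag(~df["vaccinated_before_infection"].isin(VACCINATION),
         "invalid vaccinated_before_infection")
    flag(df["education_post_secondary"].isna(), "invalid education_post_secondary")
    never = df["infection_status"] == "never_positive"
    flag(never & df["months_since_pcr"].notna(),
         "months_since_pcr present but never_positive")
    flag(never & df["n_sequelae"].notna(), "n_sequelae present but never_positive")
    flag(df["months_since_pcr"].notna() & (df["months_since_pcr"] < 0),
         "months_since_pcr must be >= 0")
    flag(df["n_sequelae"].notna() & (df["n_sequelae"] < 0),
         "n_sequelae must be >= 0")
    known = set(HEALTH_FLAGS)
    flag(
        df["health_exclusion_flags"].map(
            lambda s: bool(set(s.split(";")) - known - {""})
        ),
        "unknown health_exclusion_flags entry",
    )
    for prefix, _, vmax in ITEM_SPECS:
        cols = item_columns(prefix)
        sub = df[cols]
        flag(
            sub.isna().any(axis=1) | (sub < 0).any(axis=1) | (sub > vmax).any(axis=1),
            f"{prefix} items must all be present and in 0..{vmax}",
        )

    if bad.any():
        if on_invalid == "error":
            raise RowValidationError(
                f"{int(bad.sum())} invalid survey row(s): "
                + "; ".join(report.messages[:10])
            )
        df = df.loc[~bad]
        report.n_dropped = int(bad.sum())
    for col in ("age_years", "participation_index"):
        df[col] = df[col].astype(int)
    for c in item_cols:
        df[c] = df[c].astype(int)
    return df.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_trials(
    path,
    task_filter: Optional[str] = None,
    on_invalid: str = "error",
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a trials.csv file.

    Returns the validated frame (row order preserved) and a
    :class:`ValidationReport`. ``task_filter`` restricts to one task after
    validation.
    """
    raw = pd.read_csv(
        path,
        dtype={"participant_id": str, "stimulus_id": str},
        float_precision="round_trip",
    )
    df, report = validate_trials_frame(raw, on_invalid=on_invalid)
    if task_filter is not None:
        if task_filter not in TASKS:
            raise ValueError(f"unknown task_filter {task_filter!r}")
        df = df[df["task"] == task_filter].reset_index(drop=True)
    return df, report


def write_trials(trials, path) -> None:
    """Write trials (frame or iterable of TrialRecord) to CSV; inverse of read."""
    if not isinstance(trials, pd.DataFrame):
        trials = trials_to_frame(trials)
    df, _ = validate_trials_frame(trials, on_invalid="error")
    out = df.copy()
    out["correct"] = out["correct"].map(
        lambda v: "" if pd.isna(v) else ("true" if v else "false")
    )
    # repr() keeps float round-trips exact across write/read
    out.to_csv(path, index=False, na_rep="", float_format=lambda v: repr(float(v)))


def read_survey(path, on_invalid: str = "error") -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a survey.csv file."""
    raw = pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip")
    return validate_survey_frame(raw, on_invalid=on_invalid)


def write_survey(survey, path) -> None:
    """Write survey rows (frame or iterable of SurveyRecord) to CSV."""
    if not isinstance(survey, pd.DataFrame):
        survey = survey_to_frame(survey)
    df, _ = validate_survey_frame(survey, on_invalid="error")
    out = df.copy()
    for col in ("education_post_secondary", "recovered_self_report"):
        out[col] = out[col].map(
            lambda v: "" if pd.isna(v) else ("true" if v else "false")
        )
    out.to_csv(path, index=False, na_rep="", float_format=lambda v: repr(float(v)))


def first_participation_only(df: pd.DataFrame) -> pd.DataFrame:
    """Keep each participant's earliest records by ``participation_index``.

    Survey-shaped tables (no ``task`` column) must end up with exactly one row
    per participant; two rows sharing the minimal participation index raise
    :class:`AmbiguityError` — the tie cannot be broken honestly. Trials tables
    (with a ``task`` column) keep, per participant and task, all rows of the
    earliest participation (one dataset spans many rows).
    """
    if "participation_index" not in df.columns:
        raise SchemaError("missing required column(s): participation_index")
    keys = ["participant_id"] + (["task"] if "task" in df.columns else [])
    idx_min = df.groupby(keys)["participation_index"].transform("min")
    first = df[df["participation_index"] == idx_min]
    if "task" not in df.columns:
        dup = first["participant_id"].duplicated(keep=False)
        if dup.any():
            ids = sorted(first.loc[dup, "participant_id"].unique())
            raise AmbiguityError(
                "duplicate records with identical participant_id and "
                f"participation_index: {ids[:5]}"
            )
    return first.reset_index(drop=True)
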