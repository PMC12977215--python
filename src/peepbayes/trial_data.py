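"""Patient-level data model for a two-arm multicentre ventilation trial.

The canonical exchange format is a UTF-8 CSV with a mandatory header whose
columns are exactly the :class:`PatientRecord` fields.  Booleans are written
as the literals ``true``/``false``; missing optional covariates are empty
cells.  Ventilator-free days (VFD) at day 28 follow the composite rule used
throughout critical-care trials: a patient who dies within 28 days of
randomization, or who is still receiving invasive ventilation at the 28-day
horizon, scores 0; otherwise whole calendar days free of invasive
ventilation count, provided the unassisted period lasted at least 24
consecutive hours.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd


class ValidationError(ValueError):
    """Raised when a record, dataset or ventilation course violates an invariant."""


class Arm(str, enum.Enum):
    LOWER_PEEP = "lower_peep"
    HIGHER_PEEP = "higher_peep"


#: Optional subgroup covariates; may be missing (complete-case analyses drop them).
COVARIATE_FIELDS = (
    "cardiac_arrest",
    "surgical_admission",
    "primary_respiratory_failure",
    "bmi",
    "pf_ratio",
    "lips",
    "apache",
)


@dataclass
class PatientRecord:
    """One randomized patient.

    ``vent_duration_days`` is the duration of invasive ventilation among
    survivors and must be present iff the patient survived to day 28;
    decedents score ``vfd = 0`` by definition.
    """

    patient_id: str
    hospital_id: int
    arm: Arm
    vfd: int
    died_by_day28: bool
    vent_duration_days: Optional[float] = None
    cardiac_arrest: Optional[bool] = None
    surgical_admission: Optional[bool] = None
    primary_respiratory_failure: Optional[bool] = None
    bmi: Optional[float] = None
    pf_ratio: Optional[float] = None
    lips: Optional[float] = None
    apache: Optional[float] = None

    def __post_init__(self) -> None:
        if isinstance(self.arm, str) and not isinstance(self.arm, Arm):
            self.arm = Arm(self.arm)

    def validate(self) -> None:
        if not (0 <= self.vfd <= 28):
            raise ValidationError(
                f"patient {self.patient_id!r}: vfd={self.vfd} outside 0..28"
            )
        if int(self.vfd) != self.vfd:
            raise ValidationError(
                f"patient {self.patient_id!r}: vfd must be an integer day count"
            )
        if self.died_by_day28 and self.vfd != 0:
            raise ValidationError(
                f"patient {self.patient_id!r}: died by day 28 but vfd={self.vfd} != 0"
            )
        if self.died_by_day28 and self.vent_duration_days is not None:
            raise ValidationError(
                f"patient {self.patient_id!r}: decedent must not carry a "
                "survivor ventilation duration"
            )
        if not self.died_by_day28 and self.vent_duration_days is None:
            raise ValidationError(
                f"patient {self.patient_id!r}: survivor is missing vent_duration_days"
            )
        if self.vent_duration_days is not None and self.vent_duration_days < 0:
            raise ValidationError(
                f"patient {self.patient_id!r}: negative ventilation duration"
            )
        if self.hospital_id < 1:
            raise ValidationError(
                f"patient {self.patient_id!r}: hospital_id must be >= 1"
            )


@dataclass
class VentilationCourse:
    """A patient's raw ventilation timeline, in real days from an arbitrary origin."""

    randomization_day: float
    ventilation_episodes: Sequence[tuple[float, float]]
    death_day: Optional[float] = None

    def validate(self) -> None:
        prev_end = -math.inf
        for i, (start, end) in enumerate(self.ventilation_episodes):
            if end < start:
                raise ValidationError(
                    f"episode {i}: reversed interval ({start}, {end})"
                )
            if start < prev_end:
                raise ValidationError(
                    f"episode {i}: overlaps or precedes the previous episode "
                    f"(starts at {start}, previous ends at {prev_end})"
                )
            prev_end = end
        if self.death_day is not None and self.death_day < self.randomization_day:
            raise ValidationError("death_day precedes randomization_day")


def compute_vfd(
    course: VentilationCourse,
    horizon: int = 28,
    *,
    count_mid_course_windows: bool = True,
    min_window_days: float = 1.0,
) -> int:
    """Ventilator-free days between randomization and ``randomization + horizon``.

    Days are half-open ``[k, k+1)`` intervals from randomization; a day is
    ventilator-free iff the patient is unassisted for its entirety and the
    unassisted window containing it lasted at least ``min_window_days``
    (default 24 consecutive hours).  Zero is returned when the patient dies
    within the horizon or is still ventilated at the horizon (equivalently,
    ventilated for more than the whole observation window without a
    qualifying liberation).  Windows between extubation and reintubation
    count by default; set ``count_mid_course_windows=False`` to credit only
    the terminal unassisted period.
    """
    course.validate()
    t0 = course.randomization_day
    if course.death_day is not None and course.death_day <= t0 + horizon:
        return 0

    # Episodes clipped to the observation window, relative to randomization.
    episodes = []
    for start, end in course.ventilation_episodes:
        s, e = start - t0, end - t0
        if e <= s:  # zero-length episode: no ventilation time
            continue
        if e <= 0 or s >= horizon:
            continue
        if e >= horizon:
            return 0  # still ventilated at the horizon
        episodes.append((max(s, 0.0), e))

    # Maximal unassisted windows within [0, horizon].
    windows: list[tuple[float, float, bool]] = []  # (start, end, is_terminal)
    cursor = 0.0
    for s, e in episodes:
        if s > cursor:
            windows.append((cursor, s, False))
        cursor = max(cursor, e)
    if cursor < horizon:
        windows.append((cursor, float(horizon), True))

    free = 0
    for w_start, w_end, terminal in windows:
        if w_end - w_start < min_window_days:
            continue
        if not terminal and not count_mid_course_windows:
            continue
        free += max(0, math.floor(w_end) - math.ceil(w_start))
    return free


@dataclass
class TrialDataset:
    records: list[PatientRecord]
    n_hospitals: int
    provenance: str = "file"  # "synthetic" | "file"
    seed: Optional[int] = None

    def validate(self) -> None:
        arms = set()
        for rec in self.records:
            rec.validate()
            if not (1 <= rec.hospital_id <= self.n_hospitals):
                raise ValidationError(
                    f"patient {rec.patient_id!r}: hospital_id {rec.hospital_id} "
                    f"outside 1..{self.n_hospitals}"
                )
            arms.add(rec.arm)
        if arms != {Arm.LOWER_PEEP, Arm.HIGHER_PEEP}:
            raise ValidationError("both trial arms must be non-empty")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        cols = [f.name for f in fields(PatientRecord)]
        rows = []
        for rec in self.records:
            row = {c: getattr(rec, c) for c in cols}
            row["arm"] = rec.arm.value
            rows.append(row)
        return pd.DataFrame(rows, columns=cols)


_BOOL_COLUMNS = (
    "died_by_day28",
    "cardiac_arrest",
    "surgical_admission",
    "primary_respiratory_failure",
)
_MANDATORY = ("patient_id", "hospital_id", "arm", "vfd", "died_by_day28")


def _fmt_cell(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    return repr(value) if isinstance(value, float) else str(value)


def write_trial_table(data: TrialDataset, path: str | Path) -> Path:
    """Write the canonical CSV; the dataset is validated first."""
    data.validate()
    path = Path(path)
    cols = [f.name for f in fields(PatientRecord)]
    lines = [",".join(cols)]
    for rec in data.records:
        cells = []
        for c in cols:
            v = getattr(rec, c)
            if c == "arm":
                v = rec.arm.value
            cells.append(_fmt_cell(v))
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _parse_bool(cell: str, row: int, col: str) -> bool:
    if cell == "true":
        return True
    if cell == "false":
        return False
    raise ValidationError(f"row {row}: column {col!r} must be true/false, got {cell!r}")


def read_trial_table(path: str | Path, n_hospitals: Optional[int] = None) -> TrialDataset:
    """Read and validate the canonical CSV; failures cite row numbers (1 = first data row)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValidationError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[PatientRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        try:
            kwargs: dict = {
                "patient_id": row_d["patient_id"],
                "hospital_id": int(row_d["hospital_id"]),
                "arm": Arm(row_d["arm"]),
                "vfd": int(row_d["vfd"]),
                "died_by_day28": _parse_bool(row_d["died_by_day28"], i, "died_by_day28"),
            }
            dur = row_d.get("vent_duration_days", "")
            kwargs["vent_duration_days"] = float(dur) if dur != "" else None
            for c in ("cardiac_arrest", "surgical_admission", "primary_respiratory_failure"):
                cell = row_d.get(c, "")
                kwargs[c] = _parse_bool(cell, i, c) if cell != "" else None
            for c in ("bmi", "pf_ratio", "lips", "apache"):
                cell = row_d.get(c, "")
                kwargs[c] = float(cell) if cell != "" else None
            rec = PatientRecord(**kwargs)
            rec.validate()
            records.append(rec)
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError("; ".join(errors))

    if n_hospitals is None:
        n_hospitals = max((r.hospital_id for r in records), default=0)
    data = TrialDataset(records=records, n_hospitals=n_hospitals, provenance="file")
    data.validate()
    return data
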