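"""Measurement-session data model and flat-file I/O.

A validation session records nine consecutive blood-pressure measurements
per participant, alternating between a two-observer auscultatory reference
(mercury sphygmomanometer, readings to the nearest 2 mmHg) and the test
device: BPA, BPB, BP1 ... BP7.  Odd slots (BPA, BP1, BP3, BP5, BP7) are
simultaneous blinded observer pairs; even slots (BPB, BP2, BP4, BP6) are
device readings.  BPA/BPB are familiarisation/entry measurements; the
analysis proper uses BP1-BP7.

Cohorts are stored as one CSV row per subject with cohort-level screening
metadata (total screened, exclusion counts) in ``#``-prefixed header lines,
so a cohort is a single flat, diff-able text file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "PressureReading",
    "ObserverPairReading",
    "SubjectSession",
    "Cohort",
    "SchemaError",
    "SessionValidationError",
    "CuffError",
    "EXCLUSION_REASONS",
    "OBSERVER_SLOTS",
    "DEVICE_SLOTS",
    "ANALYSIS_DEVICE_SLOTS",
    "SLOT_ORDER",
    "read_sessions",
    "write_sessions",
    "select_cuff",
]

SCHEMA_VERSION = "1"

#: The nine measurement slots in acquisition order.
SLOT_ORDER = ("BPA", "BPB", "BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7")
OBSERVER_SLOTS = ("BPA", "BP1", "BP3", "BP5", "BP7")
DEVICE_SLOTS = ("BPB", "BP2", "BP4", "BP6")
#: Device slots entering the 99-pair comparison (BPB is an entry reading).
ANALYSIS_DEVICE_SLOTS = ("BP2", "BP4", "BP6")

#: Exclusion reasons of the screening funnel, in report order.
EXCLUSION_REASONS = (
    "ranges completed",
    "range adjustment",
    "arrhythmias",
    "device failure",
    "poor quality sounds",
    "cuff size unavailable",
    "observer disagreement",
    "distribution",
    "other",
)

DEVICE_RANGE_MMHG = (0, 299)


class SchemaError(ValueError):
    """Input file does not match the published column schema."""


class SessionValidationError(ValueError):
    """One or more rows violate a session invariant.

    Carries the full list of per-row messages so no violation is silently
    dropped.
    """

    def __init__(self, messages: list[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


class CuffError(ValueError):
    """Arm circumference below the smallest supported cuff."""


@dataclass(frozen=True)
class PressureReading:
    """A single SBP/DBP reading in mmHg, within the device detection range."""

    sbp: int
    dbp: int

    def __post_init__(self) -> None:
        lo, hi = DEVICE_RANGE_MMHG
        if not (lo <= self.dbp < self.sbp <= hi):
            raise ValueError(
                f"require {lo} <= dbp < sbp <= {hi}, got sbp={self.sbp} dbp={self.dbp}"
            )


@dataclass(frozen=True)
class ObserverPairReading:
    """Simultaneous blinded readings from two observers.

    Auscultatory readings are recorded to the nearest 2 mmHg, so the
    per-pair reference mean is always an integer.  ``repeat_count`` is the
    number of times the pair was re-taken because the observers disagreed
    by 4 mmHg or more.
    """

    observer1: PressureReading
    observer2: PressureReading
    repeat_count: int = 0

    def __post_init__(self) -> None:
        for obs in (self.observer1, self.observer2):
            if obs.sbp % 2 or obs.dbp % 2:
                raise ValueError(
                    f"observer readings must be multiples of 2 mmHg, got {obs}"
                )
        if self.repeat_count < 0:
            raise ValueError("repeat_count must be non-negative")


@dataclass(frozen=True)
class SubjectSession:
    """One participant: demographics plus the ordered 9-slot sequence."""

    subject_id: str
    sex: str  # "male" | "female"
    age: float
    arm_circumference: float
    wrist_circumference: float
    height: float
    weight: float
    bmi: float
    bpa: ObserverPairReading
    bpb: PressureReading
    bp1: ObserverPairReading
    bp2: PressureReading
    bp3: ObserverPairReading
    bp4: PressureReading
    bp5: ObserverPairReading
    bp6: PressureReading
    bp7: ObserverPairReading

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.height and self.weight and self.bmi:
            implied = self.weight / (self.height / 100.0) ** 2
            if abs(implied - self.bmi) > 0.1:
                raise ValueError(
                    f"subject {self.subject_id}: bmi {self.bmi} inconsistent with "
                    f"weight/height^2 = {implied:.2f}"
                )

    def slot(self, name: str):
        """Return the reading at a named slot (e.g. ``"BP2"``)."""
        return getattr(self, name.lower())

    def observer_pairs(self) -> dict[str, ObserverPairReading]:
        return {s: self.slot(s) for s in OBSERVER_SLOTS}

    def device_readings(self) -> dict[str, PressureReading]:
        return {s: self.slot(s) for s in DEVICE_SLOTS}


@dataclass
class Cohort:
    """Recruited sessions plus screening-funnel accounting.

    Invariant: ``screened_total - sum(exclusions.values()) == len(sessions)``.
    """

    sessions: list[SubjectSession]
    screened_total: int = 0
    exclusions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.screened_total == 0 and not self.exclusions:
            self.screened_total = len(self.sessions)
        unknown = set(self.exclusions) - set(EXCLUSION_REASONS)
        if unknown:
            raise ValueError(f"unknown exclusion reasons: {sorted(unknown)}")
        if self.screened_total - self.total_excluded != len(self.sessions):
            raise ValueError(
                f"screening accounting broken: screened {self.screened_total} - "
                f"excluded {self.total_excluded} != recruited {len(self.sessions)}"
            )

    @property
    def total_excluded(self) -> int:
        return sum(self.exclusions.values())

    def __len__(self) -> int:
        return len(self.sessions)


# --- CSV schema -----------------------------------------------------------

_DEMO_COLUMNS = (
    "subject_id",
    "sex",
    "age",
    "arm_circumference",
    "wrist_circumference",
    "height",
    "weight",
    "bmi",
)


def _pressure_columns() -> list[str]:
    cols: list[str] = []
    for slot in SLOT_ORDER:
        if slot in OBSERVER_SLOTS:
            cols += [
                f"{slot}_o1_sbp",
                f"{slot}_o1_dbp",
                f"{slot}_o2_sbp",
                f"{slot}_o2_dbp",
                f"{slot}_repeats",
            ]
        else:
            cols += [f"{slot}_sbp", f"{slot}_dbp"]
    return cols


CSV_COLUMNS = tuple(_DEMO_COLUMNS) + tuple(_pressure_columns())


def _session_to_row(s: SubjectSession) -> dict:
    row: dict = {
        "subject_id": s.subject_id,
        "sex": s.sex,
        "age": s.age,
        "arm_circumference": s.arm_circumference,
        "wrist_circumference": s.wrist_circumference,
        "height": s.height,
        "weight": s.weight,
        "bmi": s.bmi,
    }
    for slot in OBSERVER_SLOTS:
        p: ObserverPairReading = s.slot(slot)
        row[f"{slot}_o1_sbp"] = p.observer1.sbp
        row[f"{slot}_o1_dbp"] = p.observer1.dbp
        row[f"{slot}_o2_sbp"] = p.observer2.sbp
        row[f"{slot}_o2_dbp"] = p.observer2.dbp
        row[f"{slot}_repeats"] = p.repeat_count
    for slot in DEVICE_SLOTS:
        r: PressureReading = s.slot(slot)
        row[f"{slot}_sbp"] = r.sbp
        row[f"{slot}_dbp"] = r.dbp
    return row


def _row_to_session(row: Mapping) -> SubjectSession:
    kwargs: dict = {
        "subject_id": str(row["subject_id"]),
        "sex": str(row["sex"]),
        "age": float(row["age"]),
        "arm_circumference": float(row["arm_circumference"]),
        "wrist_circumference": float(row["wrist_circumference"]),
        "height": float(row["height"]),
        "weight": float(row["weight"]),
        "bmi": float(row["bmi"]),
    }
    for slot in OBSERVER_SLOTS:
        kwargs[slot.lower()] = ObserverPairReading(
            observer1=PressureReading(
                int(row[f"{slot}_o1_sbp"]), int(row[f"{slot}_o1_dbp"])
            ),
            observer2=PressureReading(
                int(row[f"{slot}_o2_sbp"]), int(row[f"{slot}_o2_dbp"])
            ),
            repeat_count=int(row[f"{slot}_repeats"]),
        )
    for slot in DEVICE_SLOTS:
        kwargs[slot.lower()] = PressureReading(
            int(row[f"{slot}_sbp"]), int(row[f"{slot}_dbp"])
        )
    return SubjectSession(**kwargs)


def write_sessions(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV with screening metadata in comment lines."""
    path = Path(path)
    lines = [
        f"# schema_version={SCHEMA_VERSION}",
        f"# screened_total={cohort.screened_total}",
    ]
    for reason in EXCLUSION_REASONS:
        n = cohort.exclusions.get(reason, 0)
        if n:
            lines.append(f"# exclusion:{reason}={n}")
    frame = pd.DataFrame(
        [_session_to_row(s) for s in cohort.sessions], columns=list(CSV_COLUMNS)
    )
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def _parse_metadata(path: Path) -> dict:
    meta: dict = {"screened_total": None, "exclusions": {}, "schema_version": None}
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" not in body:
                continue
            key, _, value = body.partition("=")
            key = key.strip()
            if key == "screened_total":
                meta["screened_total"] = int(value)
            elif key == "schema_version":
                meta["schema_version"] = value.strip()
            elif key.startswith("exclusion:"):
                meta["exclusions"][key.split(":", 1)[1]] = int(value)
    return meta


def read_sessions(path: str | Path, schema_version: str = SCHEMA_VERSION) -> Cohort:
    """Read a cohort CSV, validating schema and every session invariant.

    Raises :class:`SchemaError` if the header does not match the published
    column set, and :class:`SessionValidationError` carrying every row-level
    violation (non-numeric pressure, dbp >= sbp, odd observer reading, ...)
    rather than dropping offending rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _parse_metadata(path)
    if meta["schema_version"] is not None and meta["schema_version"] != schema_version:
        raise SchemaError(
            f"schema_version {meta['schema_version']!r} != expected {schema_version!r}"
        )
    frame = pd.read_csv(path, comment="#", dtype={"subject_id": str})
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")

    sessions: list[SubjectSession] = []
    errors: list[str] = []
    for _, row in frame.iterrows():
        sid = row.get("subject_id", "<unknown>")
        try:
            sessions.append(_row_to_session(row))
        except (ValueError, TypeError) as exc:
            errors.append(f"subject {sid}: {exc}")
    if errors:
        raise SessionValidationError(errors)

    screened = meta["screened_total"]
    exclusions = meta["exclusions"]
    if screened is None:
        screened = len(sessions) + sum(exclusions.values())
    return Cohort(sessions=sessions, screened_total=screened, exclusions=exclusions)


# --- Cuff selection -------------------------------------------------------

def select_cuff(arm_circumference: float) -> str:
    """Select the auscultatory cuff size from arm circumference in cm.

    Boundaries follow the printed ranges: small 17-21.9, regular 22-31.9,
    large 32-42, extra-large above 42.  Values in the unprinted gaps
    (e.g. 21.95) are rounded half-up to one decimal before lookup; below
    17 cm no supported cuff exists.
    """
    if arm_circumference <= 0:
        raise ValueError("arm_circumference must be positive")
    # round half-up to one decimal so 21.95 -> 22.0 (regular)
    ac = math.floor(arm_circumference * 10 + 0.5) / 10
    if ac < 17:
        raise CuffError(f"no cuff supports arm circumference {arm_circumference} cm")
    if ac <= 21.9:
        return "small"
    if ac <= 31.9:
        return "regular"
    if ac <= 42:
        return "large"
    return "extra_large"
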