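"""Study manifest, domain types, and prior-to-death (PTD) alignment.

Every retrospective endpoint in the pipeline is re-indexed by the number of
days between a recording session and the subject's day of sudden death
("days prior to death", PTD) and then pooled into 10-day bins
(bin 1 = 1-10 days PTD, bin 2 = 11-20, ...). The day of death itself is
PTD 0 and never carries a session: the earliest valid retrospective index
is 1 day PTD.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

WEANING_DAY = 21


class Genotype(str, enum.Enum):
    WT = "WT"
    KO = "KO"


class Diet(str, enum.Enum):
    SD = "SD"
    KD = "KD"


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class Modality(str, enum.Enum):
    EEG_EMG = "EEG_EMG"
    ECG = "ECG"
    AIRWAY = "AIRWAY"
    OXIMETRY = "OXIMETRY"


class AlignmentError(ValueError):
    """A session cannot be placed on the retrospective PTD axis."""


class ContractError(ValueError):
    """Inputs violate an operation's contract (mixed endpoints, bad session sets)."""


@dataclass(frozen=True)
class Subject:
    """One animal: genotype, diet treatment, sex, and day of death.

    ``death_day`` is the postnatal day of sudden death for knockouts; the
    paired wild-type littermate is euthanized the same day, so its
    ``death_day`` equals the paired KO's. All KO subjects die (100%
    mortality), hence ``death_day`` is required for them.
    """

    subject_id: str
    genotype: Genotype
    diet: Diet
    sex: Sex
    death_day: int | None = None
    paired_littermate: str | None = None

    def __post_init__(self) -> None:
        if self.genotype is Genotype.KO and self.death_day is None:
            raise ValueError(
                f"subject {self.subject_id}: KO subjects require a death_day "
                "(the genotype is fully penetrant for premature death)"
            )
        if self.death_day is not None and self.death_day <= WEANING_DAY:
            raise ValueError(
                f"subject {self.subject_id}: death_day {self.death_day} must be "
                f"after weaning (day {WEANING_DAY})"
            )

    @property
    def cohort(self) -> str:
        return f"{self.genotype.value}-{self.diet.value}"


@dataclass
class Session:
    """One recording of one modality on one postnatal day."""

    subject_id: str
    modality: Modality
    record_day: int
    duration_s: float
    payload: object | None = None
    payload_path: str | None = None


@dataclass(frozen=True)
class PTDFrame:
    """One endpoint value re-indexed by days prior to death."""

    subject_id: str
    ptd: int
    value: float
    endpoint_name: str
    units: str = ""

    @property
    def bin_index(self) -> int:
        return bin_ptd(self.ptd)


def compute_ptd(record_day: int, death_day: int) -> int:
    """Days prior to death for a session recorded on ``record_day``.

    A session recorded the day before death is at 1 day PTD; a session on
    the death day itself is rejected (no subject died during a recording,
    and PTD 0 is reserved for the death event).
    """
    if record_day > death_day:
        raise AlignmentError(
            f"record_day {record_day} is after death_day {death_day}"
        )
    ptd = death_day - record_day
    if ptd < 1:
        raise AlignmentError(
            f"session on record_day {record_day} coincides with the death day "
            f"({death_day}); the earliest retrospective index is 1 day PTD"
        )
    return ptd


def bin_ptd(ptd: int) -> int:
    """10-day PTD bin index: bin 1 covers 1-10 days PTD, bin 2 covers 11-20, ...

    Equivalent to ``ceil(ptd / 10)`` on positive integers.
    """
    if ptd <= 0:
        raise ValueError(f"ptd must be a positive integer, got {ptd}")
    return -(-int(ptd) // 10)


def pool_by_bin(
    frames: Iterable[PTDFrame],
    subjects: Mapping[str, Subject] | None = None,
) -> dict[tuple[str, str, int], list[PTDFrame]]:
    """Partition PTD frames into (genotype, diet, bin) groups.

    Every input frame lands in exactly one group. All frames must carry the
    same endpoint; ``subjects`` maps subject_id to Subject to resolve the
    cohort (when omitted, subject_id is used verbatim as the cohort key's
    first element and the diet slot is empty).
    """
    frames = list(frames)
    if not frames:
        return {}
    endpoints = {f.endpoint_name for f in frames}
    if len(endpoints) > 1:
        raise ContractError(
            f"pool_by_bin requires a single endpoint, got {sorted(endpoints)}"
        )
    groups: dict[tuple[str, str, int], list[PTDFrame]] = {}
    for f in frames:
        if subjects is not None:
            subj = subjects[f.subject_id]
            key = (subj.genotype.value, subj.diet.value, f.bin_index)
        else:
            key = (f.subject_id, "", f.bin_index)
        groups.setdefault(key, []).append(f)
    return groups


# ---------------------------------------------------------------------------
# Manifest I/O

_MANIFEST_COLUMNS = [
    "subject_id", "genotype", "diet", "sex", "death_day", "paired_littermate",
]
_SESSION_COLUMNS = [
    "subject_id", "modality", "record_day", "duration_s", "payload_path",
]


def subjects_to_frame(subjects: Iterable[Subject]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": s.subject_id,
            "genotype": s.genotype.value,
            "diet": s.diet.value,
            "sex": s.sex.value,
            "death_day": s.death_day,
            "paired_littermate": s.paired_littermate,
        }
        for s in subjects
    ]
    return pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)


def frame_to_subjects(df: pd.DataFrame) -> list[Subject]:
    out = []
    for row in df.itertuples(index=False):
        death = row.death_day
        death = None if pd.isna(death) else int(death)
        pair = row.paired_littermate
        pair = None if (pair is None or (isinstance(pair, float) and pd.isna(pair))) else str(pair)
        out.append(
            Subject(
                subject_id=str(row.subject_id),
                genotype=Genotype(row.genotype),
                diet=Diet(row.diet),
                sex=Sex(row.sex),
                death_day=death,
                paired_littermate=pair,
            )
        )
    return out


def write_manifest(subjects: Iterable[Subject], path: str | Path) -> None:
    subjects_to_frame(subjects).to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[Subject]:
    return frame_to_subjects(pd.read_csv(path))


def sessions_to_frame(sessions: Iterable[Session]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": s.subject_id,
            "modality": s.modality.value,
            "record_day": s.record_day,
            "duration_s": s.duration_s,
            "payload_path": s.payload_path,
        }
        for s in sessions
    ]
    return pd.DataFrame(rows, columns=_SESSION_COLUMNS)


def write_sessions(sessions: Iterable[Session], path: str | Path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_sessions(path: str | Path) -> list[Session]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        pp = row.payload_path
        pp = None if (isinstance(pp, float) and pd.isna(pp)) else pp
        out.append(
            Session(
                subject_id=str(row.subject_id),
                modality=Modality(row.modality),
                record_day=int(row.record_day),
                duration_s=float(row.duration_s),
                payload_path=pp,
            )
        )
    return out


def manifest_to_json(subjects: Iterable[Subject]) -> str:
    """JSON rendering of the manifest; round-trips bit-identically."""
    records = subjects_to_frame(subjects).to_dict(orient="records")
    return json.dumps(records, indent=1, sort_keys=True, default=_json_default)


def manifest_from_json(text: str) -> list[Subject]:
    return frame_to_subjects(pd.DataFrame(json.loads(text), columns=_MANIFEST_COLUMNS))


def _json_default(obj):
    try:
        import numpy as np

        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {obj!r}")


def validate_sessions(subject: Subject, sessions: list[Session]) -> None:
    """Check a subject's session list for one modality.

    Sessions must be strictly increasing in record_day and must not extend
    past the subject's death day.
    """
    days = [s.record_day for s in sessions]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ContractError(
            f"subject {subject.subject_id}: session days not strictly increasing: {days}"
        )
    if subject.death_day is not None and days and max(days) > subject.death_day:
        raise AlignmentError(
            f"subject {subject.subject_id}: session on day {max(days)} is after "
            f"death_day {subject.death_day}"
        )
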