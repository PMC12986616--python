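"""Seizure frequency, severity, duration, and per-session seizure burden.

Seizures enter as annotated events (onset, duration, modified-Racine
severity grade 1-6); identification and video adjudication happen upstream.
The burden of a session is the sum over its seizures of severity x duration
(severity-seconds); all events are included, with no filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .study import ContractError

RACINE_MIN, RACINE_MAX = 1, 6


@dataclass(frozen=True)
class SeizureEvent:
    """One seizure: onset and duration in session seconds, severity grade 1-6."""

    subject_id: str
    record_day: int
    onset_s: float
    duration_s: float
    severity: int

    def __post_init__(self) -> None:
        if not (RACINE_MIN <= self.severity <= RACINE_MAX):
            raise ValueError(
                f"severity must be a modified-Racine grade in "
                f"[{RACINE_MIN}, {RACINE_MAX}], got {self.severity}"
            )
        if self.duration_s <= 0:
            raise ValueError(f"duration must be positive, got {self.duration_s}")
        if self.onset_s < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset_s}")


def _one_session(events: list[SeizureEvent]) -> None:
    keys = {(e.subject_id, e.record_day) for e in events}
    if len(keys) > 1:
        raise ContractError(
            f"events span multiple sessions: {sorted(keys)}; per-session "
            "metrics require events from exactly one session"
        )


def seizure_count(events: Iterable[SeizureEvent]) -> int:
    """Number of seizures in one recording session (no filtering)."""
    events = list(events)
    _one_session(events)
    return len(events)


def seizure_burden(events: Iterable[SeizureEvent]) -> float:
    """Per-session seizure burden: sum of severity x duration (severity-s).

    Zero for a session with no seizures; additive over disjoint subsets of
    a session's events.
    """
    events = list(events)
    _one_session(events)
    return float(sum(e.severity * e.duration_s for e in events))
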