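"""Bradycardia quantification from ECG segment mean heart rates.

Noise-free ECG segments of 25-75 P-Q-R-S-T complexes yield one mean heart
rate each. Clean wild-type segment means pooled across diets define a
Gaussian reference (mean, SD); a segment is operationally bradycardic when
its mean rate falls strictly below the reference mean minus two reference
SDs (770 - 2x43 = 684 bpm at the reference values). The per-subject
bradycardic fraction is bradycardic clean segments over total clean
segments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class InsufficientDataError(ValueError):
    pass


class ReferenceError_(ValueError):
    """WT reference cannot be estimated (e.g., every segment was noisy)."""


class ExcludedSegmentError(ValueError):
    """A noisy segment reached a stage that requires clean input."""


@dataclass(frozen=True)
class EcgSegment:
    subject_id: str
    record_day: int
    n_beats: int
    mean_hr: float
    noisy: bool = False


@dataclass(frozen=True)
class WtReference:
    """Wild-type heart-rate Gaussian and the derived bradycardia threshold."""

    mean: float
    sd: float

    @property
    def threshold(self) -> float:
        return self.mean - 2.0 * self.sd

    def to_json(self) -> str:
        return json.dumps(
            {"mean": self.mean, "sd": self.sd, "threshold": self.threshold}
        )

    @classmethod
    def from_json(cls, text: str) -> "WtReference":
        d = json.loads(text)
        return cls(mean=d["mean"], sd=d["sd"])


def segment_mean_hr(beat_times: Sequence[float]) -> float:
    """Mean heart rate (bpm) of one segment from its beat times.

    60 * n_intervals / (last - first beat time): the rate whose constant
    inter-beat interval would span the segment in the same time.
    """
    t = np.asarray(beat_times, dtype=float)
    if t.size < 2:
        raise InsufficientDataError(
            f"need >= 2 beats to compute a segment rate, got {t.size}"
        )
    span = t[-1] - t[0]
    if span <= 0:
        raise InsufficientDataError("beat times must be strictly increasing")
    return float(60.0 * (t.size - 1) / span)


def wt_reference(wt_segment_means: Iterable[float]) -> WtReference:
    """Gaussian reference from pooled clean WT segment means (both diets).

    Sample SD (n-1 denominator). The threshold is mean - 2*SD exactly; at
    the reference values 770 +/- 43 bpm this is 684 bpm.
    """
    x = np.asarray(list(wt_segment_means), dtype=float)
    if x.size < 2:
        raise ReferenceError_(
            f"need >= 2 clean WT segments for a reference, got {x.size}"
        )
    return WtReference(mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)))


def classify_bradycardia(segment: EcgSegment | float, ref: WtReference) -> bool:
    """True iff the segment's mean rate is strictly below the threshold."""
    if isinstance(segment, EcgSegment):
        if segment.noisy:
            raise ExcludedSegmentError(
                f"segment of {segment.subject_id} on day {segment.record_day} is "
                "noisy; noisy segments must be excluded before classification"
            )
        hr = segment.mean_hr
    else:
        hr = float(segment)
    return hr < ref.threshold


def bradycardic_fraction(
    segments: Iterable[EcgSegment],
    ref: WtReference,
) -> float:
    """Per-subject bradycardic fraction: bradycardic / total clean segments.

    Noisy segments are excluded from numerator and denominator alike.
    """
    clean = [s for s in segments if not s.noisy]
    if not clean:
        raise InsufficientDataError("no clean segments; fraction is undefined")
    n_brady = sum(classify_bradycardia(s, ref) for s in clean)
    return n_brady / len(clean)


def fraction_from_rates(rates: Sequence[float], ref: WtReference) -> float:
    """Bradycardic fraction of a bare array of clean segment mean rates."""
    r = np.asarray(rates, dtype=float)
    if r.size == 0:
        raise InsufficientDataError("no clean segments; fraction is undefined")
    return float(np.mean(r < ref.threshold))


# ---------------------------------------------------------------------------
# Tabular I/O

SEGMENT_COLUMNS = ["subject_id", "record_day", "n_beats", "mean_hr_bpm", "noisy"]


def segments_to_frame(segments: Iterable[EcgSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "record_day": s.record_day,
                "n_beats": s.n_beats,
                "mean_hr_bpm": s.mean_hr,
                "noisy": s.noisy,
            }
            for s in segments
        ],
        columns=SEGMENT_COLUMNS,
    )


def frame_to_segments(df: pd.DataFrame) -> list[EcgSegment]:
    return [
        EcgSegment(
            subject_id=str(r.subject_id),
            record_day=int(r.record_day),
            n_beats=int(r.n_beats),
            mean_hr=float(r.mean_hr_bpm),
            noisy=bool(r.noisy),
        )
        for r in df.itertuples(index=False)
    ]


def write_reference(ref: WtReference, path: str | Path) -> None:
    Path(path).write_text(ref.to_json())
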