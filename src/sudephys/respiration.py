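"""Apnea detection from airflow traces.

An apnea is a decrease in airflow of at least 90% sustained for two or more
complete respiratory cycles. The two-cycle criterion is evaluated against
the subject's baseline eupneic breathing rate: two cycles last 2 * 60 / f
seconds at f breaths per minute. The airflow decrease is referenced to a
running-median breath-amplitude baseline, which is robust to single deep or
shallow breaths.

Detection pipeline: Hilbert amplitude envelope smoothed over one breath
period -> causal running median baseline over the preceding
``baseline_window`` breaths -> maximal contiguous runs where the envelope
is at or below 10% of baseline and the run lasts at least the two-cycle
window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps


class InsufficientDataError(ValueError):
    pass


class DegenerateSignalError(ValueError):
    pass


@dataclass(frozen=True)
class ApneaEvent:
    onset_s: float
    duration_s: float
    depth: float  # maximal fractional airflow decrease in [0, 1]

    def __post_init__(self) -> None:
        if self.depth < 0.90:
            raise ValueError(
                f"an emitted apnea must have depth >= 0.90, got {self.depth:.3f}"
            )


def two_cycle_window(breath_rate: float) -> float:
    """Duration (s) of two complete respiratory cycles at ``breath_rate`` bpm."""
    if breath_rate <= 0:
        raise ValueError(f"breath rate must be positive, got {breath_rate}")
    return 2.0 * 60.0 / breath_rate


def estimate_breath_rate(
    airflow: np.ndarray, sample_rate: float, window_s: float = 30.0
) -> float:
    """Eupneic breathing rate (breaths/min) from the first ``window_s`` of trace.

    Counts positive peaks with a refractory distance of a tenth of a second;
    used when the rate is not supplied by the acquisition metadata.
    """
    n = min(len(airflow), int(window_s * sample_rate))
    seg = np.asarray(airflow[:n], dtype=float)
    prominence = 0.3 * np.std(seg)
    peaks, _ = sps.find_peaks(seg, distance=max(1, int(0.1 * sample_rate)),
                              prominence=prominence)
    if len(peaks) < 2:
        raise InsufficientDataError("too few breaths to estimate a rate")
    span_s = (peaks[-1] - peaks[0]) / sample_rate
    return 60.0 * (len(peaks) - 1) / span_s


def breath_envelope(
    airflow: np.ndarray, sample_rate: float, breath_rate: float
) -> np.ndarray:
    """Per-sample breath amplitude: sliding maximum of |airflow|.

    The window spans 0.6 of a respiratory cycle — long enough to always
    contain a flow extremum during eupnea (|flow| peaks every half cycle),
    short enough that the envelope collapses within a fraction of a cycle
    of a cessation's true edges. Unlike an analytic-signal magnitude, the
    sliding maximum is strictly local, so amplitude steps produce no
    ringing that could fragment a sub-threshold run.
    """
    from scipy.ndimage import maximum_filter1d

    x = np.asarray(airflow, dtype=float)
    w = max(1, int(round(0.6 * (60.0 / breath_rate) * sample_rate)))
    return maximum_filter1d(np.abs(x), size=w, mode="nearest")


def running_median_baseline(
    envelope: np.ndarray,
    sample_rate: float,
    breath_rate: float,
    baseline_window: int = 10,
) -> np.ndarray:
    """Causal running median of the envelope over the preceding N breaths."""
    w = max(1, int(round(baseline_window * (60.0 / breath_rate) * sample_rate)))
    s = pd.Series(envelope)
    base = s.shift(1).rolling(window=w, min_periods=1).median().to_numpy()
    base[0] = envelope[0]
    return base


def detect_apneas(
    airflow: np.ndarray,
    sample_rate: float,
    breath_rate: float | None = None,
    baseline_window: int = 10,
    drop_fraction: float = 0.90,
) -> list[ApneaEvent]:
    """Detect apneic episodes in an airflow trace.

    Returns disjoint, time-ordered events where the breath envelope stays at
    or below (1 - drop_fraction) of the running-median baseline for at least
    two complete respiratory cycles. ``depth`` is the maximal fractional
    decrease within the event.
    """
    x = np.asarray(airflow, dtype=float)
    if breath_rate is None:
        breath_rate = estimate_breath_rate(x, sample_rate)
    win_s = two_cycle_window(breath_rate)
    if len(x) < 5 * win_s * sample_rate:
        raise InsufficientDataError(
            f"trace of {len(x)/sample_rate:.1f}s is shorter than five "
            f"two-cycle windows ({5*win_s:.1f}s)"
        )
    env = breath_envelope(x, sample_rate, breath_rate)
    base = running_median_baseline(env, sample_rate, breath_rate, baseline_window)
    if np.median(base) <= 0 or not np.isfinite(base).all():
        raise DegenerateSignalError("baseline breath amplitude is zero or undefined")
    mask = env <= (1.0 - drop_fraction) * base
    min_len = int(np.ceil(win_s * sample_rate))
    events = []
    for i0, i1 in _runs(mask):
        if i1 - i0 >= min_len:
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.where(base[i0:i1] > 0, env[i0:i1] / base[i0:i1], 0.0)
            events.append(
                ApneaEvent(
                    onset_s=i0 / sample_rate,
                    duration_s=(i1 - i0) / sample_rate,
                    depth=float(1.0 - np.min(rel)),
                )
            )
    return events


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous True runs as half-open index intervals."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        ends = np.r_[ends, len(m)]
    return list(zip(starts.tolist(), ends.tolist()))


def detect_apneas_bruteforce(
    airflow: np.ndarray,
    sample_rate: float,
    breath_rate: float,
    baseline_window: int = 10,
    drop_fraction: float = 0.90,
) -> list[tuple[int, int]]:
    """Reference detector: exhaustive per-sample scan for maximal intervals.

    Walks the trace sample by sample in pure Python, testing the sub-
    threshold criterion and the two-cycle duration criterion directly, with
    no vectorized run extraction. Intended as an independent cross-check on
    small traces; returns half-open sample-index intervals.
    """
    env = breath_envelope(np.asarray(airflow, dtype=float), sample_rate, breath_rate)
    base = running_median_baseline(env, sample_rate, breath_rate, baseline_window)
    thr = (1.0 - drop_fraction) * base
    min_len = int(np.ceil(two_cycle_window(breath_rate) * sample_rate))
    out = []
    i, n = 0, len(env)
    while i < n:
        if env[i] <= thr[i]:
            j = i
            while j < n and env[j] <= thr[j]:
                j += 1
            if j - i >= min_len:
                out.append((i, j))
            i = j
        else:
            i += 1
    return out


def apnea_count(events: Iterable[ApneaEvent]) -> int:
    """Number of apneic episodes in one collection session."""
    return len(list(events))


def susceptibility(counts_per_session: Sequence[int]) -> bool:
    """True iff any session in the subject's bin had at least one apnea."""
    counts = list(counts_per_session)
    if not counts:
        raise InsufficientDataError("susceptibility needs >= 1 session in the bin")
    return any(c >= 1 for c in counts)


def cohort_susceptible_proportion(per_subject: Mapping[str, Sequence[int]]) -> float:
    """Fraction of subjects with at least one apneic session."""
    flags = [susceptibility(c) for c in per_subject.values()]
    return float(np.mean(flags)) if flags else 0.0
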