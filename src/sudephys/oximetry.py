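"""Pulse-oximetry quality control and hypoxemia quantification.

The oximeter acquires eight parameters (SaO2, pulse rate, breathing rate,
and five others) at 5 Hz. A measurement is error-free only when all eight
parameters were successfully acquired — a sample with valid SaO2 but any
other failed parameter is excluded. A session with fewer than 50 error-free
measurements is excluded entirely. Error-free measurements below 90% SaO2
are demarcated hypoxemic; a subject's hypoxemia fraction pools hypoxemic
over error-free counts across their QC-passing sessions.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HYPOXEMIA_THRESHOLD = 90.0
MIN_ERROR_FREE = 50

OK_COLUMNS = [f"ok_{i}" for i in range(1, 9)]


class EmptyResultError(ValueError):
    pass


def filter_error_free(stream: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly the measurements with all eight parameter flags valid."""
    if stream.empty:
        return stream.copy()
    mask = stream[OK_COLUMNS].all(axis=1)
    return stream.loc[mask].copy()


def session_qc(kept_count: int, min_count: int = MIN_ERROR_FREE) -> bool:
    """True (keep) iff the session has at least ``min_count`` error-free samples."""
    return kept_count >= min_count


def flag_hypoxemia(sao2: float | np.ndarray) -> bool | np.ndarray:
    """Hypoxemia demarcation: strictly below 90% SaO2."""
    result = np.asarray(sao2) < HYPOXEMIA_THRESHOLD
    return bool(result) if np.isscalar(sao2) else result


def hypoxemia_fraction(sessions: Iterable[pd.DataFrame]) -> float:
    """Per-subject hypoxemia fraction pooled over QC-passing sessions.

    Each element of ``sessions`` is one raw oximetry stream; error-free
    filtering and session QC are applied here, and the fraction is hypoxemic
    over error-free counts pooled across the surviving sessions.
    """
    hypox = 0
    total = 0
    for stream in sessions:
        kept = filter_error_free(stream)
        if not session_qc(len(kept)):
            continue
        total += len(kept)
        hypox += int(flag_hypoxemia(kept["sao2_pct"].to_numpy()).sum())
    if total == 0:
        raise EmptyResultError(
            "no QC-passing session (each needs >= "
            f"{MIN_ERROR_FREE} error-free measurements)"
        )
    return hypox / total


def pooled_mean_sao2(sessions: Iterable[pd.DataFrame]) -> float:
    """Mean SaO2 over error-free measurements of QC-passing sessions."""
    values = []
    for stream in sessions:
        kept = filter_error_free(stream)
        if session_qc(len(kept)):
            values.append(kept["sao2_pct"].to_numpy())
    if not values:
        raise EmptyResultError("no QC-passing session")
    return float(np.concatenate(values).mean())


def qc_report(streams: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-session QC summary: total, error-free, kept flag, hypoxemic count."""
    rows = []
    for i, stream in enumerate(streams):
        kept = filter_error_free(stream)
        rows.append(
            {
                "session": i,
                "n_total": len(stream),
                "n_error_free": len(kept),
                "qc_pass": session_qc(len(kept)),
                "n_hypoxemic": int(flag_hypoxemia(kept["sao2_pct"].to_numpy()).sum())
                if len(kept)
                else 0,
            }
        )
    return pd.DataFrame(rows)
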