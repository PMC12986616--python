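"""Vigilance-state staging from EEG/EMG band power.

Recordings are divided into 10 s epochs. Two features summarize each epoch:
EEG power in the delta band (0.5-4 Hz) and EMG power (10-50 Hz). After a
log-transform and standardization, principal components of the feature
matrix are partitioned into three clusters, which are mapped to vigilance
states by their feature profile:

* highest mean delta power  -> NREM sleep (high delta, low-medium EMG)
* of the remaining two, higher mean EMG -> wake (low delta, high EMG)
* the last                  -> REM sleep (low delta, low EMG)

Epochs overlapping a seizure or a husbandry-check interval are excluded
before occupancy is computed; occupancies are normalized to the number of
analyzed (non-excluded) epochs per subject.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .study import ContractError

DELTA_BAND = (0.5, 4.0)
EMG_BAND = (10.0, 50.0)


class State(str, enum.Enum):
    WAKE = "WAKE"
    NREM = "NREM"
    REM = "REM"
    EXCLUDED = "EXCLUDED"


class ExclusionReason(str, enum.Enum):
    SEIZURE = "SEIZURE"
    CHECK = "CHECK"


class StagingError(ValueError):
    """Feature matrix is degenerate; automatic staging is not possible."""


def band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Mean periodogram power of ``x`` within ``band`` (signal-units^2).

    Hann-tapered periodogram; the band mean is taken over the frequency
    bins whose centers fall inside [lo, hi].
    """
    freqs, pxx = sps.periodogram(x, fs=fs, window="hann")
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        return 0.0
    return float(np.mean(pxx[sel]))


def epoch_features(
    eeg: np.ndarray,
    emg: np.ndarray,
    fs: float,
    epoch_len_s: float = 10.0,
) -> pd.DataFrame:
    """Per-epoch delta-band EEG power and EMG-band power.

    One row per complete epoch; a trailing partial epoch is dropped.
    """
    eeg = np.asarray(eeg, dtype=float)
    emg = np.asarray(emg, dtype=float)
    if eeg.shape != emg.shape:
        raise ContractError(
            f"EEG and EMG traces must share length, got {eeg.shape} vs {emg.shape}"
        )
    n_per = int(round(epoch_len_s * fs))
    n_epochs = len(eeg) // n_per
    if n_epochs == 0:
        raise ContractError(
            f"trace shorter than one epoch ({len(eeg)} samples < {n_per})"
        )
    rows = []
    for i in range(n_epochs):
        seg = slice(i * n_per, (i + 1) * n_per)
        rows.append(
            {
                "epoch_index": i,
                "delta_power": band_power(eeg[seg], fs, DELTA_BAND),
                "emg_power": band_power(emg[seg], fs, EMG_BAND),
            }
        )
    return pd.DataFrame(rows)


def _farthest_point_init(X: np.ndarray, k: int) -> np.ndarray:
    """Deterministic maximin (farthest-point) seeding for k-means.

    Starts from the point farthest from the centroid, then greedily adds the
    point maximizing the distance to the nearest chosen seed. A pure
    function of the data: staging is reproducible without any RNG.
    """
    center = X.mean(axis=0)
    first = int(np.argmax(((X - center) ** 2).sum(axis=1)))
    chosen = [first]
    d2 = ((X - X[first]) ** 2).sum(axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d2))
        chosen.append(nxt)
        d2 = np.minimum(d2, ((X - X[nxt]) ** 2).sum(axis=1))
    return X[chosen]


def classify_states(
    features: pd.DataFrame,
    seed: int = 0,
    n_components: int = 2,
) -> pd.Series:
    """Label non-excluded epochs WAKE / NREM / REM.

    log10-transform + z-score the (delta, EMG) powers, project onto
    principal components, 3-means with deterministic farthest-point
    initialization, then map clusters to states by the delta-first rule
    (see module docstring). The mapping is rule-based, so any permutation
    of cluster indices yields identical state labels.
    """
    feats = features[["delta_power", "emg_power"]].to_numpy(dtype=float)
    if len(feats) < 3:
        raise StagingError(f"need >= 3 epochs to stage, got {len(feats)}")
    if (feats <= 0).any():
        feats = np.maximum(feats, 1e-300)
    logf = np.log10(feats)
    sd = logf.std(axis=0, ddof=0)
    if (sd < 1e-12).any():
        raise StagingError(
            "degenerate feature variance; automatic staging is unreliable — "
            "configure states manually"
        )
    z = (logf - logf.mean(axis=0)) / sd
    pcs = PCA(n_components=min(n_components, z.shape[1]), random_state=seed).fit_transform(z)
    init = _farthest_point_init(pcs, 3)
    km = KMeans(n_clusters=3, init=init, n_init=1, random_state=seed).fit(pcs)
    labels = km.labels_

    # delta-first mapping: cluster mean log-delta decides NREM, then EMG
    mean_delta = np.array([logf[labels == c, 0].mean() for c in range(3)])
    mean_emg = np.array([logf[labels == c, 1].mean() for c in range(3)])
    nrem = int(np.argmax(mean_delta))
    rest = [c for c in range(3) if c != nrem]
    wake = rest[int(np.argmax(mean_emg[rest]))]
    rem = next(c for c in rest if c != wake)
    name = {nrem: State.NREM.value, wake: State.WAKE.value, rem: State.REM.value}
    return pd.Series(
        [name[c] for c in labels], index=features["epoch_index"], name="state"
    )


def apply_exclusions(
    labels: pd.Series,
    seizure_intervals: list[tuple[float, float]] = (),
    check_intervals: list[tuple[float, float]] = (),
    epoch_len_s: float = 10.0,
) -> pd.DataFrame:
    """Mark epochs overlapping seizure or husbandry-check intervals EXCLUDED.

    An epoch [i*L, (i+1)*L) is excluded when it overlaps any interval; the
    reason records which kind (seizure exclusions take precedence when both
    overlap). Returns epoch_index, state, exclusion_reason.
    """
    out = pd.DataFrame(
        {"epoch_index": labels.index, "state": labels.to_numpy(dtype=object)}
    )
    out["exclusion_reason"] = None
    for intervals, reason in (
        (check_intervals, ExclusionReason.CHECK),
        (seizure_intervals, ExclusionReason.SEIZURE),
    ):
        for a, b in intervals:
            lo = out["epoch_index"] * epoch_len_s
            hi = lo + epoch_len_s
            hit = (lo < b) & (hi > a)
            out.loc[hit, "state"] = State.EXCLUDED.value
            out.loc[hit, "exclusion_reason"] = reason.value
    return out


def occupancy(labels: pd.Series | pd.DataFrame) -> dict[str, float]:
    """State occupancy fractions over analyzed (non-excluded) epochs.

    wake + NREM + REM sums to 1 within numerical precision; raises when no
    analyzable epoch remains.
    """
    states = labels["state"] if isinstance(labels, pd.DataFrame) else labels
    analyzed = states[states != State.EXCLUDED.value]
    if len(analyzed) == 0:
        raise ContractError("no analyzable (non-excluded) epochs")
    n = len(analyzed)
    return {
        "wake": float((analyzed == State.WAKE.value).sum() / n),
        "nrem": float((analyzed == State.NREM.value).sum() / n),
        "rem": float((analyzed == State.REM.value).sum() / n),
        "n_analyzed": n,
        "n_excluded": int((states == State.EXCLUDED.value).sum()),
    }
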