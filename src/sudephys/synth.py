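"""Synthetic study generator.

Builds complete synthetic cohorts — survival times, ECG segment means,
airflow traces with injected apneas, 5 Hz pulse-oximetry streams, and
epoch-structured EEG/EMG — whose cohort-level summary statistics match the
configured targets, so every downstream analysis stage can be exercised and
validated by parameter recovery.

Design notes
------------
* Survival times are truncated normal (mean, SD = SEM * sqrt(n)), rounded to
  integer postnatal days. The study only constrains the cohort mean and SEM,
  and this is the minimal model reproducing both; it is a modeling choice,
  not a claim about the underlying mortality process.
* Bradycardic heart rates and hypoxemic SaO2 dips are modeled as a second
  mixture component with a fixed "low" distribution sitting clearly beyond
  the detection threshold (620 +/- 30 bpm; 85 +/- 3 %SaO2). Only the mixing
  weight is calibrated, which keeps calibration one-dimensional: the weight
  solves  w*P(low < thr) + (1-w)*P(high < thr) = target_fraction  in closed
  form via normal CDFs.
* Every generator takes an explicit ``numpy.random.Generator`` or integer
  seed and is fully deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats

from .study import WEANING_DAY


class CalibrationError(ValueError):
    """A configured target moment cannot be reached with the given components."""


class ConfigError(ValueError):
    """A StudyConfig field is outside its valid domain."""


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class CohortSurvival:
    """Mean +/- SEM (days) and n of one cohort's age at sudden death."""

    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class StudyConfig:
    """All generator targets, defaulting to the study's printed cohort values.

    Fractions are probabilities in [0, 1]; heart rates in bpm; SaO2 in
    percent saturation; apnea rates in episodes per 3-minute session.
    """

    # Survival: KO cohorts (WT littermates are euthanized on the paired KO's
    # death day, so they carry no independent survival distribution).
    survival: dict[str, CohortSurvival] = field(
        default_factory=lambda: {
            "KO-SD": CohortSurvival(mean=57.0, sem=2.0, n=22),
            "KO-KD": CohortSurvival(mean=77.0, sem=4.0, n=19),
        }
    )

    # Wild-type heart-rate reference (Gaussian over clean-segment means).
    wt_hr_mean: float = 770.0
    wt_hr_sd: float = 43.0

    # Bradycardic mixture: low component fixed; per-(cohort, PTD-bin) target
    # fraction of segment means below the mean - 2 SD threshold.
    hr_low_mean: float = 620.0
    hr_low_sd: float = 30.0
    bradycardic_fraction: dict[tuple[str, int], float] = field(
        default_factory=lambda: {
            ("KO-SD", 1): 0.457,
            ("KO-SD", 2): 0.457,  # elevated over the last 20 days of life
            ("KO-SD", 3): 0.072,
            ("WT-SD", 1): 0.072,
            ("WT-SD", 2): 0.072,
            ("WT-SD", 3): 0.072,
            ("KO-KD", 1): 0.072,  # diet treatment normalizes the fraction
            ("KO-KD", 2): 0.072,
            ("KO-KD", 3): 0.072,
            ("WT-KD", 1): 0.072,
            ("WT-KD", 2): 0.072,
            ("WT-KD", 3): 0.072,
        }
    )
    segments_per_session: int = 16
    segment_noise_fraction: float = 0.1

    # SaO2 streams: (target mean %, target below-90 fraction) per cohort-bin.
    spo2_low_mean: float = 85.0
    spo2_low_sd: float = 3.0
    spo2_base_sd: float = 1.0
    spo2_rate_hz: float = 5.0
    spo2_error_rate: float = 0.1
    spo2_targets: dict[tuple[str, int], tuple[float, float]] = field(
        default_factory=lambda: {
            ("KO-SD", 1): (90.05, 0.33),
            ("KO-SD", 2): (93.92, 0.08),
            ("KO-KD", 1): (95.13, 0.02),
            ("KO-KD", 2): (96.83, 0.0),
            ("WT-SD", 1): (96.48, 0.0),
            ("WT-SD", 2): (96.48, 0.0),
            ("WT-KD", 1): (96.48, 0.0),
            ("WT-KD", 2): (96.48, 0.0),
        }
    )

    # Apnea: mean injected episodes per 3-minute session (Poisson).
    breath_rate: float = 120.0  # breaths/min, eupneic baseline
    airflow_rate_hz: float = 100.0
    apnea_rate: dict[tuple[str, int], float] = field(
        default_factory=lambda: {
            ("KO-SD", 1): 6.3,
            ("KO-SD", 2): 2.0,
            ("KO-SD", 3): 0.8,
            ("KO-KD", 1): 0.9,
            ("KO-KD", 2): 1.0,
            ("KO-KD", 3): 2.6,
            ("WT-SD", 1): 0.1,
            ("WT-SD", 2): 0.1,
            ("WT-SD", 3): 0.1,
            ("WT-KD", 1): 0.2,
            ("WT-KD", 2): 0.2,
            ("WT-KD", 3): 0.2,
        }
    )

    # Sleep: target state occupancies (wake, NREM, REM) per cohort and the
    # state-conditional log-power feature distributions.
    eeg_fs: float = 2000.0
    epoch_len_s: float = 10.0
    sleep_occupancy: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "WT-SD": (0.45, 0.45, 0.10),
            "WT-KD": (0.47, 0.43, 0.10),
            "KO-SD": (0.80, 0.17, 0.03),  # sleep deficiency near death
            "KO-KD": (0.75, 0.21, 0.04),
        }
    )

    seed: int = 0

    def __post_init__(self) -> None:
        for cohort, cs in self.survival.items():
            if cs.n < 2:
                raise ConfigError(f"{cohort}: survival n must be >= 2, got {cs.n}")
            if cs.mean <= WEANING_DAY:
                raise ConfigError(
                    f"{cohort}: survival mean {cs.mean} must exceed weaning day {WEANING_DAY}"
                )
            if cs.sem < 0:
                raise ConfigError(f"{cohort}: SEM must be >= 0")
        for d in (self.bradycardic_fraction, self.apnea_rate):
            for key, v in d.items():
                if v < 0:
                    raise ConfigError(f"{key}: rate/fraction must be >= 0, got {v}")
        for key, v in self.bradycardic_fraction.items():
            if v > 1:
                raise ConfigError(f"{key}: fraction must be <= 1, got {v}")
        for key, (m, f) in self.spo2_targets.items():
            if not (0 <= f <= 1):
                raise ConfigError(f"{key}: hypoxemia fraction must be in [0,1], got {f}")
            if not (50 < m <= 100):
                raise ConfigError(f"{key}: SaO2 mean must be in (50, 100], got {m}")
        for cohort, occ in self.sleep_occupancy.items():
            if abs(sum(occ) - 1.0) > 1e-9:
                raise ConfigError(f"{cohort}: occupancies must sum to 1, got {occ}")
        if self.wt_hr_sd <= 0 or self.hr_low_sd <= 0 or self.spo2_low_sd <= 0:
            raise ConfigError("all SDs must be > 0")
        if self.breath_rate <= 0:
            raise ConfigError("breath_rate must be > 0")

    @property
    def hr_threshold(self) -> float:
        """Operational bradycardia cutoff: WT mean minus two WT SDs."""
        return self.wt_hr_mean - 2.0 * self.wt_hr_sd

    # -- serialization (tuple-keyed maps become "COHORT:bin" strings) --

    def to_dict(self) -> dict:
        def keyed(d):
            return {
                (k if isinstance(k, str) else f"{k[0]}:{k[1]}"): list(v)
                if isinstance(v, tuple) else v
                for k, v in d.items()
            }

        out = {
            "survival": {k: [v.mean, v.sem, v.n] for k, v in self.survival.items()},
            "bradycardic_fraction": keyed(self.bradycardic_fraction),
            "spo2_targets": keyed(self.spo2_targets),
            "apnea_rate": keyed(self.apnea_rate),
            "sleep_occupancy": {k: list(v) for k, v in self.sleep_occupancy.items()},
        }
        for f in (
            "wt_hr_mean", "wt_hr_sd", "hr_low_mean", "hr_low_sd",
            "segments_per_session", "segment_noise_fraction", "spo2_low_mean",
            "spo2_low_sd", "spo2_base_sd", "spo2_rate_hz", "spo2_error_rate",
            "breath_rate", "airflow_rate_hz", "eeg_fs", "epoch_len_s", "seed",
        ):
            out[f] = getattr(self, f)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        def unkey(m, tupled=False):
            out = {}
            for k, v in m.items():
                cohort, b = k.split(":")
                out[(cohort, int(b))] = tuple(v) if tupled else v
            return out

        d = dict(d)
        kwargs = {
            "survival": {
                k: CohortSurvival(mean=v[0], sem=v[1], n=int(v[2]))
                for k, v in d.pop("survival").items()
            },
            "bradycardic_fraction": unkey(d.pop("bradycardic_fraction")),
            "spo2_targets": unkey(d.pop("spo2_targets"), tupled=True),
            "apnea_rate": unkey(d.pop("apnea_rate")),
            "sleep_occupancy": {
                k: tuple(v) for k, v in d.pop("sleep_occupancy").items()
            },
        }
        kwargs.update(d)
        return cls(**kwargs)

    def save(self, path) -> None:
        """Write the config as YAML (.yaml/.yml) or JSON (anything else)."""
        import json
        from pathlib import Path

        import yaml

        p = Path(path)
        if p.suffix in (".yaml", ".yml"):
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            p.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "StudyConfig":
        import json
        from pathlib import Path

        import yaml

        p = Path(path)
        text = p.read_text()
        data = yaml.safe_load(text) if p.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Survival


def gen_survival(
    n: int,
    mean: float,
    sem: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw n integer ages at sudden death (postnatal days).

    Normal with SD = sem * sqrt(n), truncated below at day 22 (the day after
    weaning), rounded to integer days. The configuration is rejected when
    truncation would remove more than half the mass, since the sample mean
    could then no longer converge to ``mean``.
    """
    if n < 2:
        raise ConfigError(f"need n >= 2 survival draws, got {n}")
    if mean <= WEANING_DAY:
        raise ConfigError(f"survival mean must exceed day {WEANING_DAY}, got {mean}")
    sd = sem * np.sqrt(n)
    lower = WEANING_DAY + 1
    if sd > 0 and stats.norm.cdf(lower, loc=mean, scale=sd) > 0.5:
        raise ConfigError(
            f"survival normal({mean}, {sd:.2f}) loses >50% of its mass below day {lower}"
        )
    rng = _rng(seed)
    if sd == 0:
        return np.full(n, round(mean), dtype=int)
    a = (lower - mean) / sd
    draws = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
    return np.rint(draws).astype(int)


# ---------------------------------------------------------------------------
# Mixture calibration


def calibrate_mixture_weight(
    target_fraction: float,
    threshold: float,
    low: tuple[float, float],
    high: tuple[float, float],
) -> float:
    """Mixing weight w on the low component so the two-normal mixture has the
    target below-threshold probability.

    Solves  w * P(low < thr) + (1 - w) * P(high < thr) = target  exactly:
    the mixture CDF is linear in w, so  w = (target - p_hi) / (p_lo - p_hi).
    Raises when the target lies outside [p_hi, p_lo], reporting the
    attainable range.
    """
    p_lo = stats.norm.cdf(threshold, loc=low[0], scale=low[1])
    p_hi = stats.norm.cdf(threshold, loc=high[0], scale=high[1])
    if p_lo <= p_hi:
        raise CalibrationError(
            f"low component must have more mass below {threshold} than the high "
            f"component (P_low={p_lo:.4g} <= P_high={p_hi:.4g})"
        )
    tol = 1e-12
    if not (p_hi - tol <= target_fraction <= p_lo + tol):
        raise CalibrationError(
            f"target fraction {target_fraction} unreachable; attainable range is "
            f"[{p_hi:.6g}, {p_lo:.6g}] for threshold {threshold}"
        )
    w = (target_fraction - p_hi) / (p_lo - p_hi)
    return float(np.clip(w, 0.0, 1.0))


# ---------------------------------------------------------------------------
# ECG segment means


def gen_ecg_segments(
    cohort: str,
    bin_index: int,
    config: StudyConfig,
    n_segments: int | None = None,
    noise_fraction: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment mean heart rates (bpm) and noisy flags for one subject-session.

    KO clean-segment means are drawn from the calibrated two-normal mixture
    for the cohort and PTD bin; wild-type segments are drawn from the pure
    reference Gaussian (the WT distribution is the Gaussian that defines the
    bradycardia threshold, so its below-threshold mass is the ~2.3% normal
    tail by construction). A configurable fraction of segments is flagged
    noisy to exercise the exclusion path (noisy segments carry draws too,
    but downstream analysis must discard them).
    """
    rng = _rng(seed)
    if n_segments is None:
        n_segments = config.segments_per_session
    if noise_fraction is None:
        noise_fraction = config.segment_noise_fraction
    target = config.bradycardic_fraction.get((cohort, bin_index), 0.072)
    p_normal_tail = stats.norm.cdf(
        config.hr_threshold, config.wt_hr_mean, config.wt_hr_sd
    )
    if cohort.startswith("WT") or target <= p_normal_tail:
        w = 0.0
    else:
        w = calibrate_mixture_weight(
            target, config.hr_threshold,
            (config.hr_low_mean, config.hr_low_sd),
            (config.wt_hr_mean, config.wt_hr_sd),
        )
    from_low = rng.random(n_segments) < w
    hr = np.where(
        from_low,
        rng.normal(config.hr_low_mean, config.hr_low_sd, n_segments),
        rng.normal(config.wt_hr_mean, config.wt_hr_sd, n_segments),
    )
    noisy = rng.random(n_segments) < noise_fraction
    return hr, noisy


def gen_wt_segment_means(
    n: int,
    config: StudyConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw n wild-type segment mean heart rates from the reference Gaussian."""
    if config is None:
        config = StudyConfig()
    rng = _rng(seed)
    return rng.normal(config.wt_hr_mean, config.wt_hr_sd, n)


# ---------------------------------------------------------------------------
# Airflow with injected apneas


def gen_airflow(
    duration_s: float,
    breath_rate: float,
    apnea_spec: Sequence[tuple[float, float, float]] = (),
    sample_rate: float = 100.0,
    amplitude_jitter: float = 0.05,
    noise_sd: float = 0.01,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Quasi-sinusoidal breath train with injected apneic pauses.

    ``apnea_spec`` is a list of (onset_s, n_cycles, depth) events: within
    each event the breath envelope is scaled by (1 - depth). Events must lie
    within the trace and must not overlap. Returns (trace, ground_truth)
    where ground truth records each injected event with onset, duration,
    depth, and whether it meets the >= 90% decrease criterion.
    """
    rng = _rng(seed)
    if breath_rate <= 0:
        raise ValueError("breath_rate must be > 0")
    f = breath_rate / 60.0  # Hz
    cycle_s = 1.0 / f
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate

    # per-breath amplitude jitter, piecewise-constant over breaths
    n_breaths = int(np.ceil(duration_s * f)) + 1
    amps = rng.normal(1.0, amplitude_jitter, n_breaths).clip(0.5, 1.5)
    breath_idx = np.minimum((t * f).astype(int), n_breaths - 1)
    envelope = amps[breath_idx]

    truth: list[dict] = []
    intervals: list[tuple[float, float]] = []
    for onset, n_cycles, depth in apnea_spec:
        dur = n_cycles * cycle_s
        if onset < 0 or onset + dur > duration_s:
            raise ValueError(
                f"apnea at {onset}s for {dur:.2f}s falls outside the {duration_s}s trace"
            )
        for a, b in intervals:
            if onset < b and onset + dur > a:
                raise ValueError("apnea events must not overlap")
        intervals.append((onset, onset + dur))
        mask = (t >= onset) & (t < onset + dur)
        envelope = np.where(mask, envelope * (1.0 - depth), envelope)
        truth.append(
            {
                "onset_s": float(onset),
                "duration_s": float(dur),
                "depth": float(depth),
                "meets_criterion": bool(depth >= 0.90 and n_cycles >= 2),
            }
        )
    truth.sort(key=lambda e: e["onset_s"])
    trace = envelope * np.sin(2 * np.pi * f * t) + rng.normal(0, noise_sd, n)
    return trace, truth


def place_apneas(
    n_events: int,
    duration_s: float,
    breath_rate: float,
    n_cycles: float = 3.0,
    depth: float = 0.95,
    margin_s: float = 5.0,
    seed: int | np.random.Generator | None = None,
) -> list[tuple[float, float, float]]:
    """Randomly place non-overlapping apnea events inside a session.

    Events are kept ``margin_s`` from the trace edges and at least one
    eupneic cycle plus the detector's baseline window apart, so each injected
    event is separately resolvable.
    """
    rng = _rng(seed)
    cycle_s = 60.0 / breath_rate
    dur = n_cycles * cycle_s
    gap = max(2.0 * cycle_s, 1.0)
    usable = duration_s - 2 * margin_s
    max_fit = int(usable // (dur + gap))
    n_events = min(n_events, max_fit)
    if n_events <= 0:
        return []
    # sample onsets by spacing n_events slots uniformly with random jitter
    slots = np.sort(rng.choice(max_fit, size=n_events, replace=False))
    onsets = margin_s + slots * (dur + gap) + rng.uniform(0, gap * 0.5, n_events)
    return [(float(o), float(n_cycles), float(depth)) for o in onsets]


# ---------------------------------------------------------------------------
# SaO2 streams


def calibrate_spo2(
    target_mean: float,
    target_hypox_fraction: float,
    low: tuple[float, float] = (85.0, 3.0),
    base_sd: float = 1.0,
    threshold: float = 90.0,
) -> tuple[float, float]:
    """Solve for (mixture weight, baseline-component mean).

    Two constraints — the overall mean M and the below-threshold fraction F
    — and two unknowns. The mean constraint pins the baseline mean for any
    weight,  mu_b(w) = (M - w*mu_low) / (1 - w),  reducing the fraction
    constraint to a scalar root problem in w:

        g(w) = w * P(low < thr) + (1 - w) * P(N(mu_b(w), sd_b) < thr) - F.

    g can have two roots (a small-w solution where the baseline's own tail
    supplies the hypoxemia, and a larger-w one where the dip component
    does); the largest root is returned, i.e., the mixture whose baseline
    sits clearly above the threshold and whose dips carry the hypoxemic
    mass — the configuration the dip model is meant to represent.
    """
    from scipy.optimize import brentq

    mu_low, sd_low = low
    if mu_low >= target_mean:
        raise CalibrationError(
            f"dip mean {mu_low} must lie below the target mean {target_mean}"
        )
    p_low = stats.norm.cdf(threshold, mu_low, sd_low)
    if target_hypox_fraction > p_low:
        raise CalibrationError(
            f"hypoxemia fraction {target_hypox_fraction} exceeds the dip "
            f"component's own sub-{threshold} mass {p_low:.4g}"
        )

    def mu_b(w: float) -> float:
        return (target_mean - w * mu_low) / (1.0 - w)

    def g(w: float) -> float:
        return (
            w * p_low
            + (1.0 - w) * stats.norm.cdf(threshold, mu_b(w), base_sd)
            - target_hypox_fraction
        )

    # cap w where the baseline mean would run past the 100% ceiling
    w_cap = 1.0 - 1e-9
    if mu_b(w_cap) > 100.0:
        # solve mu_b(w) = 100 analytically: w = (100 - M) / (100 - mu_low)
        w_cap = min(w_cap, (100.0 - target_mean) / (100.0 - mu_low))
    grid = np.linspace(0.0, w_cap, 2001)
    vals = np.array([g(w) for w in grid])
    sign_change = np.nonzero(np.diff(np.signbit(vals)))[0]
    if sign_change.size:
        i = sign_change[-1]  # largest root: dips, not the baseline tail
        w = float(brentq(g, grid[i], grid[i + 1], xtol=1e-14))
        return w, float(mu_b(w))
    j = int(np.argmin(np.abs(vals)))
    if abs(vals[j]) < 1e-6:
        return float(grid[j]), float(mu_b(float(grid[j])))
    raise CalibrationError(
        f"(mean {target_mean}, fraction {target_hypox_fraction}) unreachable "
        f"with dip {low} and baseline SD {base_sd}; residual {vals[j]:.3g}"
    )


def gen_spo2_stream(
    duration_s: float,
    rate_hz: float = 5.0,
    target_mean: float = 96.48,
    target_hypox_fraction: float = 0.0,
    error_rate: float = 0.1,
    low: tuple[float, float] = (85.0, 3.0),
    base_sd: float = 1.0,
    seed: int | np.random.Generator | None = None,
):
    """5 Hz oximetry stream with 8 per-sample parameter-validity flags.

    Returns a DataFrame with columns t_s, sao2_pct, ok_1..ok_8, behavior.
    SaO2 is a two-component mixture (baseline vs hypoxemic dips) calibrated
    so the error-free stream hits the target mean and below-90 fraction;
    values are capped at 100%. Each sample independently corrupts at least
    one non-SaO2 parameter with probability ``error_rate``; behavior labels
    alternate rest/active in blocks (no behavior-dependent SaO2 shift).
    """
    import pandas as pd

    rng = _rng(seed)
    if not (0 <= error_rate <= 1):
        raise ConfigError(f"error_rate must be in [0,1], got {error_rate}")
    w, base_mean = calibrate_spo2(
        target_mean, target_hypox_fraction, low=low, base_sd=base_sd
    )
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    from_low = rng.random(n) < w
    sao2 = np.where(
        from_low,
        rng.normal(low[0], low[1], n),
        rng.normal(base_mean, base_sd, n),
    ).clip(None, 100.0)

    ok = np.ones((n, 8), dtype=bool)
    bad = rng.random(n) < error_rate
    # corrupt >= 1 non-SaO2 parameter (columns 2..8; SaO2 itself is column 1)
    which = rng.integers(1, 8, size=n)
    ok[bad, which[bad]] = False

    # rest/active behavior blocks of ~60 s
    block = (t // 60).astype(int)
    block_labels = rng.choice(["REST", "ACTIVE"], size=block.max() + 1)
    behavior = block_labels[block]

    df = pd.DataFrame({"t_s": t, "sao2_pct": sao2})
    for j in range(8):
        df[f"ok_{j+1}"] = ok[:, j]
    df["behavior"] = behavior
    return df


# ---------------------------------------------------------------------------
# EEG/EMG epochs

STATES = ("WAKE", "NREM", "REM")

# state-conditional mean log10 band power (delta, EMG) and common SD; the
# geometry follows the staging rule: wake = low delta / high EMG, NREM =
# high delta / low-medium EMG, REM = low delta / low EMG.
_STATE_LOGPOWER = {
    "WAKE": (0.0, 1.2),
    "NREM": (1.2, 0.4),
    "REM": (0.0, -0.6),
}
_STATE_LOGPOWER_SD = 0.18


def _markov_states(
    n_epochs: int,
    occupancy: tuple[float, float, float],
    p_stay: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """First-order chain with stationary distribution equal to ``occupancy``.

    Transition matrix p_stay * I + (1 - p_stay) * 1 pi^T, whose stationary
    distribution is pi for any p_stay in [0, 1).
    """
    pi = np.asarray(occupancy, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ConfigError(f"occupancies must sum to 1, got {occupancy}")
    states = np.empty(n_epochs, dtype=int)
    states[0] = rng.choice(3, p=pi)
    for i in range(1, n_epochs):
        if rng.random() < p_stay:
            states[i] = states[i - 1]
        else:
            states[i] = rng.choice(3, p=pi)
    return states


def _bandlimited_noise(
    n: int, fs: float, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-power noise band-limited to [lo, hi] Hz (4th-order Butterworth)."""
    x = rng.standard_normal(n)
    nyq = fs / 2.0
    hi = min(hi, 0.99 * nyq)
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    y = sps.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def gen_eeg_emg(
    duration_s: float,
    occupancy: tuple[float, float, float] = (0.45, 0.45, 0.10),
    state_sequence: Sequence[str] | None = None,
    seizure_epochs: Sequence[int] = (),
    sample_rate: float = 200.0,
    epoch_len_s: float = 10.0,
    p_stay: float = 0.9,
    seed: int | np.random.Generator | None = None,
):
    """EEG + EMG traces with per-epoch ground-truth vigilance states.

    Each 10 s epoch draws its delta-band (0.5-4 Hz) EEG power and its EMG
    (10-50 Hz) power from the state-conditional log-normal distributions;
    the traces are band-limited noise scaled per epoch. Seizure epochs
    superimpose high-amplitude transients and are flagged in the ground
    truth. Returns (eeg, emg, truth DataFrame).
    """
    import pandas as pd

    rng = _rng(seed)
    n_per = int(round(epoch_len_s * sample_rate))
    n_epochs = int(round(duration_s / epoch_len_s))
    if abs(n_epochs * epoch_len_s - duration_s) > 1e-9:
        raise ConfigError(
            f"duration {duration_s}s is not a multiple of the epoch length {epoch_len_s}s"
        )
    if state_sequence is not None:
        if len(state_sequence) != n_epochs:
            raise ConfigError("state_sequence length must equal the epoch count")
        states = np.array([STATES.index(s) for s in state_sequence])
    else:
        states = _markov_states(n_epochs, occupancy, p_stay, rng)

    seizure_set = set(int(i) for i in seizure_epochs)
    eeg = np.empty(n_epochs * n_per)
    emg = np.empty(n_epochs * n_per)
    rows = []
    for i in range(n_epochs):
        name = STATES[states[i]]
        mu_d, mu_e = _STATE_LOGPOWER[name]
        delta_p = 10 ** rng.normal(mu_d, _STATE_LOGPOWER_SD)
        emg_p = 10 ** rng.normal(mu_e, _STATE_LOGPOWER_SD)
        lo = i * n_per
        seg_eeg = _bandlimited_noise(n_per, sample_rate, 0.5, 4.0, rng) * np.sqrt(delta_p)
        # broadband floor outside the delta band keeps the trace EEG-like
        seg_eeg = seg_eeg + 0.05 * _bandlimited_noise(n_per, sample_rate, 6.0, 40.0, rng)
        seg_emg = _bandlimited_noise(n_per, sample_rate, 10.0, 50.0, rng) * np.sqrt(emg_p)
        if i in seizure_set:
            spikes = np.zeros(n_per)
            idx = rng.integers(0, n_per, size=max(4, n_per // 50))
            spikes[idx] = rng.choice([-1.0, 1.0], size=idx.size) * 30.0
            seg_eeg = seg_eeg + spikes
            seg_emg = seg_emg + np.abs(spikes) * 0.5
        eeg[lo : lo + n_per] = seg_eeg
        emg[lo : lo + n_per] = seg_emg
        rows.append(
            {
                "epoch_index": i,
                "state": name,
                "is_seizure": i in seizure_set,
                "delta_power": delta_p,
                "emg_power": emg_p,
            }
        )
    return eeg, emg, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Seizure event tables


def gen_seizures(
    n_events: int,
    session_duration_s: float,
    seed: int | np.random.Generator | None = None,
):
    """Random seizure annotations for one session.

    Severities are drawn over Racine grades 1-6 (weighted toward the lower
    grades); durations are log-normal with a ~30-60 s bulk, matching the
    magnitudes the severity x duration burden formula is used at.
    """
    import pandas as pd

    rng = _rng(seed)
    onsets = np.sort(rng.uniform(0, session_duration_s * 0.98, n_events))
    severities = rng.choice(
        np.arange(1, 7), size=n_events, p=[0.25, 0.2, 0.18, 0.15, 0.12, 0.10]
    )
    durations = np.exp(rng.normal(np.log(40.0), 0.4, n_events)).clip(5, 300)
    durations = np.minimum(durations, session_duration_s - onsets)
    return pd.DataFrame(
        {"onset_s": onsets, "duration_s": durations, "severity": severities}
    )


def cohort_subject_ids(config: StudyConfig) -> dict[str, list[str]]:
    """Deterministic subject identifiers per cohort from the survival config."""
    out: dict[str, list[str]] = {}
    for cohort, cs in config.survival.items():
        out[cohort] = [f"{cohort}-{i:02d}" for i in range(1, cs.n + 1)]
        wt = cohort.replace("KO", "WT")
        out[wt] = [f"{wt}-{i:02d}" for i in range(1, cs.n + 1)]
    return out
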