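"""Simulate -> analyze -> report orchestration.

``run_simulate`` writes a complete synthetic study to disk (manifest,
session index, seizure annotations, ECG segment tables, airflow and EEG/EMG
waveforms as .npy payloads with JSON sidecars, oximetry CSV streams).
``run_analyze`` re-reads that layout and produces prospective (by age) and
retrospective (by days-prior-to-death bin) endpoint tables plus the
survival and cohort statistics. ``run_report`` renders per-endpoint summary
tables from the analysis outputs without recomputing any statistic.

Determinism: one global seed is expanded into independent per-module
substreams with ``numpy.random.SeedSequence(seed, spawn_key=...)`` so the
draws of one modality never depend on whether another modality is enabled.
Identical (config, seed) produce byte-identical endpoint tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ecg as ecgmod
from . import oximetry as oxmod
from . import respiration as respmod
from . import seizures as seizmod
from . import sleep as sleepmod
from . import survival as survmod
from . import statsbattery as statsmod
from .study import (
    Diet, Genotype, Modality, Session, Sex, Subject,
    bin_ptd, compute_ptd, read_manifest, read_sessions,
    write_manifest, write_sessions,
)
from .synth import (
    StudyConfig, gen_airflow, gen_ecg_segments, gen_eeg_emg, gen_seizures,
    gen_spo2_stream, gen_survival, place_apneas,
)

log = logging.getLogger("sudephys")

# spawn keys for per-module substreams; appending a module never perturbs
# the draws of the existing ones
_STREAM = {"survival": 0, "seizure": 1, "sleep": 2, "ecg": 3, "airway": 4, "spo2": 5}


@dataclass(frozen=True)
class SimSizes:
    """Per-modality problem sizes for a simulated study.

    The defaults are scaled-down but structurally faithful: each modality
    covers a subset of subjects per cohort (as in the source cohorts),
    sessions recur every 10 days until death, and durations are chosen so a
    full simulate -> analyze round trip stays interactive on one CPU.
    """

    n_eeg_per_cohort: int = 6
    n_ecg_per_cohort: int = 6
    n_airway_per_cohort: int = 8
    n_spo2_per_cohort: int = 6
    eeg_fs: float = 100.0
    sleep_window_s: float = 3600.0
    airflow_duration_s: float = 180.0
    airflow_fs: float = 100.0
    spo2_duration_s: float = 720.0
    first_day: dict | None = None

    def start_day(self, modality: Modality) -> int:
        defaults = {
            Modality.EEG_EMG: 37, Modality.ECG: 30,
            Modality.AIRWAY: 30, Modality.OXIMETRY: 40,
        }
        if self.first_day and modality.value in self.first_day:
            return self.first_day[modality.value]
        return defaults[modality]


def _module_rng(seed: int, module: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAM[module],))
    )


def _session_days(start: int, death_day: int) -> list[int]:
    """Recording days every 10 days from ``start`` to the day before death."""
    return [d for d in range(start, death_day, 10)]


def simulate_subjects(config: StudyConfig, seed: int) -> list[Subject]:
    """Survival draws for the KO cohorts plus paired WT littermates.

    Each WT littermate shares its paired KO's death day (euthanized the same
    day) and carries the pairing in the manifest.
    """
    rng = _module_rng(seed, "survival")
    subjects: list[Subject] = []
    for cohort, cs in config.survival.items():
        geno, diet = cohort.split("-")
        times = gen_survival(cs.n, cs.mean, cs.sem, seed=rng)
        sexes = [Sex.M, Sex.F] * (cs.n // 2 + 1)
        for i, t in enumerate(times):
            ko_id = f"{cohort}-{i+1:02d}"
            wt_id = f"WT-{diet}-{i+1:02d}"
            subjects.append(
                Subject(ko_id, Genotype.KO, Diet(diet), sexes[i],
                        death_day=int(t), paired_littermate=wt_id)
            )
            subjects.append(
                Subject(wt_id, Genotype.WT, Diet(diet), sexes[i],
                        death_day=int(t), paired_littermate=ko_id)
            )
    return subjects


def run_simulate(
    config: StudyConfig,
    seed: int,
    outdir: str | Path,
    sizes: SimSizes | None = None,
) -> Path:
    """Write a synthetic study to ``outdir``; returns the study path."""
    sizes = sizes or SimSizes()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = simulate_subjects(config, seed)
    write_manifest(subjects, out / "manifest.csv")
    by_cohort: dict[str, list[Subject]] = {}
    for s in subjects:
        by_cohort.setdefault(s.cohort, []).append(s)
    log.info("simulated %d subjects in %d cohorts", len(subjects), len(by_cohort))

    sessions: list[Session] = []
    seiz_rows, seg_rows, truth_rows = [], [], []
    rng_seiz = _module_rng(seed, "seizure")
    rng_sleep = _module_rng(seed, "sleep")
    rng_ecg = _module_rng(seed, "ecg")
    rng_air = _module_rng(seed, "airway")
    rng_ox = _module_rng(seed, "spo2")
    (out / "waveforms").mkdir(exist_ok=True)
    (out / "oximetry").mkdir(exist_ok=True)

    for cohort, members in sorted(by_cohort.items()):
        for s in members[: sizes.n_eeg_per_cohort]:
            days = _session_days(sizes.start_day(Modality.EEG_EMG), s.death_day)
            for day in days:
                dur = 48 * 3600.0
                is_ko = s.genotype is Genotype.KO
                lam = {1: 8.0, 2: 4.0}.get(bin_ptd(compute_ptd(day, s.death_day)), 3.0)
                if s.diet is Diet.KD:
                    lam *= 0.4
                n_ev = int(rng_seiz.poisson(lam)) if is_ko else 0
                ev = gen_seizures(n_ev, dur, seed=rng_seiz)
                ev.insert(0, "subject_id", s.subject_id)
                ev.insert(1, "record_day", day)
                seiz_rows.append(ev)
                sessions.append(Session(s.subject_id, Modality.EEG_EMG, day, dur))
            if days:  # final session also carries a sleep-window waveform
                day = days[-1]
                occ = config.sleep_occupancy.get(s.cohort, (0.45, 0.45, 0.10))
                eeg, emg, truth = gen_eeg_emg(
                    sizes.sleep_window_s, occupancy=occ,
                    sample_rate=sizes.eeg_fs,
                    epoch_len_s=config.epoch_len_s, seed=rng_sleep,
                )
                stem = f"{s.subject_id}_d{day}_eegemg"
                np.save(out / "waveforms" / f"{stem}.npy",
                        np.stack([eeg, emg]).astype(np.float32))
                (out / "waveforms" / f"{stem}.json").write_text(json.dumps({
                    "channels": ["EEG", "EMG"], "sample_rate_hz": sizes.eeg_fs,
                    "units": "uV", "subject_id": s.subject_id, "record_day": day,
                }))
                truth.insert(0, "subject_id", s.subject_id)
                truth.insert(1, "record_day", day)
                truth.to_csv(out / "waveforms" / f"{stem}_truth.csv", index=False)

        for s in members[: sizes.n_ecg_per_cohort]:
            for day in _session_days(sizes.start_day(Modality.ECG), s.death_day):
                b = bin_ptd(compute_ptd(day, s.death_day))
                hr, noisy = gen_ecg_segments(s.cohort, b, config, seed=rng_ecg)
                for k in range(len(hr)):
                    seg_rows.append({
                        "subject_id": s.subject_id, "record_day": day,
                        "n_beats": 50, "mean_hr_bpm": hr[k], "noisy": noisy[k],
                    })
                sessions.append(Session(s.subject_id, Modality.ECG, day, 1800.0))

        for s in members[: sizes.n_airway_per_cohort]:
            for day in _session_days(sizes.start_day(Modality.AIRWAY), s.death_day):
                b = bin_ptd(compute_ptd(day, s.death_day))
                rate = config.apnea_rate.get((s.cohort, b), 0.2)
                n_ev = int(rng_air.poisson(rate))
                spec = place_apneas(
                    n_ev, sizes.airflow_duration_s, config.breath_rate,
                    seed=rng_air,
                )
                trace, truth = gen_airflow(
                    sizes.airflow_duration_s, config.breath_rate, spec,
                    sample_rate=sizes.airflow_fs, seed=rng_air,
                )
                stem = f"{s.subject_id}_d{day}_airflow"
                np.save(out / "waveforms" / f"{stem}.npy", trace.astype(np.float32))
                (out / "waveforms" / f"{stem}.json").write_text(json.dumps({
                    "channels": ["AIRFLOW"], "sample_rate_hz": sizes.airflow_fs,
                    "units": "a.u.", "breath_rate_bpm": config.breath_rate,
                    "subject_id": s.subject_id, "record_day": day,
                }))
                for ev in truth:
                    truth_rows.append({"subject_id": s.subject_id,
                                       "record_day": day, **ev})
                sessions.append(Session(
                    s.subject_id, Modality.AIRWAY, day, sizes.airflow_duration_s,
                    payload_path=f"waveforms/{stem}.npy",
                ))

        for s in members[: sizes.n_spo2_per_cohort]:
            for day in _session_days(sizes.start_day(Modality.OXIMETRY), s.death_day):
                b = bin_ptd(compute_ptd(day, s.death_day))
                mean, frac = config.spo2_targets.get(
                    (s.cohort, b), (96.48, 0.0) if s.genotype is Genotype.WT
                    else (96.0, 0.0)
                )
                df = gen_spo2_stream(
                    sizes.spo2_duration_s, rate_hz=config.spo2_rate_hz,
                    target_mean=mean, target_hypox_fraction=frac,
                    error_rate=config.spo2_error_rate,
                    low=(config.spo2_low_mean, config.spo2_low_sd),
                    base_sd=config.spo2_base_sd, seed=rng_ox,
                )
                path = f"oximetry/{s.subject_id}_d{day}.csv"
                df.to_csv(out / path, index=False)
                sessions.append(Session(
                    s.subject_id, Modality.OXIMETRY, day,
                    sizes.spo2_duration_s, payload_path=path,
                ))

    write_sessions(sessions, out / "sessions.csv")
    seiz = (pd.concat(seiz_rows, ignore_index=True) if seiz_rows
            else pd.DataFrame(columns=["subject_id", "record_day", "onset_s",
                                       "duration_s", "severity"]))
    seiz.to_csv(out / "seizures.csv", index=False)
    pd.DataFrame(seg_rows).to_csv(out / "ecg_segments.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "airway_truth.csv", index=False)
    counts = {
        "subjects": len(subjects),
        "sessions": len(sessions),
        "seizures": int(len(seiz)),
        "ecg_segments": len(seg_rows),
    }
    (out / "run_manifest.json").write_text(json.dumps({
        "seed": seed, "sizes": asdict(sizes), "counts": counts,
    }, indent=1, default=str))
    log.info("study written to %s: %s", out, counts)
    return out


# ---------------------------------------------------------------------------
# Analysis


def _retro(df: pd.DataFrame, death: dict[str, int]) -> pd.DataFrame:
    """Attach ptd and bin columns from record_day and the death-day map."""
    out = df.copy()
    out["ptd"] = [
        compute_ptd(int(d), death[s]) for s, d in zip(out["subject_id"], out["record_day"])
    ]
    out["bin"] = [bin_ptd(p) for p in out["ptd"]]
    return out


def run_analyze(study_dir: str | Path, outdir: str | Path | None = None) -> Path:
    """Analyze a simulated (or equivalently laid-out) study directory."""
    study = Path(study_dir)
    out = Path(outdir) if outdir else study / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    subjects = {s.subject_id: s for s in read_manifest(study / "manifest.csv")}
    death = {sid: s.death_day for sid, s in subjects.items()}
    cohort = {sid: s.cohort for sid, s in subjects.items()}
    sessions = read_sessions(study / "sessions.csv")
    partial: list[str] = []

    # --- survival (KO cohorts only; WT littermates are euthanized) ---
    ko = [s for s in subjects.values() if s.genotype is Genotype.KO]
    groups = {}
    for s in ko:
        groups.setdefault(s.cohort, []).append(
            survmod.SurvivalRecord(s.subject_id, float(s.death_day))
        )
    surv_out: dict = {"cohorts": {}}
    for name, recs in sorted(groups.items()):
        km = survmod.km_curve(recs)
        surv_out["cohorts"][name] = {
            "n": len(recs), "mean_days": km.mean, "median_days": km.median,
        }
    if len(groups) == 2:
        (a, ra), (b, rb) = sorted(groups.items())
        chi2, p = survmod.logrank(ra, rb)
        hr, ci = survmod.hazard_ratio_mh(ra, rb)
        surv_out["logrank"] = {"comparison": f"{a} vs {b}", "chi2": chi2, "p": p}
        surv_out["hazard_ratio"] = {"hr": hr, "ci95": list(ci)}
    (out / "survival.json").write_text(json.dumps(surv_out, indent=1))

    # --- seizures: per-session count and burden, prospective + retrospective ---
    seiz_path = study / "seizures.csv"
    if seiz_path.exists():
        seiz = pd.read_csv(seiz_path)
        eeg_sessions = pd.DataFrame([
            {"subject_id": s.subject_id, "record_day": s.record_day}
            for s in sessions if s.modality is Modality.EEG_EMG
        ])
        rows = []
        for r in eeg_sessions.itertuples(index=False):
            ev = seiz[(seiz.subject_id == r.subject_id)
                      & (seiz.record_day == r.record_day)]
            events = [
                seizmod.SeizureEvent(r.subject_id, int(r.record_day),
                                     float(e.onset_s), float(e.duration_s),
                                     int(e.severity))
                for e in ev.itertuples(index=False)
            ]
            rows.append({
                "subject_id": r.subject_id, "record_day": r.record_day,
                "cohort": cohort[r.subject_id],
                "count": seizmod.seizure_count(events),
                "burden": seizmod.seizure_burden(events),
            })
        sz = pd.DataFrame(rows)
        if not sz.empty:
            sz = _retro(sz, death)
            sz.sort_values(["subject_id", "record_day"]).to_csv(
                out / "seizure_endpoints.csv", index=False)
    else:
        partial.append("seizures")

    # --- sleep staging on final-session waveforms ---
    wf = study / "waveforms"
    occ_rows = []
    for sidecar in sorted(wf.glob("*_eegemg.json")) if wf.exists() else []:
        meta = json.loads(sidecar.read_text())
        arr = np.load(sidecar.with_suffix(".npy"))
        feats = sleepmod.epoch_features(arr[0], arr[1], fs=meta["sample_rate_hz"])
        labels = sleepmod.classify_states(feats)
        frame = sleepmod.apply_exclusions(labels)
        occ = sleepmod.occupancy(frame)
        sid, day = meta["subject_id"], int(meta["record_day"])
        occ_rows.append({
            "subject_id": sid, "record_day": day, "cohort": cohort[sid],
            "ptd": compute_ptd(day, death[sid]),
            "bin": bin_ptd(compute_ptd(day, death[sid])), **occ,
        })
    if occ_rows:
        pd.DataFrame(occ_rows).sort_values("subject_id").to_csv(
            out / "sleep_occupancy.csv", index=False)
    elif not wf.exists():
        partial.append("eeg")

    # --- ECG: WT reference, bradycardic fractions per subject-bin ---
    seg_path = study / "ecg_segments.csv"
    if seg_path.exists():
        segs = pd.read_csv(seg_path)
        segs["cohort"] = segs["subject_id"].map(cohort)
        clean = segs[~segs["noisy"]]
        wt_means = clean.loc[
            clean["cohort"].str.startswith("WT"), "mean_hr_bpm"
        ].to_numpy()
        ref = ecgmod.wt_reference(wt_means)
        ecgmod.write_reference(ref, out / "wt_reference.json")
        cr = _retro(clean, death)
        frac = (
            cr.groupby(["subject_id", "cohort", "bin"])["mean_hr_bpm"]
            .apply(lambda x: ecgmod.fraction_from_rates(x.to_numpy(), ref))
            .rename("bradycardic_fraction").reset_index()
        )
        frac.sort_values(["cohort", "subject_id", "bin"]).to_csv(
            out / "bradycardic_fraction.csv", index=False)
        n_noisy = int(segs["noisy"].sum())
        log.info("ECG: %d segments, %d noisy excluded, threshold %.1f bpm",
                 len(segs), n_noisy, ref.threshold)
    else:
        partial.append("ecg")

    # --- airway: apnea detection on traces ---
    ap_rows = []
    for s in sessions:
        if s.modality is not Modality.AIRWAY or not s.payload_path:
            continue
        meta = json.loads((study / s.payload_path).with_suffix(".json").read_text())
        trace = np.load(study / s.payload_path).astype(float)
        events = respmod.detect_apneas(
            trace, sample_rate=meta["sample_rate_hz"],
            breath_rate=meta["breath_rate_bpm"],
        )
        ap_rows.append({
            "subject_id": s.subject_id, "record_day": s.record_day,
            "cohort": cohort[s.subject_id],
            "apnea_count": respmod.apnea_count(events),
        })
    if ap_rows:
        ap = _retro(pd.DataFrame(ap_rows), death)
        ap.sort_values(["subject_id", "record_day"]).to_csv(
            out / "apnea_endpoints.csv", index=False)
        sus = (
            ap.groupby(["cohort", "bin", "subject_id"])["apnea_count"]
            .apply(lambda c: respmod.susceptibility(list(c)))
            .rename("susceptible").reset_index()
        )
        sus.to_csv(out / "apnea_susceptibility.csv", index=False)
    else:
        partial.append("airway")

    # --- oximetry: per subject-bin pooled fractions and means ---
    ox_rows = []
    ox_sessions: dict[tuple[str, int], list[pd.DataFrame]] = {}
    for s in sessions:
        if s.modality is not Modality.OXIMETRY or not s.payload_path:
            continue
        b = bin_ptd(compute_ptd(s.record_day, death[s.subject_id]))
        ox_sessions.setdefault((s.subject_id, b), []).append(
            pd.read_csv(study / s.payload_path)
        )
    for (sid, b), streams in sorted(ox_sessions.items()):
        try:
            frac = oxmod.hypoxemia_fraction(streams)
            mean = oxmod.pooled_mean_sao2(streams)
        except oxmod.EmptyResultError:
            continue
        ox_rows.append({
            "subject_id": sid, "cohort": cohort[sid], "bin": b,
            "hypoxemia_fraction": frac, "mean_sao2": mean,
        })
    if ox_rows:
        pd.DataFrame(ox_rows).sort_values(["cohort", "subject_id", "bin"]).to_csv(
            out / "oximetry_endpoints.csv", index=False)
    elif not (study / "oximetry").exists():
        partial.append("oximetry")

    # --- cohort statistics on the binned endpoints ---
    stats_out: dict = {}
    try:
        stats_out.update(_endpoint_stats(out))
    except Exception as exc:  # noqa: BLE001 — partial studies are allowed
        log.warning("endpoint statistics incomplete: %s", exc)
    (out / "stats.json").write_text(json.dumps(stats_out, indent=1))
    (out / "analysis_manifest.json").write_text(json.dumps({
        "partial_modalities": partial,
        "tables": sorted(p.name for p in out.glob("*.csv")),
    }, indent=1))
    if partial:
        log.warning("partial analysis; missing modalities: %s", partial)
    return out


def _endpoint_stats(analysis_dir: Path) -> dict:
    """The statistical battery over whichever endpoint tables exist."""
    res: dict = {}
    bf = analysis_dir / "bradycardic_fraction.csv"
    if bf.exists():
        df = pd.read_csv(bf)
        d1 = df[df["bin"] == 1].copy()
        if d1["cohort"].nunique() >= 4:
            d1["genotype"] = d1["cohort"].str.split("-").str[0]
            d1["diet"] = d1["cohort"].str.split("-").str[1]
            eff = statsmod.two_way_anova(
                d1.rename(columns={"bradycardic_fraction": "value"}),
                factor_a="genotype", factor_b="diet",
            )
            res["bradycardia_bin1_anova"] = {
                k: {"F": v.F, "df": v.df, "p": v.p, "eta_sq": v.eta_sq}
                for k, v in eff.items()
            }
    ox = analysis_dir / "oximetry_endpoints.csv"
    if ox.exists():
        df = pd.read_csv(ox)
        groups = {
            f"{c}-bin{b}": g["hypoxemia_fraction"].to_numpy()
            for (c, b), g in df.groupby(["cohort", "bin"]) if len(g) >= 2
        }
        if len(groups) >= 2:
            h, p, comps = statsmod.kruskal_dunn(groups)
            res["hypoxemia_kruskal"] = {
                "H": h, "p": p,
                "dunn": [
                    {"i": c.group_i, "j": c.group_j, "z": c.z, "p_adj": c.p_adj}
                    for c in comps
                ],
            }
    ap = analysis_dir / "apnea_susceptibility.csv"
    if ap.exists():
        df = pd.read_csv(ap)
        d1 = df[df["bin"] == 1]
        tab = pd.crosstab(d1["susceptible"], d1["cohort"])
        if tab.shape[0] == 2 and tab.shape[1] >= 2:
            chi2, dfree, p = statsmod.chi_square(tab.to_numpy())
            res["apnea_susceptibility_chi2"] = {"chi2": chi2, "df": dfree, "p": p}
    return res


def run_report(analysis_dir: str | Path, outdir: str | Path | None = None) -> Path:
    """Render per-endpoint cohort summary tables (no statistics recomputed)."""
    src = Path(analysis_dir)
    out = Path(outdir) if outdir else src / "report"
    if not src.exists() or not any(src.glob("*.csv")) and not any(src.glob("*.json")):
        raise FileNotFoundError(f"no analysis results under {src}")
    out.mkdir(parents=True, exist_ok=True)
    summaries = {
        "seizure_endpoints.csv": ("burden", ["cohort", "bin"]),
        "sleep_occupancy.csv": ("nrem", ["cohort"]),
        "bradycardic_fraction.csv": ("bradycardic_fraction", ["cohort", "bin"]),
        "apnea_endpoints.csv": ("apnea_count", ["cohort", "bin"]),
        "oximetry_endpoints.csv": ("hypoxemia_fraction", ["cohort", "bin"]),
    }
    for fname, (col, keys) in summaries.items():
        path = src / fname
        if not path.exists():
            continue
        df = pd.read_csv(path)
        summary = (
            df.groupby(keys)[col]
            .agg(n="count", mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)))
            .reset_index()
            .sort_values(keys)
        )
        summary.to_csv(out / f"summary_{fname}", index=False)
    for jname in ("survival.json", "stats.json"):
        if (src / jname).exists():
            (out / jname).write_text((src / jname).read_text())
    return out
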