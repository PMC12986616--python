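#!/usr/bin/env python
"""Run every endpoint analysis over the simulated study.

Reads results/study/, applies the full pipeline — Kaplan-Meier survival with
log-rank and hazard ratio; seizure counts and burden; sleep staging and
occupancy; WT heart-rate reference, bradycardia classification and
per-subject fractions; apnea detection and susceptibility; oximetry QC and
hypoxemia fractions — and writes the endpoint tables and statistics JSON
under results/study/analysis/.
"""

import argparse
import json
import logging
from pathlib import Path

import pandas as pd

from sudephys.pipeline import run_analyze

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/study"))
args = parser.parse_args()

out = run_analyze(args.study)
surv = json.loads((out / "survival.json").read_text())
print("survival:")
for name, c in surv["cohorts"].items():
    print(f"  {name}: n={c['n']}, mean age of death {c['mean_days']:.1f} d, "
          f"median {c['median_days']:.0f} d")
lr = surv["logrank"]
hr = surv["hazard_ratio"]
print(f"  log-rank {lr['comparison']}: chi2={lr['chi2']:.2f}, p={lr['p']:.2e}")
print(f"  hazard ratio {hr['hr']:.2f} (95% CI {hr['ci95'][0]:.2f}-{hr['ci95'][1]:.2f})")

ref = json.loads((out / "wt_reference.json").read_text())
print(f"WT heart-rate reference: {ref['mean']:.0f} +/- {ref['sd']:.0f} bpm "
      f"-> bradycardia threshold {ref['threshold']:.0f} bpm")

frac = pd.read_csv(out / "bradycardic_fraction.csv")
bin1 = frac[frac["bin"] == 1].groupby("cohort")["bradycardic_fraction"].mean()
print("mean bradycardic fraction, 1-10 days prior to death:")
for cohort, v in bin1.items():
    print(f"  {cohort}: {100 * v:.1f}%")

ap = pd.read_csv(out / "apnea_endpoints.csv")
bin1 = ap[ap["bin"] == 1].groupby("cohort")["apnea_count"].mean()
print("mean apneic episodes per 3-min session, 1-10 days prior to death:")
for cohort, v in bin1.items():
    print(f"  {cohort}: {v:.1f}")

ox = pd.read_csv(out / "oximetry_endpoints.csv")
bin1 = ox[ox["bin"] == 1].groupby("cohort")[["mean_sao2", "hypoxemia_fraction"]].mean()
print("oximetry, 1-10 days prior to death (pooled error-free measurements):")
for cohort, row in bin1.iterrows():
    print(f"  {cohort}: mean SaO2 {row['mean_sao2']:.2f}%, "
          f"hypoxemia fraction {100 * row['hypoxemia_fraction']:.1f}%")
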