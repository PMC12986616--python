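#!/usr/bin/env python
"""Render cohort summary tables from the analysis outputs.

Reads results/study/analysis/ and writes one mean +/- SEM summary table per
endpoint under results/study/analysis/report/. No statistics are computed
here; the tables aggregate what 02_analyze.py already produced.
"""

import argparse
from pathlib import Path

from sudephys.pipeline import run_report

parser = argparse.ArgumentParser()
parser.add_argument("--analysis", type=Path, default=Path("results/study/analysis"))
args = parser.parse_args()

rep = run_report(args.analysis)
print(f"report written to {rep}")
for p in sorted(rep.glob("summary_*.csv")):
    print(f"  {p.name}")
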