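#!/usr/bin/env python
"""Sign classification of the simulated cohort's fitted correlations.

Applies the P/N/NS rule and the longitudinal sign-kept bookkeeping to
the per-pair fits from 04_fit_correlations.py, mirroring the summary
derived from the reference tables by 01.  Outputs land in
results/summary/.
"""

import json
from pathlib import Path

import pandas as pd

from plaqueprog import summarize
from plaqueprog.progression import sign_grid

OUT = Path("results/summary")
OUT.mkdir(parents=True, exist_ok=True)

payload = {}
for predictor in ("pws", "fss"):
    records = pd.read_csv(f"results/fits/per_pair_{predictor}.csv")
    summary = summarize(records, predictor.upper())
    grid = sign_grid(records).reset_index()
    grid.to_csv(OUT / f"sign_grid_{predictor}.csv", index=False)
    payload[predictor.upper()] = {
        "period_counts": {k: list(v) for k, v in summary.period_counts.items()},
        "total_counts": list(summary.total_counts),
        "n_kept": summary.n_kept,
        "n_changed_or_ns": summary.n_changed_or_ns,
        "pct_kept": summary.pct_kept,
    }
    p, n, ns = summary.total_counts
    print(f"{predictor.upper()}: P={p} N={n} NS={ns} over "
          f"{sum(summary.total_counts)} pairs; "
          f"{summary.n_kept}/{summary.n_patients} patients kept the sign")
(OUT / "sign_summary.json").write_text(json.dumps(payload, indent=2))
print(f"wrote {OUT}/")
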