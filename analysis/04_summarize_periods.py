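#!/usr/bin/env python
"""Average the heterogeneity fraction over cohorts within historical periods.

Bins the per-cohort results from 03_decompose_variance.py into the standard
historical periods (1751-1815, 1816-1871, 1872-1899) and reports the mean
fraction of longevity variance attributable to heterogeneous frailty per
(period, starting age).  With the synthetic design the 1860s cohorts fall
in the second period and the 1880s cohorts in the third; the first period
is empty and is reported as such.

Writes results/period_summary.tsv.
"""

from pathlib import Path

import pandas as pd

root = Path(__file__).resolve().parent.parent / "results"
path = root / "decomposition.tsv"
if not path.exists():
    raise SystemExit("run analysis/03_decompose_variance.py first")
frame = pd.read_csv(path, sep="\t")

BINS = [("1751-1815", 1751, 1815), ("1816-1871", 1816, 1871),
        ("1872-1899", 1872, 1899)]

rows = []
years = pd.to_numeric(frame["cohort"], errors="coerce")
for label, lo, hi in BINS:
    sub = frame[(years >= lo) & (years <= hi) & ~frame["failed"]]
    for age in sorted(frame["start_age"].unique()):
        grp = sub[sub["start_age"] == age]
        rows.append(dict(
            period=label, start_age=age, n_cohorts=len(grp),
            mean_fraction_heterogeneity=grp["fraction_heterogeneity"].mean(),
        ))

summary = pd.DataFrame(rows)
summary.to_csv(root / "period_summary.tsv", sep="\t", index=False)
print(summary.to_string(index=False))

filled = summary.dropna()
mono_40_60 = bool(
    filled[filled.start_age <= 60]
    .groupby("period")["mean_fraction_heterogeneity"]
    .apply(lambda s: s.is_monotonic_increasing)
    .all()
)
print(f"\nfraction increases with starting age over 40-60 in every "
      f"non-empty period: {mono_40_60}")
print("at starting age 70 only 40 high-mortality ages enter each fit, so "
      "gamma-hat (and with it the fraction) is much noisier there; the "
      "increase with age is clean when computed from the true generating "
      "parameters (see scripts/acceptance.py).")
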