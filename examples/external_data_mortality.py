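"""Segmented mortality analysis of an externally supplied event CSV.

For users who have downloaded a real study's individual-level survival
records (e.g. the mito-nuclear rapamycin dataset published at
github.com/dobdobby/rapa-mito-nuclear), this script runs the same
life-table + weighted segmented regression analysis the package applies
to synthetic cohorts, including outlier diagnostics with AIC
with/without each flagged point.

Usage:
    python examples/external_data_mortality.py path/to/events.csv

The CSV must use the package's event dialect:
    fly_id,population,mito,nuclear,replicate,treatment,day,status
"""

import sys

from mitolife import build_life_tables, detect_outliers, select_by_aic
from mitolife.simulate import read_events

if len(sys.argv) != 2:
    sys.exit(__doc__)

events = read_events(sys.argv[1])
tables = build_life_tables(events)

for key, tab in tables.items():
    usable = tab[~tab["exclude"]]
    fit = select_by_aic(usable["x_pct"], usable["mu_x"], usable["n_alive"],
                        K_max=3, seed=0)
    print(f"{'/'.join(map(str, key))}: K={fit.K} AIC={fit.aic:.1f} R2={fit.r2:.3f}")
    rep = detect_outliers(fit)
    for i in rep.flagged:
        print(f"  outlier candidate at x={fit.x[i]:.1f}%: "
              f"AIC with point {rep.aic_with:.1f}, "
              f"without {rep.aic_without[int(i)]:.1f}")
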