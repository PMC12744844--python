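"""Correlating structural distortion with off-target activity.

Builds a tidy table of siRMSD values against SOA with a planted linear
relationship at seed positions 2-5 and none at 6-8, then computes grouped
Pearson correlations with Fisher-z confidence intervals — the analysis
that separates distortion-driven from stability-driven off-target
suppression.
"""

import numpy as np
import pandas as pd

from sirmsd.stats import fit_with_band, grouped_correlations

rng = np.random.default_rng(11)
rows = []
for mod in ("DNA", "FLUORO", "MOE", "OME", "FA"):
    for pos in range(2, 9):
        sirmsd = rng.uniform(0.1, 1.8)
        if pos <= 5:  # distortion predicts SOA at positions 2-5 only
            soa = 15 + 45 * sirmsd + rng.normal(0, 8)
        else:
            soa = rng.uniform(10, 90)
        rows.append({"position": pos, "modification": mod,
                     "combination": "N-1/N/N+1",
                     "sirmsd_A": sirmsd, "soa_pct": soa})
table = pd.DataFrame(rows)

report = grouped_correlations(table, groups=("2-8", "2-5", "6-8"))
print(report.to_string(index=False,
                       float_format=lambda v: f"{v:.3f}"))
# Expect r high for positions 2-5, weak for 6-8: only where the guide must
# keep its pre-organized A-form does distortion predict SOA.

sub = table[table["position"] <= 5]
band = fit_with_band(sub["sirmsd_A"], sub["soa_pct"])
print(f"\nfit over positions 2-5: SOA = {band.slope:.1f} * siRMSD "
      f"+ {band.intercept:.1f} (95% mean-response band available per x)")
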