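"""Seed-match off-target analysis of an expression matrix.

Simulates 2,000 transcripts with 3'UTRs, 10% of which carry the guide
seed's reverse complement and a planted -1 log2 down-shift after
treatment, then runs the full analysis: quantile normalization, seed-match
classification, group shift and Wilcoxon rank-sum test.
"""

from sirmsd.offtarget import classify_sm, offtarget_magnitude, quantile_normalize, seed_of
from sirmsd.simulate import simulate_expression

fixture = simulate_expression(n_transcripts=2000, sm_fraction=0.1,
                              effect_l2fc=-1.0, noise_sd=0.25,
                              utr_length=60, seed=5)
normalized = quantile_normalize(fixture.matrix)
sm = classify_sm(fixture.utrs, seed_of(fixture.guide))
summary, cumulative, ma = offtarget_magnitude(normalized, sm, "treated", "mock")

print(f"guide seed (positions 2-8): {seed_of(fixture.guide)}")
print(f"seed-matched transcripts:   {summary.n_sm} of "
      f"{summary.n_sm + summary.n_nonsm}")
print(f"mean log2FC, SM:            {summary.mean_l2fc_sm:+.3f}")
print(f"mean log2FC, non-SM:        {summary.mean_l2fc_nonsm:+.3f}")
print(f"difference (off-target magnitude): {summary.difference:+.3f} log2 units")
print(f"Wilcoxon rank-sum p:        {summary.p_wilcoxon:.3g}")
# The difference recovers the planted -1.0 shift; a strongly negative value
# with small p is the expression-level signature of seed-mediated
# off-target repression.
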