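# Methods

## The siRMSD statistic

For a guide strand carrying one chemical modification at position N
(1-based from the 5′ end) and its unmodified counterpart, both posed on
AGO2 in a single shared coordinate frame, the statistic is

    siRMSD (Å) = sqrt( (1/K) · Σ δ_i² )

over the K nucleobase heavy atoms of the selected window, where δ_i is the
Euclidean distance between equivalent atoms (matched by guide position and
atom name). Three deliberate restrictions define the quantity:

* **Nucleobase atoms only.** Sugar and phosphate atoms never enter the
  sum, even when present in the input. The statistic asks where the
  *bases* — the Watson–Crick faces that pair with an off-target 3′UTR —
  have moved, not how the backbone accommodated the modification.
* **No superposition.** Both structures share the AGO2 frame (the protein
  Cα positions are fixed during geometry optimization), so the raw
  frame-difference is the signal. An optimal rigid (Kabsch) superposition
  of the selected atoms is available as an explicit, off-default option
  (`superpose=True`, via scipy's rotation alignment) for exploratory use;
  it removes exactly the rigid component the default mode is designed to
  keep.
* **Heavy atoms only.** Hydrogens are excluded, identified by element
  (H/D), never by name heuristics.

### Windows and combination modes

Structural perturbations propagate to neighbors, so the statistic is
evaluated over windows drawn from {N−1, N, N+1} — all seven non-empty
combinations in a profile scan. Position 2's full window includes guide
nucleotide 1, and position 8's includes nucleotide 9. For multi-nucleotide
windows three combination modes exist:

* `POOLED` (default): one RMSD over the union of the window's atoms. Units
  stay Å, the value reduces exactly to the single-nucleotide statistic for
  one member, and POOLED² is the atom-count-weighted mean of the
  per-nucleotide squared values.
* `SUM_RMSD`: the sum of per-nucleotide RMSDs (Å). Always ≥ POOLED for two
  or more members.
* `SUM_MSD`: the sum of per-nucleotide mean squared distances (Å²).

Published descriptions of multi-nucleotide variants of such scores are
ambiguous between pooling and summation; lacking the deposited coordinates
that would let the alternatives be discriminated against printed anchor
values, the package defaults to POOLED — the only mode that is literally
the defining equation applied to a larger atom set — and keeps the other
two selectable. Reported values should state the mode.

## Structure input

Fixed-column PDB ATOM/HETATM records or bare element/x/y/z coordinate
blocks accompanied by a TSV annotation table (guide_position, base,
modification, atom_name) — the form quantum-chemistry supplementary
listings take, which carry no residue labels of their own. Parsing is
deliberately strict where silent recovery would corrupt the per-position
indexing: malformed records fail naming the line, insertion codes are
rejected outright, and annotation tables are checked row-by-row for
element agreement with the mapped atom name. Alternate locations keep the
highest-occupancy copy, ties breaking to the smallest alt-loc code. Atom
names are normalized across PDB dialects (`C2*` ≡ `C2'`; thymine's methyl
`C5M` ≡ `C7`). Residue sequence numbers are interpreted directly as
1-based guide positions.

## Steric extent of 2′ modifications

The size of a 2′-ribose substituent is the distance from C2′ to its
farthest atom. Coordinate files carry no connectivity, so bonds are
inferred: atoms i, j are bonded iff d(i,j) < r_cov(i) + r_cov(j) + t with
single-bond covalent radii and a default tolerance t = 0.45 Å — generous
enough for DFT-optimized geometries, tight enough not to hallucinate
bonds across a furanose ring (ring diagonals sit near 2.3 Å against a
C/O cutoff of ~1.9 Å). The substituent is collected by breadth-first
traversal from C2′ with C1′ and C3′ blocked; reaching ring or backbone
atoms any other way is reported as a topology error rather than silently
truncated. The substituent is the non-hydrogen branch when one exists;
for 2′-deoxy residues the geminal hydrogens are the substituent — which
is why hydrogens count: a 2′-H extent (~1.09 Å) and a 2′-OH extent
terminating at the hydroxyl proton (~1.94 Å) both match measured sizes
only when terminal hydrogens are included.

## Reporter-assay quantities

Per well, Renilla luminescence is divided by the firefly co-transfection
control; a condition's relative activity is its mean ratio over the
unrelated-control mean ratio × 100, with SD propagated from the sample
replicates. Substantial off-target activity rescales the change against
the headroom the unmodified siRNA left:

    SOA (%) = (rel_mod − rel_unmod) / (100 − rel_unmod) × 100

0 when the modification changes nothing, 100 when repression is abolished;
values outside [0, 100] are reported as computed. SOA is undefined when
the unmodified activity is exactly 100%.

IC50 uses bracketing interpolation on the log-concentration scale between
the adjacent tested concentrations straddling 50% inhibition — no
four-parameter logistic is fit, so the estimate is exactly reproducible
from the printed dose table. An exact 50% hit returns that concentration;
a curve that never crosses yields an explicit not-estimable sentinel. With
non-monotone data the lowest-concentration crossing is used (the
conservative potency estimate). Group comparisons use a two-sided Welch t
test (no equal-variance assumption).

## Melting temperature

Tm is the inflection of the A260-vs-temperature curve: absorbance is
smoothed with a centered local quadratic (Savitzky–Golay) filter, first
and second derivatives are taken from the same fit, and Tm is the + → −
sign change of the second derivative nearest the global maximum of the
first derivative, refined by linear interpolation (tolerating a run of
exactly-zero curvature when the midpoint falls on a grid point). No
baseline subtraction or fraction-folded normalization is applied. The
estimate is invariant under positive affine transforms of the absorbance
and equivariant under temperature shifts.

The default smoothing window is 25 points (12 °C at the 0.5 °C/min ramp's
0.5 °C spacing). This width was chosen from simulation: with
instrument-level noise of 0.002 AU on a ~0.13 AU transition, an 11-point
window leaves the second-derivative zero reproducible only to ~0.7 °C,
while 25 points achieve ~0.14 °C — comfortably inside the ±0.3 °C the
package's own recovery tests demand — without biasing the symmetric
two-state transition (a linear baseline has zero curvature, so the
estimator is exactly unbiased on the simulated model). A curve with no
transition (strictly linear absorbance) yields a not-estimable sentinel
via a curvature floor scaled to the observed absorbance range. When both
heating and cooling ramps exist, the heating ramp is used by default;
descending series are re-sorted internally. ΔTm is the plain difference
against an unmodified reference duplex (e.g. 74.5 °C for an unmodified
vimentin-targeting siRNA duplex).

## Seed-match expression analysis

The seed is guide positions 2–8; a transcript is seed-matched (SM) iff the
DNA reverse complement of that 7-mer occurs exactly in its 3′UTR (U/T
normalized, no G:U wobble, no mismatches). Records first pass six
feature-extraction QC flags (ControlType = 0, gIsPosAndSignif = 1,
gIsFeatNonUnifOL = 0, gIsWellAboveBG = 1, gIsSaturated = 0,
gIsFeatPopnOL = 0) and a RefSeq-mRNA identifier pattern. Intensities are
quantile-normalized (columns forced onto the across-column mean
distribution; ties receive the mean of their tied targets, making the
transform idempotent), fold changes are computed on the normalized scale
with mock as denominator, and the off-target magnitude is the difference
in mean log2 fold change between SM and non-SM transcripts with a
two-sided Wilcoxon rank-sum p value (exact enumeration for small tie-free
groups, normal approximation with continuity correction otherwise).
Cumulative-fraction curves per group and an MA table (M = log2 fold
change, A = mean log10 intensity) accompany the summary. Note that
quantile normalization redistributes any global shift across both groups;
the SM-vs-non-SM *difference* is the invariant readout.

## Correlation machinery

Pearson r with the exact t-based two-sided p (t = r·√((n−2)/(1−r²))) and
a Fisher-z 95% CI (tanh(atanh r ± z₀.₉₇₅/√(n−3))). Zero-variance input
yields an undefined-correlation sentinel, as do groups smaller than three
points in grouped reports — sentinels, never silent omissions. Grouped
correlations evaluate each window combination over positions 2–8, 2–5 and
6–8 (and per position on request), one point per modification × position.
Regression lines carry a mean-response confidence band from the t
distribution with n−2 df (statsmodels OLS under the hood) — the band of
the conditional mean, not a prediction interval. One-way ANOVA and
Welch's t are provided as from-definition auxiliaries; no multiple-testing
correction is applied.

## Synthetic fixtures

The generator exists to make every analysis testable against planted
truth; all generators are pure functions of (parameters, seed).

* **Structures**: an idealized helix — planar regular-polygon nucleobases,
  a planar ribose pentagon, standard bond lengths and angles, A-form-like
  rise 2.8 Å and twist 32.7° per step. This is *not* a physically accurate
  nucleic-acid conformation (no sugar pucker, no base propeller); siRMSD
  depends only on the displacement field between two structures, so
  geometric realism buys nothing for validating it. Each nucleotide's
  declared bond topology is recorded so bond inference can be checked
  exactly. 2′ substituents are built from internal coordinates under a
  fixed conformation rule: torsions anti, except gauche O–C–C–O (the
  well-documented MOE side-chain preference) and gauche acetal C–O–C–O
  (anomeric effect); O3′ is placed on the sugar face opposite the 2′
  substituent so long 2′ chains cannot collide with the 3′ hydroxyl in
  the planar idealization. These geometries double as synthetic stand-ins
  for DFT-optimized modified riboses: single-bond extents (2′-H 1.09 Å,
  C–F 1.39 Å, O–H-terminated 1.94 Å, OMe 3.30 Å) land on measured sizes,
  while longer chains (FA 3.61, MOE 6.06, MTMM 6.60 Å) depend on the true
  torsional state of the optimized structure and carry ±0.1–0.4 Å model
  uncertainty. The published size *ordering* of all seven chemistries is
  reproduced.
* **Perturbations** displace the base atoms of chosen positions
  (isotropic Gaussian, or one rigid shift) and record the expected siRMSD
  per mode computed from the *realized* displacements by explicit loops —
  an oracle independent of the scoring path.
* **Reporter wells** draw multiplicative log-normal noise (default CV
  0.08, triplicates — typical dual-luciferase scatter) around planted
  relative activities.
* **Melting curves**: linear baseline (0.55 AU, 4×10⁻⁴ AU/°C) plus a
  logistic transition (amplitude 0.13 AU ≈ 25% hyperchromicity, width
  2.5 °C), 30–90 °C at 0.5 °C steps, optional Gaussian noise. The
  logistic midpoint is the planted Tm.
* **Expression matrices**: log2-normal baseline (mean 9, sd 1.5),
  independent per-sample Gaussian log2 noise (default 0.25), a planted
  effect on a chosen SM fraction (default 10% of 2,000 transcripts,
  −1.0 log2), and 3′UTRs with the seed complement planted in SM
  transcripts and rejection-sampled out of the others.

What passing on these fixtures does **not** show: robustness to real
microarray probe effects, UTR base composition, multi-probe transcripts,
non-two-state melting, or DFT-level conformational detail. The fixtures
validate the *arithmetic and statistical machinery*, not instrument
physics.

## Numerical choices and degenerate inputs

* Bond-inference tolerance 0.45 Å (configurable); unknown elements are
  errors, not guesses.
* siRMSD of an empty pairing, correlations of constant series, IC50
  without a crossing, Tm without a transition: each returns a typed error
  or an explicit sentinel as documented — never NaN by accident.
* TSV output at 6 significant digits; JSON at full precision.
* CLI writes are atomic (temp file + rename) and accompanied by a run
  manifest (inputs, parameters, version, seed).

## Known limitations

* The package measures structures; it does not produce them. Scoring real
  modified guides requires externally optimized coordinates plus an
  annotation map — the bridge format exists, but curated maps for
  deposited structures must be built by inspection of each deposit.
* The steric-extent stand-ins are conformational idealizations (see
  above); treat multi-atom extents as ±0.1–0.4 Å.
* Eq.-style bracketing IC50 ignores replicate scatter at the bracket
  points; no confidence interval is attached.
* The Wilcoxon normal approximation is used for large groups even with
  heavy ties; exact enumeration is reserved for small tie-free samples.
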