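# Methods

## Scope and model

nanosip quantifies minor-isotope enrichment (¹⁵N, ³⁴S) of organelle-scale
regions from NanoSIMS ion-count image stacks and compares groups of regions
nonparametrically. Stacks are assumed pre-registered (no drift correction)
and counts are treated as pure shot noise: no dead-time, quasi-simultaneous
arrival (QSA) or instrumental mass-fractionation corrections are applied.
Sulfur is treated as a two-isotope ³²S/³⁴S system (³³S/³⁶S ignored, matching
the measured species); ³⁴S atom% values are therefore *relative* labels, not
absolute compositions.

## Isotope arithmetic

Atom fraction f = minor/(minor+major); counting SE √(f(1−f)/n) with
n = minor+major (binomial shot noise). δ-notation offers two conventions:

* `fraction_ratio` (default): δ = (f/f_std − 1)·1000. With
  f_std(AIR ¹⁵N) = 0.0036630 this maps 0.3751 atom% to +24.0 ‰, matching the
  published natural-specimen cross-check; the `isotope_ratio` convention
  gives 24.1 ‰ for the same input.
* `isotope_ratio`: δ = (R/R_std − 1)·1000 with R = f/(1−f),
  R_std(AIR) = 0.0036765, R_std(VCDT ³⁴S/³²S) = 0.0441626.

Both are exact inverses of their `fraction_from_delta` counterparts and
agree to first order for tracer-level fractions (|δ_fr − δ_ir| < 5 ‰ for
f < 0.005). A second published pair (0.3714 atom%, δ¹⁵N 10.1 ‰) is
inconsistent with either convention (~13.9 ‰ both ways); the package flags
only the 0.3751 ↔ 24.0 pair as its anchor and does not attempt to
reconcile the other.

## Quantification chain

1. **Amalgamation.** Planes are summed per species before anything else.
2. **Masking.** Thresholds apply to *accumulated* counts (not per plane):
   nitrogen analysis keeps pixels with CN⁻ pair total ≥ 1000, sulfur
   analysis keeps pixels with ³²S⁻ ≥ 60. "Below … removed" is strict, so
   the boundary value survives. Each analysis thresholds only its own
   species — N and S are separate acquisitions. Both thresholds are
   configurable.
3. **Ratio maps.** Valid pixels carry f; a masked-in pixel with zero pair
   total (possible for S, which masks on ³²S only) is demoted and counted.
4. **ROI estimators.** `pixelwise` (default) averages per-pixel fractions
   over the ROI's valid pixels — the natural reading of "averaged values
   from corresponding pixels"; `pooled` forms the fraction of ROI-summed
   counts, is exactly scale-conserving, count-weighted, and less biased at
   low per-pixel totals, so it is recommended for faint ROIs. Both report
   the counting SE from ROI-summed counts, the per-pixel SD as dispersion,
   and the two estimators converge as per-pixel totals grow (within one
   counting SE at ≥1000 counts/pixel). ROIs with zero valid pixels are
   reported with a no-estimate flag, never dropped.
5. **QC.** Spearman rank correlation between ROI total counts and ROI
   fraction, which should be null when composition is independent of
   emission rate.

Whether published quantifications averaged pixelwise or pooled is not
stated anywhere we know of; both are provided and the default is the
pixelwise reading. Likewise, whether count masks were applied during
quantification or only for display is open; the default applies them to
quantification and both thresholds can be set to 0 to disable.

## The phantom

A single convex cell (ellipse, ~60 % of a 10 × 10 µm field; a deliberate
reduction of multi-chamber anatomy to one chamber with an optional chamber
tag) wrapped in a closed 1-px organic-lining ring, embedded in resin.
Organelles are placed by rejection sampling (≤1000 attempts each, failure
raises a placement error naming the class; placement order is the class
enumeration order): disks for vacuoles (0.8–1.5 µm), food vacuoles
(0.6–1.2 µm), mitochondria (0.4–0.8 µm), peroxisomes (0.2–0.5 µm), plastids
(0.5–1 µm), lipid droplets (0.4–0.9 µm) and electron dense bodies
(0.2–0.5 µm, the published size range); rods 0.1–0.3 µm × 0.6–1.5 µm for
the possible endobionts. Under the anoxic condition, electron dense bodies
and endobionts are confined to a peripheral band (default 1.5 µm) against
the lining, mimicking anoxia-incubated ultrastructure; under dysoxia they
scatter uniformly.

**Ground truth.** Per-class true atom fractions default to the published
per-condition class means (÷100), with per-ROI heterogeneity (on by
default) drawing each ROI's true fraction from a normal with the published
between-ROI SD, truncated to (0, 1). Plastids, too rarely measured to be
tabulated, default to the cytosome values. **Acquisition** is the simplest
model consistent with counting statistics: per pixel and plane, the pair
total is Poisson(λ_class) and the minor count a Binomial(total, f) split;
minor + major equals the simulated total exactly. The standard protocol is
50 planes at 256 × 256; a gentler 25-plane / 128 × 128 variant
(stride-subsampling the label map, doubling the pixel size) mirrors
beam-sensitive S measurements.

**Emission rates** are unconstrained by published values (only the mask
thresholds anchor the count scale). Defaults: λ_CN = 40 counts/px/plane for
cell material (accumulated 2000, comfortably above the 1000 mask) and 19
for nitrogen-poor classes (resin, vacuoles, lipid droplets; accumulated
950, mostly *below* the mask, reproducing the dark background of published
ratio images while the Poisson upper tail keeps every ROI quantifiable).
For sulfur: λ_S = 8 (electron dense bodies), 6 (organic lining), 3 (cell
classes), 2.4 (S-poor classes). S-poor rates are deliberately kept clear of
the 60-count ³²S mask at the 50-plane protocol: the CN mask thresholds the
ratio's own pair total, so surviving pixels are an unbiased sample of the
binomial split, but the S mask thresholds the *major species alone* —
near-threshold pixels pass preferentially when their ³⁴S share is small,
which measurably biases pooled estimates low. At 2.4 counts/px/plane the
S-poor accumulated ³²S ≈ 115 and the bias is negligible; the 25-plane
protocol halves totals and genuinely exercises the S mask.

**What the phantom does not emulate:** TEM-correlated ROI drawing,
registration error between planes, detector artifacts (dead time, QSA),
spatial gradients within organelles, multi-chamber 3-D morphology, and any
matrix effect. Passing recovery tests therefore demonstrates correctness of
the counting-statistics pipeline, not robustness to instrumental
systematics.

## Statistics

All tests are two-sided (the convention of the tables being emulated) and
are invariant under strictly increasing transforms of the data.

* **Mann–Whitney.** U = #{x>y} + ½·ties via midranks; tie-corrected normal
  Z by default with the continuity correction off — this reproduces the
  printed complete-separation statistics (e.g. |Z| = 7.07 at 25 vs 52,
  4.46 at 9 vs 28, 2.45 at 5 vs 4, 4.02 at 9 vs 15), which a continuity
  correction would shift. Z is positive when the first sample tends larger;
  report layers pass the anoxic group first so enrichment under dysoxia
  prints negative, the published sign convention. The exact method
  enumerates all C(N, n) labelings (N ≤ 20, tie-free only). Exhaustive
  enumeration shows exact and normal p order every small-sample dataset
  identically, but the *absolute* gap between them at mid-range p reaches
  ~0.19 at min(n,m)=3 and falls below 0.05 only around min(n,m)=8 — the
  normal approximation is for ordering and tail decisions at small N, not
  mid-range p values. Several published Z values for tied-looking classes
  (e.g. cytosome ¹⁵N −4.98) differ slightly from the tie-free
  complete-separation value, implying ties in the original data; those rows
  are not used as anchors.
* **Kruskal–Wallis.** Standard H with tie correction C = 1 − Σ(t³−t)/(N³−N),
  χ²_{k−1} reference. At k = 2, H equals the squared MW Z exactly.
* **Steel–Dwass.** Each pair ranked on its own; tie-corrected t; adjusted
  p = 1 − P(Q_{k,∞} ≤ √2|t|) with the ν = ∞ studentized range CDF evaluated
  by adaptive quadrature of k·∫φ(z)[Φ(z) − Φ(z−q)]^{k−1} dz (abs. tol.
  1e-8; k = 2 reduces to 2Φ(q/√2) − 1 and to the MW p). Original
  implementations of this test vary in tie handling; here the contract is
  the formula above plus the permutation oracle, not any particular legacy
  code.
* **Permutation oracle.** Joint label permutation; family-wise adjusted
  p_ij = add-one proportion of permutations whose max pairwise |t| reaches
  the observed |t_ij|. Tie-free inputs use a vectorized comparison-count
  path; tied inputs fall back to explicit ranking. The oracle is the
  arbiter where the asymptotic is doubtful. One numerical caveat governs
  comparisons between the two: the rank statistic is discrete, q moves on a
  lattice with spacing √2/√(nm(N+1)/12), so asymptotic and oracle can
  disagree by up to ~(spacing × range-CDF density) regardless of the number
  of permutations — agreement to Monte-Carlo precision is only a well-posed
  expectation when that quantization term is below the Monte-Carlo SE
  (about n ≳ 80 per group for a 100k-permutation check).

## Reduced-scale experiment defaults

The end-to-end demo runs 2 specimens × 6 fields per condition (12 fields,
so 12 ROIs per condition for the one-per-field classes — the scale of the
smallest published per-class counts) at the full 256 × 256 / 50-plane
acquisition, pixelwise estimator, default masks, per-ROI heterogeneity on.
All per-field seeds derive from the single run seed via a seed sequence;
outputs are byte-reproducible given (config, seed).

## Known limitations

* Counting error is binomial/Poisson only; no overdispersion model.
* The pixelwise estimator is ratio-biased at very low per-pixel totals
  (use pooled there); neither estimator corrects for the S-mask selection
  bias when ³²S totals sit near the threshold — avoid quantifying classes
  whose major-species counts straddle their mask.
* The studentized-range reference is ν = ∞; for very small groups trust the
  permutation oracle instead.
* Phantom geometry is 2-D and single-chambered; organelle shapes are
  disks/rods without texture.
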