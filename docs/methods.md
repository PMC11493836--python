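# Methods and design notes

This note records the models behind `gslmrm`, the defaults and why they
were chosen, and what the synthetic data can and cannot establish.

## Compositional mass model

Every species is a ceramide plus a glycan head group. A d-type sphingoid
base with B carbons and k double bonds is C_B H_(2B−2k+3) N O2; a fatty
acyl with n carbons and j double bonds contributes C_n H_(2n−2j) O2 minus
one water for the amide bond. Glycan residues are added in dehydrated
form (each glycosidic bond loses one water): Hex C6H10O5 (162.0528 Da),
HexNAc C8H13NO5 (203.0794 Da), NeuAc C11H17NO8 (291.0954 Da). The
14 class compositions follow the biosynthetic pathway: e.g. GM3 =
ceramide + 2 Hex + 1 NeuAc; GA2 (asialo-GM2) = ceramide + 2 Hex +
1 HexNAc. Monoisotopic atomic masses ship as a documented JSON table;
charge adjustment uses the proton mass 1.00727646 Da, not the H-atom
mass, so `[M−H]−` = M − 1.00727646.

Summed shorthand (`d36:1`) is resolved assuming a fixed d18:1 sphingoid
base, because every commercial standard in the panel carries that base;
this is an assumption, not a measurement — `d36:1` could in principle be
d16:1/20:0 etc. Deuterium labels are placed on the acyl chain, which is
why labelled internal standards share the unlabelled sphingosine
fragment (m/z 264.27) while gaining precursor mass.

Quantifier fragments are computed, not tabulated: the dehydrated sialic
acid anion [NeuAc−H2O−H]− = 290.088 for all sialylated classes and the
doubly dehydrated sphingosine cation [d18:1+H−2H2O]+ = 264.269 for the
neutral classes (they round to the instrument-method values 290.1 and
264.3). Fragment charge is fixed (−1 / +1) regardless of precursor
charge state.

Default precursor charges: [M−H]− for mono-sialo classes, [M−2H]2− for
classes with ≥2 NeuAc, [M+H]+ for neutral classes. These are common
ganglioside MRM practice; the panel config stores a per-species charge
override so an instrument method's actual values can replace them.

## Panel reconstruction

The assay monitors 84 species across 14 classes, but the per-class
roster is instrument-method metadata that is not public. The
default config assigns six ceramides per class — d34:1, d36:1, d38:1,
d40:1, d41:1, d42:1 — giving exactly 84 analytes and covering every
purchased standard (d18:1/16:0 = d34:1, d18:1/18:0 = d36:1, d18:1/24:0
= d42:1). The config is data (`data/default_panel.yaml`, flagged
RECONSTRUCTED); swapping in the true roster changes no code.

The retention-time model is ordinal, not predictive: class base RT (at
d36:1) + 0.05 min per ceramide carbon beyond 36 − 0.05 min per double
bond beyond 1. Base RTs encode the observed elution order on a
phenyl-hexyl column — more sialic acids elute earlier (GQ1 first, then
GT < GD < GM), neutral glycosphingolipids later, with small spacing by
glycan count. Absolute minutes are nominal config values; only the
ordering and the 1.0-min scheduled windows matter to the pipeline.

## Synthetic acquisition model

No raw instrument data are available for redistribution, so every
chromatogram is synthetic, from the simplest model that exercises the
downstream math:

* points at the acquisition cycle time (0.5 s) inside each transition's
  scheduled window only;
* one Gaussian peak per transition (σ = 2.5 s; an exponentially
  modified Gaussian with τ = 2 s is available for tailing), centred on
  the scheduled RT with 0.02-min jitter keyed to the sample/transition
  identity (so noise seeds change noise, never peak locations);
* true area = amount × response factor (default 1000 counts/fmol) ×
  matrix factor × extraction efficiency, times a per-peak log-normal
  fluctuation with CV 3 % — the term that models spray/injection
  variability and drives realistic assay CVs, chosen to land
  intra-assay CVs in the single digits as printed validation tables for
  such assays do (additive trace noise alone integrates away);
* additive Gaussian noise (σ = 10 counts) plus a 1 % signal-
  proportional term on every point, baseline 50 counts, saturation cap.

Internal standards are spiked post-extraction, so the extraction
efficiency applies only to analytes while the matrix factor applies to
both — matching how the corresponding validation experiments are
interpreted.

Study designs mirror the assay's validation plan: a 7-point 1:4 serial
dilution from 5000 fmol (per-injection equivalents; amounts are used
exactly as printed, with no volume re-scaling anywhere), low/high QC at
50 and 1000 fmol, five replicates per day over five days, first-order
storage decay, and per-cycle freeze-thaw losses.

The cohort generator draws control amounts of each class's d36:1
species log-normally. σ² is the sample variance of log amounts in the
packaged serum table; µ is set to log(mean) − σ²/2 so the generative
arithmetic mean equals the observed control mean exactly (pure
log-moment matching would bias the mean, and the generator is required
to reproduce class means within 2 SE at n = 36). Patient samples
multiply the class draw by fold factors taken from the observed
per-species changes — GM2 ×10, GM1 ×6, GM3 ×0.57, GA2 ×2.4 in the
Sandhoff group only (β-hexosaminidase B loss), all other classes ×1 as
placeholders. Other chain lengths scale from the d36:1 draw by fixed
weights (d34:1 0.6, d38:1 0.35, d40:1 0.25, d41:1 0.05, d42:1 0.3) —
a crude stand-in for real chain-length distributions. Classes absent
from the serum table (GlcCer, LacCer, Gb3, GA2, GT2, GT3, GQ1) get
nominal placeholder levels with log-σ 0.4.

What the synthetic data do **not** emulate: isotope interference and
isotopologue envelopes, carryover, retention drift between runs,
co-eluting matrix peaks, detector saturation in practice, and real
chain-length concentration profiles. Tests passing on synthetic data
therefore establish the correctness of the computations (integration,
normalization, calibration algebra, statistics), not instrument-level
performance claims such as amol-range LODs or the fraction of species
detectable in real serum.

## Peak integration

The trace is median-smoothed over 3 points. Baseline = median of the
window (robust because a peak occupies a small fraction of its 1-min
scheduled window). Noise = MAD of the lowest-intensity quartile scaled
by 3.3, a factor calibrated so the estimate matches the SD of
median-smoothed Gaussian noise. Detection requires the smoothed apex to
exceed baseline + 3·noise; boundaries walk outward from the apex to the
nearest points at or below baseline + 1·noise; area is the trapezoid
over [left, right] minus baseline. Degenerate inputs (empty, flat, <3
points) return a not-detected result rather than raising. This is a
deliberately simple, deterministic algorithm testable against
closed-form Gaussian areas (recovery within 0.5 % at the default point
spacing); pure-noise windows occasionally clear the robust threshold,
with areas orders of magnitude below genuine peaks.

## Calibration and LOD

`fit_calibration` is ordinary least squares of response ratio on
amount; S_y is the residual SD with the n−2 denominator, r² from the
same fit, and LOD = 3.3·S_y/S as an exact identity. Two options exist:
a low-level subset fit (so S_y can be estimated from the calibrators
nearest the detection limit rather than the whole curve) and 1/x
weighting.

The pipeline-level builder `calibrate_from_records` applies 1/x
weighting **by default**. With a 4096-fold calibration range and
signal-proportional noise, unweighted OLS leaves intercept errors of
several fmol (measured: ±10 fmol across standards), which destroys
back-calculation accuracy exactly where serum gangliosides sit; 1/x
weighting reduces the intercept-equivalent to ~0.1 fmol and brings the
per-species median round-trip error to 2–4 %. This is standard
bioanalytical practice for wide calibration ranges. The unweighted
primitive remains the documented default of `fit_calibration` itself.

Negative back-calculated amounts are floored at zero and flagged rather
than reported negative.

## Internal-standard assignment

Only four labelled/odd-chain standards are available, so each analyte
class maps to the structurally closest one: GM3-d5 covers the
di-hexosyl gangliosides (GM3, GD3, GT3); GM1 d18:1/17:0 covers the
tetra/tri-hexosyl gangliosides and GA2 (GM1, GM2, GD1, GD2, GT1, GT2,
GQ1, GA2); GlcCer-d3 covers GlcCer and LacCer; Gb3-d3 covers Gb3. The
map is config data and fully overridable.

## Validation metrics

CV% = 100·SD/mean (SD with n−1). Intra-assay uses one day's replicates;
inter-assay defaults to pooling all 25 measurements (5/day × 5 days),
since the wording "five times daily over 5 days" does not specify
nesting — a day-means variant is exposed for the other reading.
Extraction yield = 100 × (amount spiked before / amount spiked after
extraction); matrix factor = 100 × (area in matrix / area in neat
solvent); both are exact ratios. Stability aggregates IS-normalized
response ratios (not back-calculated fmol) by class, and a class is
unstable at a time point iff its recovery departs from 100 % by
strictly more than 15 % (114.9 % is stable, 115.1 % is not).

## Cohort statistics

Group comparison uses the two-tailed Student's (pooled-variance) t-test
per species, as specified for the original analysis, despite the 36 vs 3
imbalance; Welch is available. Under null resampling from the fitted
log-normal model the pooled test's type-I error at α = 0.05 is within
0.05 ± 0.01 (verified over 5000 simulations), so the pooling is not
materially anticonservative here. The adjustment procedure is
Benjamini-Hochberg by default (the original analysis reports "adjusted
p-values" without naming one), with Bonferroni available.

Fold-changes are always reported both mean-based and median-based: the
headline per-species figure (GM2 ×10.0) is mean-based arithmetic on the
cohort table, while total-class summaries elsewhere use medians. Grubbs
screening (two-sided, iterative single removal, α = 0.05, per species
per group) is exposed but **off by default** in `group_compare`: the
headline group means (GM3 397.4, GD3 235.9, GM2 203.1 fmol) and the
GM2 ×10.0 fold-change are plain arithmetic over all 36 controls and
would change if the two high-GM2 controls were removed first.

The GM2/GM3 ratio is computed per sample; its group fold-change on the
packaged table is 16.4 (mean-based) / 21.1 (median-based). A
total-species ratio would aggregate all chain-length species, which the
d36:1-only table cannot supply; the d36:1 arithmetic is what this
package validates.

PCA autoscales each species (mean 0, SD 1, n−1 denominator) and takes
the SVD; each loading vector's largest-magnitude element is made
positive so score signs are reproducible. Scores × loadingsᵀ
reconstructs the autoscaled matrix to machine precision with full
components. Heatmap export is z-scores only; no rendering (plots were
produced by external web tools in the original workflow and are out of
scope).

## Problem sizes

Default analysis and test runs use 21 calibrators (7 levels × 3
replicates, matching the three replicate calibration runs of the
assay), 50 QC injections, 39–50 cohort samples, and 5000 null
simulations for the type-I-error check — sizes chosen so the whole
suite exercises every code path at full panel width (88 transitions per
sample) while remaining quick on a laptop.

## Known limitations

* The 84-species roster, per-species charge states and RTs are
  reconstructions; real instrument method values should replace the
  shipped config for any real deployment.
* The simulator's noise model is stationary and per-peak independent;
  it cannot produce inter-day drift, so simulated inter-assay CVs are
  not systematically larger than intra-assay ones, unlike typical real
  validation tables.
* LOD values from synthetic calibrations reflect the simulator's noise
  floor (single-digit fmol), not the amol-range sensitivity of the real
  instrument.
* Patient fold factors for classes without known per-species changes
  default to 1 and are placeholders.
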