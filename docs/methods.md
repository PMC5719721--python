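# Methods

## The analysis model

The package analyses one coronary vessel per patient, imaged by IVUS-VH at
baseline and at 1-year follow-up.  Each pullback is an ordered frame
sequence; axial positions are measured in mm from the distal fiduciary
landmark and increase toward the ostium.  When a frame table carries no
positions they are synthesized as `frame_index × frame_spacing_mm`
(default 0.5 mm), treating ECG-gated frames as uniformly spaced — an
approximation of gating.

**Morphometry.**  Plaque CSA = EEM − lumen; plaque burden = plaque/EEM;
PAV = 100 × Σ(EEM − lumen)/ΣEEM over a frame set.  Composition fractions
are taken relative to *characterized* tissue (F+FF+NC+DC), not to plaque
CSA, because VH leaves media and unclassified pixels uncounted; under this
convention typical fibrous fractions of ~0.55 cohere with the remaining
components.  Segment means are unweighted frame means (uniform gated
spacing assumed); a config flag switches to trapezoidal length weighting.

**Remodeling index.**  No standard segment-level definition exists, so the
package uses: EEM CSA at the segment's minimal-lumen-area (MLA) frame over
the mean EEM CSA of the segment's two end frames — the nearest available
reference sites in a segment-based design.  When the MLA frame *is* an end
frame, the opposite end frame alone is the reference.  MLA ties resolve to
the most distal frame.  The definition is isolated in one function so
alternatives are drop-in.

**Phenotype cascade.**  NL (burden < 40%) → TCFA candidate (NC ≥ 10% with
NC–lumen arc ≥ 30°) → ThCFA (NC ≥ 10%, no contact) → FcP (DC ≥ 10%) → PIT
(FF ≥ 15%) → FP.  Two surrogates are explicit: a scalar NC fraction cannot
express spatial confluence, so total NC ≥ 10% stands in for "confluent
NC"; and "no visible fibrous cap" is read from the contact arc, with the
30° default swappable for a strict any-contact (≥ 1°) reading.  TCFA
requires ≥ 3 consecutive candidate frames, confirmed over the whole
pullback; members of shorter runs demote to ThCFA (NC-rich plaque whose
cap criterion is unconfirmed — the severity-conservative choice, rather
than a demotion to FP).  Because confirmation is pullback-wide, a run
straddling a 5-mm boundary automatically labels both segments TCFA; the
explicit straddle flag in `label_segment` is a guard for per-segment
confirmation workflows.

**LAPS.**  The frame score is the published linear form (coefficients live
in config, not code, so alternative coefficient sets — including a
negative MLA coefficient — are drop-in).  Frame-level conventions: the MLA
term uses the frame's own lumen CSA, the only frame-local reading of a
lesion-level quantity (config flag to use the segment MLA instead); the
remodeling condition comes from the enclosing segment; NC/DC floors DC at
0.01 mm² and caps the ratio at 10 so calcium-free frames stay finite and
monotone, and NC = 0 gives ratio 0.  Segment LAPS = max over frames;
pullback LAPS = mean over segments.

**Registration and segmentation.**  Landmark frame pairs define a
piecewise-linear, strictly monotone map from baseline to follow-up axial
position, exact at every landmark and clamped outside the outermost pair.
The registered overlap is partitioned into consecutive 5-mm windows
anchored at the distal landmark; the proximal residual shorter than one
segment is dropped.  Follow-up spans may hold different frame counts
(registration stretch); each timepoint is averaged over its own span.
Patients with < 25 mm registered overlap are excluded with a recorded
reason.  Window membership uses half-open intervals with a 10⁻⁹ mm
boundary tolerance so grid points on a window edge resolve consistently.

**Statistics.**  Welch's unequal-variance t test for numeric contrasts
(group sizes differ ~3:1), Mann–Whitney U when normality cannot be
assumed (normality is a caller decision, recorded with every result);
Fisher's exact test for 2×2 tables; Pearson correlation; and a linear
mixed model (REML, statsmodels MixedLM) with a patient random intercept
for segment-level group contrasts, since segments cluster within patients.
A singular mixed fit falls back to the fixed-effect-only estimate, flagged
in the output, never silently.  No multiple-testing correction is applied
by default; a flag adds Benjamini–Hochberg.  Percentages are reported to
one decimal, rounding halves away from zero.

## The synthetic cohort generator

The generator emulates the tabular statistical structure of a two-group
serial statin study — 17 diabetic and 44 non-diabetic patients, vessels of
70.5 ± 15.8 / 72.9 ± 18.6 mm, per-segment baseline geometry, 1-year change
distributions, baseline phenotype mix and TCFA fate probabilities
(new 20.3%/12.6%, persistent 82.1%/71.3%), and LDL-cholesterol covariates
whose change correlates with plaque change at 0.47 in the non-diabetic
group only.  Defaults live in `src/plaquekit/data/generator_defaults.yaml`.

Generation is top-down so recovery tests have exact ground truth: segment
targets are drawn first, then frames are synthesized with zero-mean
within-segment variation, making every segment mean hit its target
exactly (to machine precision).  Key design choices:

- **Joint plaque/vessel changes.**  Per segment the plaque-area and
  EEM-area changes are drawn as a correlated bivariate normal
  (ρ = 0.93 DM / 0.97 non-DM).  The correlation is not free: the three
  change SDs (plaque 0.97/1.15, vessel 1.4/1.8, PAV 2.8/2.5) are mutually
  consistent only near those values, and the implied PAV-change mean then
  reproduces the group values (+0.7 / −1.4 %) without being imposed.
  Drawing the changes independently would inject artificial lumen noise
  (SD ≈ 1.5 mm² per segment) that the reported vessel-area SD rules out.
  Each change carries a shared patient random intercept (30% of the SD)
  plus segment noise.
- **Phenotype realization.**  Six composition templates sit safely inside
  the cascade thresholds so multiplicative frame noise (lognormal,
  σ = 0.12) cannot cross a class boundary.  TCFA segments carry a
  candidate run of 3–7 of their ~10 frames with contact arcs of 40–120°,
  the rest ThCFA-like — which is why the cohort-wide fraction of TCFA
  *frames* (~23%) stays below the fraction of TCFA *segments* (~45–49%).
  Baseline lesion PAV is truncated at ≥ 43% and no-lesion PAV at ≤ 38% so
  intended classes survive frame noise; follow-up lesions are floored at
  41.5%.  Burden adjustments at follow-up rescale plaque and EEM *at
  constant lumen*, so they cannot leak into the lumen-driven part of the
  risk score; a new TCFA arising from a no-lesion segment is brought to
  lesion burden the same way (adaptive outward remodeling).
- **Fates and remodeling dynamics.**  Follow-up labels come from the fate
  probabilities (TCFA: persistent vs healed-to-ThCFA; non-TCFA: new-TCFA
  vs a 10% one-step severity drift).  About 30% of lesion segments carry a
  focal, positively remodeled profile (central EEM bump, remodeling index
  ≈ 1.07); between timepoints diabetic lesions gain such a profile with
  probability 0.05 and non-diabetic lesions lose theirs with probability
  0.05, reflecting the diverging remodeling behavior of progressing vs
  regressing plaque.  With these mechanisms the pullback-LAPS change —
  which is never imposed directly — emerges positive in the diabetic and
  negative in the non-diabetic group; its configured distribution
  (0.13 ± 1.79 / −0.23 ± 1.66) is drawn directly only by the fast
  segment-delta sampler used in statistics-layer tests.
- **Registration structure.**  Follow-up pullbacks are stretched
  piecewise-linearly (each landmark leg scaled by U(0.92, 1.08), snapped
  to the 0.5-mm grid) around a mid-vessel landmark, so baseline and
  follow-up spans genuinely differ in frame count.

What the generator does **not** emulate: real 3-D geometry, speckle or
RF-derived measurement noise, within-segment spatial autocorrelation of
composition, joint dependence between morphometric change and fate beyond
group membership (assumed conditionally independent), or inter-observer
contouring variability.  Passing recovery tests therefore demonstrate that
the pipeline's bookkeeping, registration, classification and statistics
are correct under known ground truth — not that the pipeline is robust to
real-world imaging artifacts.

## Numerical and reporting conventions

- Units are fixed (mm², mm, degrees) and never auto-detected.
- Composition sum tolerance is 5% of plaque area (fractional, because VH
  leaves pixels unclassified); every frame invariant raises a validation
  error naming the frame and rule.
- Result CSVs are written with 12 significant digits (re-read reproduces
  reals to 1e-9, integers exactly); the run manifest records a config
  hash, the seed, per-group counts and exclusions.
- The pipeline is deterministic: identical inputs and config give
  bit-identical tables.

## Problem sizes used by the test suite

Full-cohort tests run one default cohort (61 patients, ~850 segment
pairs, ~36 000 frames) at a fixed seed; the directional group checks pool
three replicate cohorts to keep patient-level means clear of sampling
noise; null-calibration checks use 1000 two-sample replicates and 100
mixed-model cohorts.  The whole suite completes in under a minute on one
CPU.

## Known limitations

- The remodeling-index definition is a package convention; published
  lesion-level definitions using distal/proximal reference segments will
  give different values at segment boundaries.
- Frame-level LAPS with the frame's own lumen CSA makes the score higher
  in larger lumens by construction; the positive MLA coefficient is kept
  exactly as published and can be overridden in config.
- The new-TCFA rate is reported against the baseline-non-TCFA denominator
  (the alternative all-segments rate is emitted alongside), since
  published rates do not state their denominator.
- Mixed-model p-values rely on asymptotic Wald inference; with very few
  patients per group, permutation inference would be preferable.
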