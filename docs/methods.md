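# Methods

## Problem and model

In facioscapulohumeral muscular dystrophy (FSHD), muscle tissue is
progressively replaced by fat, and the replacement is not uniform along a
muscle: affected lower-extremity muscles are typically most infiltrated at
their distal end, with a transition zone — the *fat front* — separating a
high distal plateau from a spared proximal plateau. `fatfront` implements
the analysis chain needed to quantify this from Dixon MRI: voxelwise fat
fractions, length-normalized per-muscle profiles, segment statistics,
longitudinal "wave" progression summaries, a parametric front model, and an
audit of the bias incurred by sampling only a few slices.

### Fat-fraction mapping

For co-registered fat (F) and water (W) images, FF = 100·F/(F+W) percent.
Voxels with total signal F+W ≤ ε (default ε = 0) carry no information and
are marked missing (NaN); they are excluded from every mean rather than
forced to zero, which would otherwise create 0/0 artifacts in background.

A linear cross-scanner correction FF′ = a·FF + b (defaults a = 1.1864,
b = −2.7878, appropriate for mapping pre-upgrade baseline scans onto a
post-upgrade scale) is applied voxelwise to baseline maps. Because the
affine map sends FF < b/|a| ≈ 2.35% below 0 and FF ≳ 86.6% above 100, the
corrected values are clipped to [0, 100] to preserve the FF invariant.

### Stack stitching

Multi-station acquisitions are stitched on the shared 5 mm slice grid.
In overlap regions (typically 9 slices = 45 mm) each output slice takes the
value from the stack in which it lies farther from the stack edge, because
coil sensitivity — and hence image quality — is worst at stack edges. The
policy is deterministic; ties keep the more distal stack. Averaging across
overlapping stacks is available as `blend="average"`. A gap between stacks
is a validation error reporting the uncovered extent. All volumes are
normalized so slice 0 is the most distal slice.

### Profiles, segments, subsampling

Muscle lengths differ, so slice i of an N-slice muscle sits at relative
position 100·i/(N−1) percent (endpoints exactly 0 and 100). Slices interior
to the span with no labeled voxels (segmentation holes) are dropped with a
warning; positions are computed from the span so the endpoints are kept.

* **Whole-muscle FF** is the voxel-count-weighted mean of per-slice FFs,
  identical to the plain mean over all labeled, non-missing voxels.
* **Segments**: slices are binned by relative position into five equal
  bands [0,20), [20,40), [40,60), [60,80), [80,100] (the last closed so
  the proximal end belongs to segment 5); segment means are voxel-weighted.
  For N ≥ 5 no segment can be empty under this convention (positions 0,
  25, 50, 75, 100 at N = 5 land one per bin); emptiness is still checked.
* **Subsampling schemes**: `central5` takes five contiguous slices starting
  at ⌊(N−5)/2⌋ (for even windows the extra slice falls proximal — any fixed
  convention works; this one is documented and tested); `spread5` takes the
  slices nearest 10/30/50/70/90% of muscle length, rounding half away from
  zero, with duplicates allowed and retained for N < 10. Subsampled FF is
  the *unweighted* mean over the selected slices, emulating a reading of
  five acquired slices without volumetric context; whole-muscle values are
  always voxel-weighted.

The profile-shape classifier (`decreasing` / `reversed` / `u_shape` /
`homogeneous` / `other`, threshold δ = 5 pp, rules evaluated in that order)
is a convenience heuristic for triage, not a validated clinical score.

### Cohort metrics

Composite FFs are volume-weighted means (muscle volume = labeled voxel
count × voxel volume), so larger muscles dominate; a patient-level
composite pools both legs' muscles in one weighted pool. Longitudinal
change is FF(follow-up) − FF(baseline), and change per year divides by the
follow-up interval. Baseline bins (0–10 … 80–90%) and Mercuri severity
bands (<10, 10–30, 30–60, >60%) use half-open [lo, hi) edges — the
boundary convention is arbitrary but fixed and tested; FF ≥ 90 is assigned
to 80–90 with a warning. SDs are sample SDs (n−1). The wave analysis
computes, per muscle, segment-level change on each timepoint's own
relative-length axis and aggregates by the muscle's baseline bin.

### Front model

The profile of an affected muscle is modeled as a reversed logistic

    FF(x) = π_base + (π_top − π_base) / (1 + exp((x − x0)/w)),

x ∈ [0,1] distal→proximal, with distal plateau π_top, proximal plateau
π_base, front position x0 (the half-maximum point, allowed in [−0.5, 1.5]
so fronts can sit beyond the muscle ends) and width w > 0. The logistic is
one of several sigmoid families that would fit; it was chosen for its
closed-form mean (∫ logistic = x − w·log(1+e^{(x−x0)/w})) and standard
interpretation of x0 as the front location. Whether the visually identified
"front" is exactly the half-maximum point is an interpretation; it is the
natural center of the transition zone.

Fitting is bounded nonlinear least squares (`scipy.optimize.least_squares`)
with one data-driven start (plateaus from the profile extremes, x0 at the
steepest observed drop) plus nine seeded random restarts; the best-RMSE
solution wins. The seed is mandatory, making fits reproducible. Constant
profiles cannot constrain a front and return a plateau-only fit flagged
`converged=False`. On noiseless model-generated profiles the round trip
recovers all four parameters to ≤ 1e-4 relative; with 2 pp noise on
60-slice profiles, x0 is recovered within ±0.05 in ≥ 95% of replicates.

### Progression law (synthesis only)

Follow-up fronts advance proximally at speed v(FF) = v_max·exp(−((FF −
μ_v)/s_v)²) per year, evaluated at the current whole-muscle FF — a
phenomenological bell law encoding that progression is fastest at
intermediate infiltration. Defaults: μ_v = 35%, s_v = 20%, v_max = 0.065
relative-length/year; with typical plateaus (π_top ≈ 80%, π_base ≈ 5%) the
peak whole-muscle rate is ≈ 4.9%/year in the 30–40% bin. The front also
widens by dw = 0.02/year (the slope grows shallower as disease advances);
widening is *mean-neutral* — after growing w, x0 is re-solved (Brent root
find on the closed-form mean) so the whole-muscle FF is unchanged, and only
the advance term raises it. This enforces the model property that fat
replacement never regresses; when x0 is pinned at its bound the widening is
skipped rather than allowed to lower the mean. The law is an emulator for
pipeline testing, not a biophysical model of DUX4 spread.

### Sampling-bias audit

Error = subsampled value − whole-muscle value, per muscle-side (no
left/right averaging), for baseline FF and change per year. Subsampled
change re-selects slices independently at each timepoint from that
timepoint's own slice count, mirroring how repeat scans are planned in
practice. Bland–Altman summaries report mean error, sample SD and limits
of agreement mean ± k·SD with k = 1.96. The cohort-level mean absolute
error is estimated by an intercept-only random-intercept model (below);
with a single patient it falls back to a one-sample t-test with a logged
caveat.

### Inference

Muscles are nested in patients, so muscle-level models are linear mixed
models with a random intercept per patient, variance-components covariance,
REML estimation — delegated to `statsmodels` MixedLM, which implements
exactly this structure. Fixed-effect p-values use the Wald normal
approximation; with few patients these are indicative, and estimates with
SEs are the primary output (Satterthwaite/Kenward–Roger df would be a
possible extension). The segment-gradient model is FF = β₀ + β₁·segment
(segment numeric 1–5; β₁ < 0 means distal-to-proximal decline); baseline-bin
contrasts compare each bin's change per year against the 0–10% reference
bin with Bonferroni correction over m = 8 tests (capped at 1). The Wilcoxon
signed-rank test uses the exact null distribution for n ≤ 25 without tied
ranks (zeros dropped, ties midranked; tied ranks or larger n fall back to
the normal approximation with continuity correction); exactness is verified
in tests against full 2ⁿ sign enumeration.

## Synthetic phantoms

A phantom leg is a bundle of disjoint elliptical muscle "tubes" (placed on
a ring, radii capped so neighbours cannot touch) inside a subcutaneous fat
shell (FF ≈ 90%), on a 64×64×80 grid at 1.36×1.36×5 mm. Each muscle's
voxel FF is the front model evaluated along its own span plus Gaussian
noise (default SD 2 pp), clipped to [0,100]; fat/water intensities are
F = FF·I/100, W = (100−FF)·I/100 with constant I, so the FF map inverts
exactly. Noise is applied in FF space rather than as complex-valued Dixon
noise — simpler, and adequate for testing the analysis chain. The volume is
cut into 2 stacks with a 9-slice (45 mm) overlap. A cohort has 9 patients
(7 with follow-up at 3.67 years), 2 legs × 6 muscles each; per-muscle front
draws (π_top ∈ [55,90], π_base ∈ [1,8], x0 ∈ [−0.4,1.3], w ∈ [0.04,0.12])
plus a per-patient severity shift (SD 0.25 on x0) populate all baseline
bins. All draws flow from one seeded generator with spawned substreams, so
the same seed gives bit-identical volumes.

What the phantoms do **not** emulate: partial-volume beyond voxelization,
bias fields, motion, fat-water swaps, anatomical muscle shapes, or
between-muscle correlation within a patient beyond the severity shift.
Passing tests therefore demonstrate that the *analysis* is correct and
well-calibrated under the assumed signal model, not that the model captures
every property of patient data.

## Numerical choices

* Logistic evaluated via `scipy.special.expit` (no overflow at extreme
  arguments); plateaus may saturate in floats, so "strictly decreasing" is
  enforced away from saturation.
* Stack offsets must align to the slice grid within 1e-6 slice units.
* Fit bounds: plateaus [0,100]%, x0 [−0.5,1.5], w [1e-3,1]; optimizer
  tolerances 1e-12; if the optimizer crosses π_top < π_base the plateaus
  are collapsed to their midpoint.
* Mean-neutral widening solves x0 by Brent's method to 1e-12.
* Determinism: every stochastic routine takes a seed; CLI runs write logs
  with inputs, versions, and collected warnings.

## Problem sizes used in the checks

The statistical acceptance checks run at desk scale: 1,000 randomized
profiles for the oracle-equivalence checks, 200 replicates for front
recovery and mixed-model CI coverage (9 patients × 40 muscles each),
10,000 replicates for the Wilcoxon type-I rate, the default 9-patient
phantom cohort for the wave signature, and 200 front-bearing muscles for
the sampling-bias direction. These sizes give binomial/Monte-Carlo margins
comfortably inside the asserted bands while keeping a full run under a
minute of compute for the suite's heavy tests.

## Known limitations

* The harmonization is a global affine map; no spatially varying
  correction.
* Timepoint alignment crops to shared coverage only; no voxel
  registration is attempted (per-muscle analyses use relative length, so
  none is needed).
* Mixed-model p-values are Wald/normal; exact small-sample df methods are
  not implemented.
* Fat-water swap detection is not automated; muscles are excluded via an
  explicit exclusion list.
* The profile-shape classifier is a fixed-threshold heuristic.
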