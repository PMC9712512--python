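# fatfront

Whole-muscle proximo-distal fat-infiltration analysis for quantitative
Dixon muscle MRI.

In facioscapulohumeral muscular dystrophy (FSHD) and related myopathies,
muscle is progressively replaced by fat — and not uniformly: affected leg
muscles are typically most infiltrated at the distal end, with a *fat
front* that advances proximally over time. Quantifying this requires
analysing whole muscles end to end rather than the handful of central
slices most quantitative MRI studies use. `fatfront` is a library and CLI
for researchers doing exactly that: it turns Dixon fat/water volumes and
muscle label maps into length-normalized fat-fraction profiles, segment
statistics, longitudinal progression summaries, parametric front fits,
and an audit of how badly few-slice sampling biases the results.

## What it computes

* **Fat-fraction maps**: FF = 100·F/(F+W) percent per voxel, with
  missing-value handling for background, an affine cross-scanner
  harmonization (FF′ = 1.1864·FF − 2.7878 by default, clipped to
  [0, 100]), and stitching of overlapping acquisition stacks (45 mm
  overlap, distance-to-edge policy).
* **Profiles**: per-slice muscle FF against relative muscle length
  (distal 0% → proximal 100%), five equal proximo-distal segments, and the
  two localized-sampling schemes used in practice (central 5 slices;
  5 slices spread at 10/30/50/70/90% of length).
* **Cohort metrics**: volume-weighted composite FFs, change and change
  per year, 10%-baseline-FF bins, Mercuri severity bands, and the
  segment × baseline-bin change matrix that exposes wave-like proximal
  progression.
* **Front model**: FF(x) = π_base + (π_top − π_base)/(1 + e^{(x−x0)/w}),
  a reversed logistic with plateaus π_top/π_base, front position x0 and
  width w; bounded multi-start least-squares fitting and a progression law
  for synthesis.
* **Sampling-bias audit**: per-muscle error (subsampled − whole-muscle)
  for baseline FF and yearly change, Bland–Altman limits of agreement,
  and mixed-model estimates of the mean absolute error.
* **Inference**: random-intercept (patient) linear mixed models fitted by
  REML, exact small-sample Wilcoxon signed-rank, Bonferroni correction.
* **Phantoms**: a seeded generator of synthetic legs and longitudinal
  cohorts with known ground truth, so the full pipeline runs and is
  validated without any patient data.

## Worked example

```python
import numpy as np
from fatfront import (SyntheticLegConfig, generate_leg, whole_muscle_ff,
                      segment_means, fit_front, mercuri_class)
from fatfront.pipeline import leg_profiles

leg = generate_leg(SyntheticLegConfig(seed=42))          # phantom leg
profiles = leg_profiles(leg.stacks, leg.label_map)       # FF map -> stitch -> profiles
for prof in profiles[:3]:
    ff = whole_muscle_ff(prof)
    seg = segment_means(prof)
    fit = fit_front(prof, seed=0)
    print(f"{prof.muscle}: whole-muscle FF {ff:5.1f}% ({mercuri_class(ff)}), "
          f"segments {np.round(seg.means, 1)}, "
          f"front x0={fit.params.x0:.2f}, w={fit.params.w:.3f}")
```

prints

```
muscle_01: whole-muscle FF  73.9% (>60), segments [83.9 83.9 83.6 78.1 41.6], front x0=0.89, w=0.069
muscle_02: whole-muscle FF  81.3% (>60), segments [89.  89.  88.8 86.6 53.2], front x0=0.92, w=0.057
muscle_03: whole-muscle FF   3.0% (<10), segments [7.6 2.4 1.7 1.6 1.7], front x0=-0.12, w=0.088
```

Reading `muscle_01`: the five segment means fall from 83.9% distally to
41.6% proximally — the classic decreasing profile — and the fitted front
sits at 89% of muscle length (x0 = 0.89), i.e. the transition zone has
nearly reached the proximal end. `muscle_03` is essentially spared (3.0%
whole-muscle FF); its front position below 0 means the transition lies
beyond the distal end.

The same stages are available from the shell:

```bash
fatfront simulate --seed 1 --out-dir sim/            # phantom cohort (NIfTI + truth)
fatfront ffmap --fat f0.nii.gz --water w0.nii.gz \
         --fat f1.nii.gz --water w1.nii.gz \
         --offset-mm 0 --offset-mm 80 --out ff.nii.gz
fatfront profile --ff ff.nii.gz --labels labels.nii.gz \
         --config config.yaml --out-dir tables/
fatfront fit-front --profiles tables/profiles.csv --seed 1 --out fits.json
fatfront cohort --baseline tables/profiles.csv --followup fu/profiles.csv \
         --interval-years 3.67 --out-dir cohort/
fatfront bias --baseline tables/profiles.csv --out-dir bias/
```

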