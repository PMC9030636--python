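# scalafit

Template-based scalar localization of cochlear-implant electrode arrays.

After cochlear implantation, each electrode of the array should lie in the
scala tympani (ST); contacts that cross the basilar membrane into the scala
vestibuli (SV) mark insertion trauma and predict poorer hearing outcomes.
Post-operative CT cannot show the membrane directly (metal artifact,
limited resolution), so `scalafit` implements a fast template workflow for
clinicians and researchers working with temporal-bone imaging:

1. **Measure** the cochlear dimensions on the pre-operative scan: distance
   *A* (round-window center to lateral wall at 180°), distance *B*
   (lateral wall 90° to 270°), and the height *H³⁶⁰* at one turn.
2. **Index** the cochlea by *(A/B)·H³⁶⁰* (with *A·H³⁶⁰* and *A·B·H³⁶⁰* as
   alternatives).
3. **Select** the nearest of five basilar-membrane templates — mid-surface
   meshes of the cochlear duct spanning the population quantiles of the
   index — with mirrored contralateral versions for the other ear.
4. **Merge** the template with the electrode-array reconstruction by a
   least-squares similarity transform on four shared landmarks
   (round-window center; lateral wall at 90°, 180°, 270°).
5. **Classify** each contact from the fraction of a sphere of the contact
   diameter lying under the membrane's local tangent plane:
   ≥ 50 % → ST, ≥ 10 % and < 50 % → intermediate (INT), < 10 % → SV.

Because patient and cadaver image banks are not distributable, the package
ships a parametric cochlear simulator: a logarithmic spiral
*r(θ) = a·e^(−bθ)* swept into a ribbon mid-surface, solved so its
landmarks reproduce sampled population dimensions
(A = 9.1 ± 0.30 mm, B = 6.8 ± 0.32 mm, H³⁶⁰ = 2.8 ± 0.21 mm, 2.25–3
turns), implanted with 16- or 20-contact arrays in prescribed
translocation scenarios with known per-electrode ground truth.  An
agreement module provides Fleiss' κ (overall and per category, bootstrap
CIs) and the χ² comparison of intermediate-electrode proportions for rater
studies.

## Worked example

```python
import scalafit as sf

case = sf.synth_case(seed=42, pattern="proximal_crossing",
                     model_name="midscala_like")
transform = sf.fit_landmark_transform(case.template_truth.landmarks,
                                      case.landmarks_noisy)
call = sf.classify_array(case.array, case.template_truth, transform)
print(call.summary())
```

prints

```
{'translocated': True, 'first_sv_angle': 181.8457...,
 'counts': {'ST': 10, 'INT': 0, 'SV': 6}}
```

— the simulated perimodiolar array crossed the duct mid-plane at 180° of
insertion; the ten basal contacts are called scala tympani, the six apical
contacts scala vestibuli, and the first SV contact sits at 181.8°, one
contact past the crossing.  The registration residual for this case is
0.093 mm against 0.1 mm landmark click noise.  The scripts in `examples/`
walk through simulation and classification, bank construction and fit,
rater agreement, and a batch pipeline run; each prints the numbers it
computes and a line on how to read them.

A thin CLI mirrors the library:

```sh
scalafit simulate --n 1 --pattern proximal_crossing --seed 7 --out-dir sim/
scalafit index --landmarks sim/case-000_landmarks.json --h360 2.8
scalafit classify --array sim/case-000_array.csv --template sim/case-000.ply \
         --case-landmarks sim/case-000_landmarks.json --out calls.csv
scalafit agree --ratings ratings.csv --per-category --seed 1
```

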