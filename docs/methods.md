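# Methods

## The clinical problem and the method in brief

The cochlea is a spiral of 2.25–3 turns whose duct is divided by the
basilar membrane (together with the osseous spiral lamina, the "mid-plane
of the cochlear duct") into the scala tympani below and the scala
vestibuli above.  A cochlear-implant array inserted through the round
window should stay in the scala tympani; crossing the mid-plane
(translocation) is traumatic.  Post-implantation imaging cannot resolve
the membrane, so its position is inferred by registering a membrane
*template* — a mid-surface mesh reconstructed from a different, well-imaged
cochlea of matching proportions — into the patient scene through four
landmarks that are identifiable on any scan: the round-window center and
the lateral wall at 90°, 180° and 270° of insertion angle.  Each electrode
is then called scala tympani (ST), intermediate (INT) or scala vestibuli
(SV) from how much of the contact lies under the registered surface.

## Coordinate convention

All geometry is millimetres and degrees in a right-handed frame: modiolar
axis = +z, base plane z = 0, insertion angle θ = 0 at the round-window
center, θ increasing apically.  A right cochlea winds counterclockwise
seen from the apex; a left cochlea is the mirror image through the plane
of the modiolar axis and the 0° ray.  Replacing the viewer-based
multiplanar alignment of clinical practice with this explicit frame is
what makes the pipeline testable end to end.

## Parametric cochlea (the simulator)

The duct mid-line is a logarithmic planar spiral r(θ) = a·e^(−bθ) with a
piecewise-linear height profile: slope H³⁶⁰/2π up to one turn (pinning
z(2π) − z(0) = H³⁶⁰ exactly), then half that slope to the apex (default
total height H³⁶⁰·(1 + 0.5·(turns − 1))).  The mid-surface is a ribbon of
constant width (default 0.8 mm) swept radially about the mid-line and
triangulated at a configurable angular step (2.5° default; 5° in cohort
studies for speed).  Given sampled dimensions (A, B, H³⁶⁰), the two spiral
parameters (a, b) are solved exactly — including the vertical components
of the two landmark chords — by bracketing b; the analytic landmarks of
the solved spiral reproduce A and B to 1e−9 mm, and mesh-extracted
landmarks agree within the vertex discretization.

Two deliberate simplifications:

* A log spiral fitted to the basal chords decays fast apically; where the
  nominal half-width would cross the modiolar axis (beyond ~540°) the
  ribbon tapers, keeping the inner edge at 2 % of the basal radius.
  Landmarks (≤ 270°) and the classification window (≤ 540°) are
  unaffected.
* The height profile makes consecutive apical turns vertically close
  (~1.4 mm past one turn), as in real cochleae.  Classification therefore
  restricts nearest-surface queries to the insertion region of interest
  (0–570°); otherwise a contact displaced toward the scala vestibuli
  near 400° could be attributed to the turn above it.

Population sampling uses independent normals
A = 9.1 ± 0.30, B = 6.8 ± 0.32, H³⁶⁰ = 2.8 ± 0.21 mm (pre-implantation
patient statistics; a specimen-like variant 9.2/7.0/2.9 feeds bank
candidates), turns ~ U(2.25, 3.0), side fair-coin.  Non-physical draws
(non-positive, A ≤ B) are resampled with bounded retries.  Every case gets
a random rigid pose (the scanner frame) before landmark noise — isotropic
Gaussian, σ = 0.1 mm by default, emulating sub-voxel click error — is
added; without the pose, template and case would share the canonical
generator frame and registration would be vacuous.

### Implanted arrays and ground truth

Two built-in models: `midscala_like` (16 contacts over ~420°,
0.7 mm contact diameter, perimodiolar-style) and `evo_like` (20 contacts
over ~450°, 0.5 mm, lateral-wall-style); contacts are spaced uniformly in
arc length along the mid-line.  The contact path is offset along the local
surface normal:

* clean insertion: −0.6 mm (scala tympani side) everywhere.  The true
  clearance between a well-placed array and the membrane is not published;
  0.6 mm is an assumption consistent with a contact resting near the
  scala-tympani floor (basal scala height ≈ 1 mm) and is configurable.
* proximal crossing: −0.6 mm below the onset angle (default exactly 180°),
  +0.8 mm above it — the array perforates the membrane and stays in the
  scala vestibuli, with the crossing falling between two contacts.
* distal bending (lateral-wall arrays beyond 300°): beyond onset the
  contact centers sit +0.27 × contact-radius above the plane — the middle
  of the intermediate band in distance, i.e. the array rides up against
  the membrane without fully crossing.

Ground-truth categories come from these construction offsets pushed
through the spherical-cap fraction and the fixed thresholds — independent
of the classification pipeline under test.  Cohort pattern frequencies
mirror a 30-cochlea cadaver design: half perimodiolar-style (8 clean / 7
proximal per 15), half lateral-wall-style (7 clean / 4 proximal / 4 distal
per 15; distal patterns are specific to lateral-wall arrays).

## Morphometric indices and the template bank

From the landmarks: A = ‖rw − lw180‖, B = ‖lw90 − lw270‖; H³⁶⁰ is supplied
per case (it is measured on an aligned image plane, which is viewer work
outside this package's scope; the simulator provides it as truth).  The
three indices are A·H³⁶⁰ (mm²), A·B·H³⁶⁰ (mm³) and (A/B)·H³⁶⁰ (mm); the
ratio index drives the default pipeline.  The algebraic identities
i_ABH / i_AH = B and i_AH / i_AoBH = B hold to machine precision and are
property-tested.

Bank construction fits a Gaussian to a reference index sample (the
100-patient emulation; Shapiro–Wilk normality is reported by
`fit_index_distribution`), computes the quantiles at the 10/30/50/70/90th
percentiles — equal-mass quintile midpoints; the source procedure says
only "selected according to the Gaussian distribution", so the symmetric
choice is ours and configurable — and greedily assigns each quantile the
unused candidate with the nearest index, ties toward the lower index.
The five picks are mirrored for the contralateral side.  Selection for a
case minimizes |index − case index|, ties toward the lower index;
out-of-range cases clamp to the extreme template with a logged warning
(every patient gets a template).

## Registration

The four-landmark merge is the closed-form Umeyama least-squares
similarity fit with det(R) = +1 enforced; `allow_scale=False` gives the
rigid variant.  Scaling defaults on: the templates come from
different-sized cochleae and the uniform scale absorbs the size mismatch,
which is the premise of index-based template selection.  A reflection is
never fitted; if the (disallowed) reflective fit would reduce the residual
more than tenfold, a chirality warning tells the caller to use the
mirrored template.  Transform recovery on noiseless quadruples is exact to
< 1e−8 over 1000 random similarity transforms.

Cloud-to-cloud distance is nearest-neighbour point-to-point by default
(matching the common mesh-processing tool used for the original
validation), with an exact point-to-surface option and a symmetric mode
that pools both directions.  Template-fit validation crops both membranes
to 90–540° first — basally the hook region is unreliable to segment,
apically coverage varies.

## Scalar classification

For each contact (pulled into template frame through the inverse
transform, distances rescaled by the fitted scale), the signed distance to
the membrane is the distance to the nearest surface point, positive on the
scala-vestibuli side of the local tangent plane (normals are
vestibuli-oriented by construction; the loader checks and flips).  The
"percent of the electrode under the membrane" is operationalized as the
volume fraction of a sphere of the contact diameter below that plane:
with h the signed distance clamped to ±r and a = r − h,
f = a²(3r − a)/4r³ — closed-form, rotation-invariant, strictly decreasing
in the distance, exactly ½ at contact center on the membrane.  The
clinical definition quantifies "percent" without fixing the geometry; the
spherical model is this package's choice, and a chord (projected-length)
alternative is available via `method="chord"`.  Thresholds are the fixed
clinical ones: f ≥ 0.50 → ST, 0.10 ≤ f < 0.50 → INT, f < 0.10 → SV,
boundaries inclusive exactly as written.

Reported electrode angles come from projecting the contact onto the duct
mid-line, not onto the ribbon surface: the surface normal is perpendicular
to the mid-line tangent, so normal offsets project back with no
first-order angle bias.  Contacts whose nearest surface point lies on a
mesh boundary, or whose angle falls outside 90–540°, are flagged
edge-extrapolated but still classified (the tangent plane is effectively
extended past the ribbon edge), mirroring how hook-region electrodes are
judged in practice.

## Agreement statistics

Fleiss' (1971) fixed-marginal κ: per-item agreement
P_i = (Σ_j n_ij² − n)/(n(n−1)), chance agreement P_e = Σ_j p_j²,
κ = (P̄ − P_e)/(1 − P_e); undefined when every rating falls in one
category.  Per-category κ collapses to category-vs-rest and applies the
same statistic.  Confidence intervals default to a seeded nonparametric
bootstrap over items (2000 resamples, percentile interval; single-category
resamples are skipped) — valid for the collapsed tables where asymptotic
formulas are shaky — with the Fleiss large-sample variance available as
`method="asymptotic"`; fewer than 5 items refuses the interval with a
warning.  The intermediate-proportion comparison is the Pearson χ² on the
2×2 table, 1 df, continuity correction off by default, with a warning when
an expected cell drops below 1.

## Problem sizes and numerical choices

Cohort studies use 100 cases (classification) and 30 cases (bank fit) at a
5° angular step, chosen as the package's standard study sizes; meshes are
a few thousand faces and exhaustive exact point-triangle projection (no
spatial index) is both correct and fast at this scale.  Seeds propagate
through `numpy` `SeedSequence`/`default_rng` only: rebuilding any case,
cohort, bank or bootstrap with the same seed is bit-for-bit reproducible.
Tolerances: orthonormality of rotations 1e−9; landmark-degeneracy test via
the second singular value at 1e−9 relative; tie-breaks (bank assignment,
template selection) always toward the lower index value.

## What the synthetic studies do and do not show

Passing cohorts demonstrate that the pipeline recovers known ground truth
under the stated geometric model and landmark-noise level: per-electrode
accuracy ≥ 95 % (typically ~99.5 %), translocation flags essentially
perfect for clean-vs-proximal scenarios, first-SV localization within one
local inter-electrode spacing, and template-bank fit distances well under
0.5 mm for ≥ 90 % of cases.  They do not reproduce rater variability,
segmentation error, metal artifact, non-spiral anatomic variants, or
histology — the simulator's membranes are exactly the model family the
templates come from, so these results bound what the method can do when
its geometric assumptions hold, not clinical performance.  Intermediate
calls are intrinsically the hardest: the INT band spans only ~0.6 contact
radius in distance (~0.15 mm for a 0.5 mm contact), the same order as the
registration error induced by 0.1 mm landmark noise, which is consistent
with intermediate electrodes showing by far the weakest inter-rater
agreement in clinical studies.

## Known limitations

* H³⁶⁰ is an input, not measured from imaging by this package.
* The spiral family is smooth and single-parameter per dimension set;
  real cochleae show local wall irregularities the similarity transform
  cannot absorb.
* Distal-bending ground truth places contacts at a fixed offset in the
  intermediate band; real partial detachments are heterogeneous.
* The classifier treats the membrane as rigid and locally planar at the
  contact scale, as the template method itself does.
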