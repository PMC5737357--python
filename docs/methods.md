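# Methods

`dirdose` studies how the choice of dose-accumulation method changes the
reported rectum and bladder dose in combined radiotherapy for cervical
cancer: external-beam treatment (a whole-pelvis box plan plus a
centre-shielded boost with a midline block) delivered together with
weekly high-dose-rate intracavitary brachytherapy. Because the
brachytherapy applicator deforms the pelvic anatomy strongly between
imaging sessions, the per-plan dose grids live on incompatible patient
geometries. The package implements and compares two ways of combining
them:

1. **DVH parameter addition** — the GEC-ESTRO-style baseline: convert
   each plan to EQD2, read the DVH parameter (D_0.1/1/2 cm³) off each
   plan's own frame, and sum the parameters. This assumes the most
   exposed subvolumes coincide across plans.
2. **DIR-based accumulation** — deformably register every frame to the
   reference (first brachytherapy) CT, warp the per-plan EQD2 dose with
   the resulting displacement fields, sum voxel-wise on the reference
   frame, and read the DVH parameters off the accumulated volume.

Everything is validated on synthetic pelvic phantoms with known
ground-truth deformations, since that is the only setting in which
registration error can be measured exactly.

## Volumetric model

Volumes are regular axis-aligned grids; world coordinates are
`origin + index · spacing` (voxel centres, mm), axes fixed as
right→left / anterior→posterior / inferior→superior. Displacement
fields use the pull-back convention: the moving image is sampled at
`p + u(p)` for reference point `p`. All frames are brought onto the
reference grid before accumulation; out-of-support voxels are filled
with −1000 HU for CT and 0 Gy for dose (physically neutral defaults).
I/O is plain NIfTI with a JSON sidecar naming the structure masks.

Interpolation uses `scipy.ndimage.map_coordinates` with
`mode="grid-constant"` so values roll off linearly into the fill value
at grid edges; a hard cutoff there would make the registration
objective discontinuous in `u`.

## Synthetic phantom

The reference frame contains a soft-tissue body cylinder, a uterus
ellipsoid with a metal-like applicator tandem (2500 HU) running through
its canal, bladder and rectum as anterior/posterior neighbours, and an
HR-CTV around the cervix. Organ HU values are separated by tens of HU
(soft-tissue-like contrast) and Gaussian noise (σ = 6 HU) is added
independently per frame. The default grid is 96×96×64 voxels at 2.5 mm
isotropic — under 10⁶ voxels while still resolving the 4 cm midline
shield and the brachytherapy dose gradient.

Deformed frames are produced by warping the noise-free reference
anatomy with an analytic map and adding fresh noise, so the exact
displacement field is stored with each frame:

* **organ filling** — radial rescaling about each organ centroid with a
  Gaussian window (per-fraction bladder scales 1.15/0.85/1.10, rectum
  0.90/1.12/1.05; EBRT frame 1.25/1.10);
* **applicator push** — for the applicator-free EBRT frame, a radial
  displacement about the tandem axis with profile
  `p(r) = A (r/ρ) e^{(1-(r/ρ)²)/2}` (peak `A` = 8 mm at `r = ρ` = 25 mm),
  which is smooth at the axis and invertible whenever `A < ρ`;
* **setup pose** — the EBRT frame is additionally posed rigidly
  (5 mm translation + 3° rotation by default).

A small seeded jitter (3 % on scales, 1 mm / 0.5° on the pose)
individualises cases while keeping them reproducible from one integer
seed. Every generated field is checked for a positive discrete Jacobian
determinant; amplitudes that break invertibility are rejected.

The bladder is deliberately kept within the lateral extent of the 4 cm
midline block (semi-axis 16 mm left–right). The premise of the
centre-shielded technique — and of excluding the CS plan from DVH
addition — is that the block fully covers the zone where the organs at
risk receive their highest brachytherapy dose; a laterally protruding
organ would break that premise by construction rather than by
registration physics.

### Dose models

* **Brachytherapy**: a bare inverse-square dwell sum,
  `dose(x) = S Σᵢ (r₀/rᵢ)²` with `r₀` = 10 mm, six dwells along the
  tandem over 30 mm, distances floored at half a voxel diagonal. `S` is
  set so the frame's HR-CTV D90 equals the 6 Gy prescription exactly
  (the metric is linear in the scale). No TG-43 anisotropy or radial
  dose function: the analysis only needs a sharp applicator-centred
  gradient, and the 30 %-isodose volume exceeds 4× the 90 %-isodose
  volume at default geometry.
* **Whole pelvis (WP)**: flat `total` Gy (30 Gy / 15 fractions) inside
  the body bounding box shrunk by 15 mm, with a compactly supported
  cubic-smoothstep penumbra of ±3 mm. The dose is *exactly* the
  prescription more than 3 mm inside the field and exactly zero more
  than 3 mm outside.
* **Centre-shielded (CS)**: the same box (20 Gy / 10 fractions) with a
  40 mm-wide full-height strip at the body midline reduced to
  `transmission × total` (default transmission 0, configurable to model
  leakage). With the compact penumbra the block is exactly zero over
  the whole high-BT-dose zone.

The compact penumbra (instead of a logistic tail) is what makes the
zero-deformation limit exact: with all frames identical, the WP dose is
constant over the organs, the CS dose vanishes on the hottest voxels,
and DIR-based accumulation reproduces DVH parameter addition to
floating-point precision.

## Registration

**Rigid fusion** automates the clinical manual shift-and-rotate step:
centroid alignment of the uterus masks seeds a Powell search over six
pose parameters (bounded ±20 mm / ±15°) minimising a soft
(Gaussian-smoothed) Dice objective on a cropped subgrid; the returned
transform never scores a lower hard uterus DSC than the identity.

**Deformable registration** minimises one documented energy on a dense
displacement field:

```
E(u) = w_img · S_img(u) + w_struct · S_struct(u) + w_reg · R(u)
```

* `S_img` — one minus the mean local normalized cross-correlation of HU
  (Gaussian window σ = 3 voxels) inside the body contour;
* `S_struct` — mean over the configured structures of one minus the
  squared-denominator soft Dice `2Σpq/(Σp²+Σq²)` between the warped
  moving and fixed structure probability maps. This Dice variant equals
  1 exactly when the maps coincide, so a perfect match is a stationary
  point even for smoothed (non-binary) maps — with the plain
  `2Σpq/(Σp+Σq)` form the optimiser can drift away from a perfect
  alignment;
* `R` — discrete bending energy (mean squared Laplacian of `u`).

The two clinical settings are expressed purely through the structure
term: *intensity* mode (`w_struct = 0`, body contour used only as the
similarity region) and *hybrid* mode (`w_struct = 1` over uterus,
rectum, bladder and body). Defaults: `w_img = 1`, `w_reg = 1`.
`w_reg = 1` (rather than a much smaller value) is needed because the
Dice term constrains only boundary-normal motion; with weak bending
regularisation the optimiser introduces tangential drift that leaves
the DSC high but degrades point correspondence (measured as TRE against
the ground-truth fields).

Optimisation is multi-resolution gradient descent (pyramid factors
4×/2×/1×, 80/40/10 iterations) with Gaussian-smoothed updates
(σ = 2 voxels) and a backtracking accept test, so the objective is
non-increasing within each level and the whole procedure is
bit-deterministic (zero-field initialisation, no randomness). Gradients
of the correlation term use the standard local approximation that
ignores the window coupling; the accept test guards against any
resulting non-descent step. The iteration budget is deliberately light
at full resolution — the fields are smooth by construction, so most of
the work happens at the coarser levels; this keeps a full five-case
registration study at desk scale.

This module is a *class* surrogate for commercial hybrid DIR
implementations: it reproduces the intensity-vs-hybrid contrast, not
any particular vendor algorithm, and bit-level agreement with
commercial tools is a non-goal.

**Evaluation**: DSC is computed on voxel masks warped by the dense
field (linear interpolation, threshold 0.5). Target registration error
inverts the stored ground-truth map by fixed-point iteration and
measures the mean distance between estimated and true correspondences
at the surface voxels of the three organs.

## Dose accumulation and DVH metrics

EQD2 conversion applies `EQD2 = D (d + α/β)/(2 + α/β)` per voxel with
`d = D/n_fractions` and α/β = 3 Gy for the late-responding organs at
risk (30 Gy in 15 fractions maps to itself; a single 6 Gy fraction maps
to 10.8 Gy_EQD2). Conversion happens in each plan's native frame
*before* warping by default — the LQ transform is nonlinear and should
see the planned dose, not a resampled one; the opposite order is
available behind a switch (`accumulation_order="warp_then_eqd2"`) so
its effect can be surfaced rather than hidden.

DIR-based accumulation sums *all* plans, including CS; the CS exclusion
rule applies only to DVH parameter addition, where each included plan
contributes the D_x cm³ read off its own frame's organ contour.

D_x cm³ is computed by exact descending voxel sort with partial-voxel
linear interpolation at the crossing voxel — no histogram binning, so
the small 0.1 cm³ metric is free of bin-width sensitivity. The binned
cumulative DVH (default bin 0.1 Gy) exists for export and plotting
only. D90 is D_x at 90 % of the target volume.

## Pipeline and reporting

`run_course` executes rigid fusion → applicator HU replacement (CT
voxels inside the applicator mask set to −1000 HU before DIR, on both
BT images) → both DIR settings → EQD2 → warping → summation → metrics,
and assembles a per-case report: D_0.1/1/2 cm³ for rectum and bladder
under {addition, intensity-DIR, hybrid-DIR}, pairwise method
differences, and the per-frame DSC table — for two scopes
(brachytherapy fractions alone, and brachytherapy plus external beam).
`cohort_summary` aggregates per-case reports to mean ± SD; no
hypothesis testing is performed.

## What the phantoms do and do not show

The generator reproduces the *structure* of the clinical problem:
applicator-induced deformation concentrated around the tandem,
inter-fraction organ filling, low soft-tissue contrast, sharp
inverse-square brachytherapy gradients, a flat box EBRT dose and a
midline block that spares the high-BT-dose zone. It does not reproduce
CT texture, gauze packing, ovoid applicator geometry, tumour
regression, organ sliding, or realistic beam physics (no scatter,
transmission, or heterogeneity corrections). Passing tests therefore
demonstrate that the workflow is *internally consistent* and that the
method ordering (hybrid ≥ intensity ≥ rigid; addition ≥ DIR for
separated hotspots; agreement in the co-located limit) emerges under
controlled conditions — not that any particular clinical DVH value
would be reproduced. Cohort-scale patient values are outside what a
synthetic desk-scale study can or should claim.

## Numerical choices and degenerate inputs

* DSC of two empty masks is an error, not silently 0/0.
* `d_cc` rejects volumes exceeding the organ; the volume→0⁺ limit
  returns the maximum organ dose.
* BT dose normalisation rejects an empty HR-CTV; the inverse-square
  singularity is floored at half a voxel diagonal.
* Ground-truth fields with non-positive Jacobian determinant are
  rejected with the offending amplitude.
* Registration aborts with level context if the objective becomes
  non-finite; a level ends early when no backtracked step decreases the
  objective.
* All randomness flows from explicit integer seeds; repeated runs are
  bit-identical.
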