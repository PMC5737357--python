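# dirdose

Dose accumulation for combined external-beam radiotherapy (EBRT) and
high-dose-rate intracavitary brachytherapy (BT) of cervical cancer,
based on deformable image registration (DIR), with a built-in synthetic
pelvic phantom bench for validating the whole workflow against known
ground-truth deformations.

The package is aimed at medical-physics researchers who want to study
*methodology* — how registration quality propagates into accumulated
organ-at-risk dose — without access to patient data: every input it
needs can be generated, with controlled deformations whose exact
displacement fields are stored alongside the images.

## The problem

A cervical-cancer course combines a whole-pelvis (WP) box plan, a
centre-shielded (CS) plan whose 4 cm midline block spares the zone
where rectum and bladder receive their highest BT dose, and several
weekly BT fractions delivered through an intracavitary applicator. The
applicator deforms the anatomy strongly, so the per-plan dose grids
live on incompatible geometries. Two ways to combine them:

* **DVH parameter addition** (GEC-ESTRO style): convert each plan to
  the equivalent dose in 2 Gy fractions,

  EQD2 = D·(d + α/β)/(2 + α/β),  d = D/n_fractions,  α/β = 3 Gy,

  read D_x cm³ (the minimum dose to the most exposed x cm³) off each
  plan's own frame, and add the parameters — assuming the hottest
  subvolumes coincide across plans. The CS plan is excluded because its
  block covers exactly that zone.
* **DIR-based accumulation**: register every frame to the reference
  (first BT) CT, warp each plan's EQD2 dose with the estimated
  displacement field, sum voxel-wise, then read D_x cm³ off the
  accumulated volume.

Registration accuracy is scored with the Dice similarity coefficient
of the warped versus reference contours,

DSC = |V_d ∩ V_s| / ((|V_d| + |V_s|)/2),

and, on phantoms, with the target registration error against the stored
ground-truth fields. Two DIR settings are provided: *intensity* (local
normalized cross-correlation inside the body contour) and *hybrid*
(intensity plus a soft-Dice structure term over uterus, rectum, bladder
and body), both minimising one documented energy
`E(u) = w_img·S_img + w_struct·S_struct + w_reg·R` with bending-energy
regularisation. See `docs/methods.md` for the full model.

## Worked example

```python
import dirdose as dd
from dirdose.pipeline import run_course

case = dd.generate_case(seed=1)        # frames, masks, WP/CS/BT doses
report = run_course(case)              # rigid + both DIR modes + metrics
print(report.to_frame().round(2))
```

Output (brachytherapy-only scope shown; full table also carries the
BT+EBRT scope and the pairwise difference columns):

```
     scope    organ  volume_cm3  addition  intensity  hybrid
   BT_only   rectum         0.1     15.17      15.14   15.13
   BT_only   rectum         1.0     12.02      12.05   12.02
   BT_only   rectum         2.0     10.69      10.79   10.80
   BT_only  bladder         0.1     16.67      15.69   16.16
   BT_only  bladder         1.0     12.49      11.80   12.10
   BT_only  bladder         2.0     10.13       9.60    9.75
```

Reading: values are accumulated D_x cm³ in Gy_EQD2 over the four 6 Gy
BT fractions. For the bladder — whose filling changes most between
fractions — DVH parameter addition reports up to ~1 Gy more than
DIR-based accumulation at D_0.1 cm³, because the per-fraction hotspots
do not coincide exactly; the gap shrinks toward D_2 cm³. The per-frame
registration accuracy table is in `report.dsc`.

A command-line interface mirrors the stages on case directories:

```bash
dirdose generate --out case1 --seed 1
dirdose register --case case1 --out case1/reg
dirdose report   --case case1 --out case1/report
```

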