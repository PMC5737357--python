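"""Synthetic pelvic phantom cases with known ground-truth deformations.

A *case* emulates one course of combined radiotherapy for cervical cancer:

* a reference CT frame acquired at the first brachytherapy (BT) session,
  with the intracavitary applicator in place;
* further BT frames whose bladder/rectum filling differs between sessions;
* one external-beam (EBRT) frame without the applicator, in a different
  setup pose, with the uterus relaxed because nothing distends the canal;
* per-plan dose grids: a 4-field-box whole-pelvis (WP) dose, an AP/PA
  centre-shielded (CS) dose with a midline block, and inverse-square BT
  dwell doses normalised so that HR-CTV D90 equals the per-fraction
  prescription.

Every deformed frame stores the exact displacement field that generated
it (pull-back convention on the frame grid: ``frame(x) = ref(x + g(x))``),
so registration error can be measured against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import (
    HU_MAX,
    HU_MIN,
    DisplacementField,
    Grid,
    RigidTransform,
    ScalarVolume,
    StructureSet,
    read_field,
    read_structures,
    read_volume,
    write_field,
    write_structures,
    write_volume,
)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, HU assignments and grid of the reference phantom.

    All positions/lengths are world millimetres on a 240×240×160 mm domain
    (96×96×64 voxels at 2.5 mm isotropic by default).  Anatomy follows the
    pelvic layout the analysis assumes: bladder anterior to the uterus,
    rectum posterior, applicator tandem running through the uterine canal.
    """

    shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    body_center: tuple[float, float] = (120.0, 120.0)
    body_semi: tuple[float, float] = (105.0, 85.0)
    uterus_center: tuple[float, float, float] = (120.0, 116.0, 95.0)
    uterus_semi: tuple[float, float, float] = (22.0, 24.0, 42.0)
    # bladder kept within the 40 mm midline block (x extent ±16 mm): the
    # centre-shielded fields must fully block the high-BT-dose organ zone
    bladder_center: tuple[float, float, float] = (120.0, 66.0, 62.0)
    bladder_semi: tuple[float, float, float] = (16.0, 24.0, 26.0)
    rectum_center_xy: tuple[float, float] = (120.0, 158.0)
    rectum_radius: float = 14.0
    rectum_z: tuple[float, float] = (15.0, 110.0)
    hrctv_center: tuple[float, float, float] = (120.0, 116.0, 62.0)
    hrctv_semi: tuple[float, float, float] = (18.0, 20.0, 22.0)
    applicator_xy: tuple[float, float] = (120.0, 116.0)
    applicator_radius: float = 3.5
    applicator_z: tuple[float, float] = (8.0, 95.0)

    hu_body: float = 25.0
    hu_uterus: float = 70.0
    hu_bladder: float = -15.0
    hu_rectum: float = -80.0
    hu_applicator: float = 2500.0

    smooth_sigma_vox: float = 0.8
    noise_hu: float = 6.0
    seed: int = 0

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, self.spacing, self.origin)


@dataclass(frozen=True)
class DeformationSpec:
    """Ground-truth deformation parameters for the non-reference frames.

    ``push_mm`` is the peak radial displacement around the applicator axis
    (the uterus relaxes inward once the tandem is removed, so the EBRT
    frame differs from the reference by this push); the per-fraction scale
    factors model inter-session bladder/rectum filling.  The EBRT frame
    additionally carries a rigid setup offset.  A small seeded jitter makes
    each case individual while staying deterministic.
    """

    push_mm: float = 8.0
    push_falloff_mm: float = 25.0
    bladder_scales: tuple[float, ...] = (1.15, 0.85, 1.10)
    rectum_scales: tuple[float, ...] = (0.90, 1.12, 1.05)
    ebrt_bladder_scale: float = 1.25
    ebrt_rectum_scale: float = 1.10
    ebrt_rotation_deg: tuple[float, float, float] = (0.0, 0.0, 3.0)
    ebrt_translation_mm: tuple[float, float, float] = (5.0, 0.0, 0.0)
    scale_jitter_sd: float = 0.03
    pose_jitter_mm: float = 1.0
    pose_jitter_deg: float = 0.5
    field_smooth_vox: float = 1.5
    seed: int = 0


@dataclass(frozen=True)
class PlanPrescription:
    label: str
    frame: str
    total_gy: float
    n_fractions: int
    include_in_addition: bool = True


@dataclass(frozen=True)
class CourseManifest:
    """Treatment course: WP + CS external beam and weekly HDR BT fractions."""

    wp_total_gy: float = 30.0
    wp_fractions: int = 15
    cs_total_gy: float = 20.0
    cs_fractions: int = 10
    cs_block_width_mm: float = 40.0
    cs_transmission: float = 0.0
    bt_fractions: int = 4
    bt_prescription_gy: float = 6.0
    alpha_beta_gy: float = 3.0

    def __post_init__(self) -> None:
        if self.bt_fractions < 1:
            raise ValueError("at least one BT fraction is required")

    @property
    def ebrt_total_gy(self) -> float:
        return self.wp_total_gy + self.cs_total_gy

    def plans(self) -> list[PlanPrescription]:
        out = [
            PlanPrescription("WP", "ebrt", self.wp_total_gy, self.wp_fractions),
            PlanPrescription(
                "CS", "ebrt", self.cs_total_gy, self.cs_fractions,
                include_in_addition=False,
            ),
        ]
        for i in range(1, self.bt_fractions + 1):
            out.append(
                PlanPrescription(f"BT{i}", f"bt{i}", self.bt_prescription_gy, 1)
            )
        return out


@dataclass
class Frame:
    """One imaging session: CT, structures and (if deformed) the exact field."""

    name: str
    ct: ScalarVolume
    structures: StructureSet
    gt_field: DisplacementField | None = None


# ---------------------------------------------------------------------------
# geometry rasterisation
# ---------------------------------------------------------------------------


def _ellipsoid(mesh, center, semi) -> np.ndarray:
    d = sum(((mesh[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return d <= 1.0


def _masks_from_spec(spec: PhantomSpec, mesh) -> dict[str, np.ndarray]:
    x, y, z = mesh
    body = (
        ((x - spec.body_center[0]) / spec.body_semi[0]) ** 2
        + ((y - spec.body_center[1]) / spec.body_semi[1]) ** 2
    ) <= 1.0
    uterus = _ellipsoid(mesh, spec.uterus_center, spec.uterus_semi)
    bladder = _ellipsoid(mesh, spec.bladder_center, spec.bladder_semi)
    rectum = (
        ((x - spec.rectum_center_xy[0]) ** 2 + (y - spec.rectum_center_xy[1]) ** 2)
        <= spec.rectum_radius**2
    ) & (z >= spec.rectum_z[0]) & (z <= spec.rectum_z[1])
    hrctv = _ellipsoid(mesh, spec.hrctv_center, spec.hrctv_semi)
    applicator = (
        ((x - spec.applicator_xy[0]) ** 2 + (y - spec.applicator_xy[1]) ** 2)
        <= spec.applicator_radius**2
    ) & (z >= spec.applicator_z[0]) & (z <= spec.applicator_z[1])

    masks = {
        "body": body,
        "uterus": uterus & body,
        "bladder": bladder & body,
        "rectum": rectum & body,
        "hrctv": hrctv & body,
        "applicator": applicator & body,
    }
    # the spec must not imply overlapping organs; reject rather than carve
    for a, b in (("uterus", "bladder"), ("uterus", "rectum"), ("bladder", "rectum")):
        n = int(np.count_nonzero(masks[a] & masks[b]))
        if n:
            raise ValueError(
                f"phantom spec implies overlap between {a} and {b} ({n} voxels)"
            )
    return masks


def _smooth_hu(spec: PhantomSpec, masks: dict[str, np.ndarray],
               with_applicator: bool) -> np.ndarray:
    hu = np.full(spec.shape, -1000.0, dtype=np.float32)
    hu[masks["body"]] = spec.hu_body
    hu[masks["uterus"]] = spec.hu_uterus
    hu[masks["bladder"]] = spec.hu_bladder
    hu[masks["rectum"]] = spec.hu_rectum
    if with_applicator:
        hu[masks["applicator"]] = spec.hu_applicator
    return ndimage.gaussian_filter(hu, spec.smooth_sigma_vox)


def _add_noise(hu: np.ndarray, spec: PhantomSpec, noise_seed: int) -> np.ndarray:
    rng = np.random.default_rng(noise_seed)
    noisy = hu + rng.normal(0.0, spec.noise_hu, size=hu.shape).astype(np.float32)
    return np.clip(noisy, HU_MIN, HU_MAX)


def generate_reference_case(spec: PhantomSpec) -> tuple[ScalarVolume, StructureSet]:
    """Build the reference BT1 frame: CT with applicator + structure set."""
    grid = spec.grid
    mesh = grid.world_mesh(dtype=np.float32)
    masks = _masks_from_spec(spec, mesh)
    hu = _add_noise(_smooth_hu(spec, masks, with_applicator=True), spec, spec.seed)
    return ScalarVolume(hu, grid), StructureSet(masks, grid)


# ---------------------------------------------------------------------------
# ground-truth deformations
# ---------------------------------------------------------------------------


def _filling_field(mesh, center, semi, scale: float) -> np.ndarray:
    """Pull-back field that rescales an organ about its centre by ``scale``.

    ``g(x) = (1/s - 1)(x - c) w(x)`` with a Gaussian window normalised to
    the organ's semi-axes, so warping the reference mask with ``g`` grows
    the organ for ``s > 1`` and shrinks it for ``s < 1``.
    """
    if scale <= 0:
        raise ValueError("filling scale must be positive")
    k = 1.4  # window reaches ~0.77 at the organ surface
    rho2 = sum(((mesh[a] - center[a]) / (k * semi[a])) ** 2 for a in range(3))
    w = np.exp(-0.5 * rho2)
    coef = (1.0 / scale - 1.0)
    out = np.empty(mesh[0].shape + (3,), dtype=np.float32)
    for a in range(3):
        out[..., a] = coef * (mesh[a] - center[a]) * w
    return out


def _applicator_push_field(mesh, spec: PhantomSpec, amplitude: float,
                           falloff: float) -> np.ndarray:
    """Radial push away from the applicator axis with Gaussian falloff.

    Profile ``p(r) = A (r/ρ) exp((1 - (r/ρ)²)/2)`` peaks at ``r = ρ`` with
    value ``A`` and vanishes smoothly at the axis; ``|p'| ≤ A/ρ < 1`` keeps
    the radial map monotone (invertible) whenever ``A < ρ``.
    """
    ax, ay = spec.applicator_xy
    x, y, z = mesh
    dx = x - ax
    dy = y - ay
    r = np.sqrt(dx * dx + dy * dy)
    s = r / falloff
    p = amplitude * s * np.exp(0.5 * (1.0 - s * s))
    z0, z1 = spec.applicator_z
    wz = 1.0 / (1.0 + np.exp(-(z - (z0 - 10.0)) / 8.0))
    wz *= 1.0 / (1.0 + np.exp((z - (z1 + 15.0)) / 8.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(r > 1e-6, p * dx / r, 0.0) * wz
        uy = np.where(r > 1e-6, p * dy / r, 0.0) * wz
    out = np.zeros(x.shape + (3,), dtype=np.float32)
    out[..., 0] = ux
    out[..., 1] = uy
    return out


def map_jacobian_det(field: DisplacementField) -> np.ndarray:
    """Determinant of the discrete Jacobian of ``x ↦ x + g(x)``."""
    g = field.offsets.astype(np.float64)
    sp = field.grid.spacing
    J = np.empty(g.shape[:3] + (3, 3))
    for comp in range(3):
        for ax in range(3):
            J[..., comp, ax] = np.gradient(g[..., comp], sp[ax], axis=ax)
        J[..., comp, comp] += 1.0
    return np.linalg.det(J)


def invert_field(field: DisplacementField, iterations: int = 20) -> DisplacementField:
    """Fixed-point inverse of ``x ↦ x + g(x)`` on the same grid."""
    from .grids import warp_volume  # local import to avoid cycle noise

    grid = field.grid
    inv = -field.offsets.copy()
    for _ in range(iterations):
        sampled = np.empty_like(inv)
        probe = DisplacementField(inv, grid)
        for a in range(3):
            comp = ScalarVolume(field.offsets[..., a], grid)
            sampled[..., a] = warp_volume(comp, probe, mode="linear").values
        inv = -sampled
    return DisplacementField(inv, grid)


def generate_deformed_frame(
    spec: PhantomSpec,
    deformation: DeformationSpec,
    kind: str,
    frame_index: int = 1,
) -> Frame:
    """Create a deformed frame plus the exact field that generated it.

    ``kind='BT_fraction'`` applies only organ-filling changes (applicator
    stays in place); ``kind='EBRT'`` removes the applicator, relaxes the
    anatomy inward around the canal and applies the rigid setup offset.
    ``frame_index`` selects the per-fraction filling scales (1-based).
    """
    if kind not in ("BT_fraction", "EBRT"):
        raise ValueError(f"unknown frame kind '{kind}'")
    grid = spec.grid
    mesh = grid.world_mesh(dtype=np.float32)
    masks = _masks_from_spec(spec, mesh)
    rng = np.random.default_rng(
        np.random.SeedSequence([deformation.seed, frame_index, kind == "EBRT"])
    )

    def jitter(v: float) -> float:
        if deformation.scale_jitter_sd <= 0:
            return v
        return float(v * (1.0 + rng.normal(0.0, deformation.scale_jitter_sd)))

    if kind == "BT_fraction":
        i = max(frame_index - 2, 0)  # bt2 is the first deformed BT frame
        b_scale = jitter(deformation.bladder_scales[i % len(deformation.bladder_scales)])
        r_scale = jitter(deformation.rectum_scales[i % len(deformation.rectum_scales)])
        push = 0.0
        pose = RigidTransform()
    else:
        b_scale = jitter(deformation.ebrt_bladder_scale)
        r_scale = jitter(deformation.ebrt_rectum_scale)
        push = deformation.push_mm
        rot = np.asarray(deformation.ebrt_rotation_deg) + rng.normal(
            0.0, deformation.pose_jitter_deg, 3
        )
        tra = np.asarray(deformation.ebrt_translation_mm) + rng.normal(
            0.0, deformation.pose_jitter_mm, 3
        )
        center = tuple(np.asarray(grid.origin)
                       + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing) / 2.0)
        pose = RigidTransform(tuple(rot), tuple(tra), center)

    # deformable part, defined in reference coordinates
    g_def = np.zeros(tuple(grid.shape) + (3,), dtype=np.float32)
    rect_cz = 0.5 * (spec.rectum_z[0] + spec.rectum_z[1])
    rect_center = (*spec.rectum_center_xy, rect_cz)
    rect_semi = (spec.rectum_radius, spec.rectum_radius,
                 0.5 * (spec.rectum_z[1] - spec.rectum_z[0]))
    g_def += _filling_field(mesh, spec.bladder_center, spec.bladder_semi, b_scale)
    g_def += _filling_field(mesh, rect_center, rect_semi, r_scale)
    if push:
        g_def += _applicator_push_field(mesh, spec, push, deformation.push_falloff_mm)
    if deformation.field_smooth_vox > 0:
        for a in range(3):
            g_def[..., a] = ndimage.gaussian_filter(
                g_def[..., a], deformation.field_smooth_vox
            )

    # total pull-back map m(x) = m_def(m_rigid(x)); g = m - x
    if pose.is_identity:
        g_total = g_def
    else:
        pts = np.stack([m.ravel() for m in mesh], axis=-1).astype(np.float64)
        mid = pose.apply_points(pts)
        sampled = np.empty_like(g_def)
        # clamped (nearest) sampling: the deformable field extends smoothly
        # past the domain edge, keeping the composed map invertible there
        coords = [
            (mid[:, a].reshape(grid.shape) - grid.origin[a]) / grid.spacing[a]
            for a in range(3)
        ]
        for a in range(3):
            sampled[..., a] = ndimage.map_coordinates(
                g_def[..., a], coords, order=1, mode="nearest", prefilter=False
            )
        g_total = (mid - pts).reshape(g_def.shape).astype(np.float32) + sampled

    gt = DisplacementField(g_total, grid)
    detj = map_jacobian_det(gt)
    if np.any(detj <= 0):
        raise ValueError(
            f"deformation amplitude (push={push} mm, scales={b_scale:.2f}/"
            f"{r_scale:.2f}) produces a non-invertible field "
            f"(min |J| = {detj.min():.3f})"
        )

    from .grids import warp_volume

    smooth = _smooth_hu(spec, masks, with_applicator=(kind == "BT_fraction"))
    warped_hu = warp_volume(ScalarVolume(smooth, grid), gt, fill=-1000.0).values
    noise_seed = int(
        np.random.SeedSequence([spec.seed, 7919, frame_index, kind == "EBRT"])
        .generate_state(1)[0] % (2**31)
    )
    ct = ScalarVolume(_add_noise(warped_hu, spec, noise_seed), grid)

    new_masks = {}
    for name, mask in masks.items():
        if kind == "EBRT" and name == "applicator":
            new_masks[name] = np.zeros(grid.shape, dtype=bool)
            continue
        w = warp_volume(ScalarVolume(mask.astype(np.float32), grid), gt).values
        new_masks[name] = w >= 0.5
    structs = StructureSet(new_masks, grid, validate=False)
    return Frame(f"{kind.lower()}{frame_index}", ct, structs, gt)


# ---------------------------------------------------------------------------
# dose simulation
# ---------------------------------------------------------------------------


def dwell_positions(spec: PhantomSpec, n_dwells: int = 6,
                    z_range: tuple[float, float] = (55.0, 85.0)) -> np.ndarray:
    """Dwell positions along the tandem axis (world mm)."""
    z = np.linspace(z_range[0], z_range[1], n_dwells)
    ax, ay = spec.applicator_xy
    return np.stack([np.full(n_dwells, ax), np.full(n_dwells, ay), z], axis=-1)


def simulate_bt_dose(
    frame: Frame,
    dwells: np.ndarray,
    prescription_gy: float = 6.0,
) -> ScalarVolume:
    """Inverse-square dwell-sum BT dose, normalised to HR-CTV D90.

    ``dose(x) = S Σ_i (r₀ / r_i)²`` with ``r₀ = 10 mm`` and ``r_i`` the
    distance to dwell *i*, floored at half the voxel diagonal; ``S`` is
    chosen so the frame's HR-CTV D90 equals the prescription exactly
    (the metric is linear in the dose scale).
    """
    from .dvh import d90 as _d90

    if "applicator" not in frame.structures or not frame.structures["applicator"].any():
        raise ValueError("BT dose requires an applicator in the frame")
    if "hrctv" not in frame.structures or not frame.structures["hrctv"].any():
        raise ValueError("empty HR-CTV mask; cannot normalise the BT dose")
    dwells = np.atleast_2d(np.asarray(dwells, dtype=np.float64))
    if dwells.shape[0] < 1:
        raise ValueError("at least one dwell position is required")
    grid = frame.ct.grid
    mesh = grid.world_mesh(dtype=np.float32)
    r0 = 10.0
    r_floor = 0.5 * float(np.linalg.norm(grid.spacing))
    dose = np.zeros(grid.shape, dtype=np.float64)
    for dw in dwells:
        r2 = ((mesh[0] - dw[0]) ** 2 + (mesh[1] - dw[1]) ** 2
              + (mesh[2] - dw[2]) ** 2)
        r2 = np.maximum(r2, r_floor**2)
        dose += (r0**2) / r2
    vol = ScalarVolume(dose, grid)
    d90_raw = _d90(vol, frame.structures["hrctv"])
    scale = prescription_gy / d90_raw
    return ScalarVolume((dose * scale).astype(np.float32), grid)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _edge_profile(coord: np.ndarray, lo: float, hi: float, half_width: float) -> np.ndarray:
    """1 well inside [lo, hi], 0 well outside, cubic transition of ±half_width."""
    rise = _smoothstep((coord - (lo - half_width)) / (2.0 * half_width))
    fall = _smoothstep(((hi + half_width) - coord) / (2.0 * half_width))
    return rise * fall


def _field_box(frame: Frame, margin_mm: float = 15.0) -> list[tuple[float, float]]:
    body = frame.structures["body"]
    if not body.any():
        raise ValueError("body mask is required to place EBRT fields")
    grid = frame.ct.grid
    box = []
    for a in range(3):
        idx = np.where(body.any(axis=tuple(i for i in range(3) if i != a)))[0]
        lo = grid.origin[a] + idx[0] * grid.spacing[a] + margin_mm
        hi = grid.origin[a] + idx[-1] * grid.spacing[a] - margin_mm
        if hi <= lo:
            raise ValueError("EBRT field box collapsed outside the body")
        box.append((float(lo), float(hi)))
    return box


def simulate_ebrt_wp(
    frame: Frame,
    total_gy: float = 30.0,
    penumbra_mm: float = 3.0,
    margin_mm: float = 15.0,
) -> ScalarVolume:
    """4-field-box whole-pelvis dose: flat ``total_gy`` inside the box.

    The box is the body bounding box shrunk by ``margin_mm`` per side;
    edges roll off over a compact ±``penumbra_mm`` cubic transition, so the
    dose is exactly ``total_gy`` more than ``penumbra_mm`` inside the box
    and exactly zero more than ``penumbra_mm`` outside.
    """
    grid = frame.ct.grid
    box = _field_box(frame, margin_mm)
    mesh = grid.world_mesh(dtype=np.float32)
    prof = np.ones(grid.shape, dtype=np.float32)
    for a in range(3):
        prof *= _edge_profile(mesh[a], box[a][0], box[a][1], penumbra_mm)
    return ScalarVolume((total_gy * prof).astype(np.float32), grid)


def simulate_ebrt_cs(
    frame: Frame,
    total_gy: float = 20.0,
    block_width_mm: float = 40.0,
    transmission: float = 0.0,
    penumbra_mm: float = 3.0,
    margin_mm: float = 15.0,
) -> ScalarVolume:
    """AP/PA centre-shielded dose with a midline block.

    The central left–right strip of ``block_width_mm`` (full height, at the
    body midline) is reduced to ``transmission * total_gy``; outside the
    strip the dose behaves like the WP box.
    """
    if block_width_mm <= 0:
        raise ValueError("block width must be positive")
    grid = frame.ct.grid
    box = _field_box(frame, margin_mm)
    if block_width_mm >= (box[0][1] - box[0][0]):
        raise ValueError("midline block is wider than the field")
    mesh = grid.world_mesh(dtype=np.float32)
    prof = np.ones(grid.shape, dtype=np.float32)
    for a in range(3):
        prof *= _edge_profile(mesh[a], box[a][0], box[a][1], penumbra_mm)
    body = frame.structures["body"]
    com = ndimage.center_of_mass(body)
    mid_x = grid.origin[0] + com[0] * grid.spacing[0]
    half = block_width_mm / 2.0
    in_block = _edge_profile(mesh[0], mid_x - half, mid_x + half, penumbra_mm)
    factor = 1.0 - (1.0 - transmission) * in_block
    return ScalarVolume((total_gy * prof * factor).astype(np.float32), grid)


# ---------------------------------------------------------------------------
# whole-case assembly and case-directory I/O
# ---------------------------------------------------------------------------


@dataclass
class Case:
    """A complete synthetic course: frames, per-plan doses and the manifest."""

    frames: dict[str, Frame]
    doses: dict[str, ScalarVolume]  # plan label -> physical dose on its frame
    manifest: CourseManifest
    reference: str = "bt1"

    def plan_frame(self, label: str) -> Frame:
        plan = {p.label: p for p in self.manifest.plans()}[label]
        return self.frames[plan.frame]


def generate_case(
    spec: PhantomSpec | None = None,
    deformation: DeformationSpec | None = None,
    manifest: CourseManifest | None = None,
    seed: int | None = None,
    with_doses: bool = True,
) -> Case:
    """Generate a full synthetic course.

    ``seed`` (if given) overrides both the phantom and deformation seeds so
    a single integer reproduces the whole case.  ``with_doses=False`` skips
    the dose simulation (enough for registration-only studies).
    """
    spec = spec or PhantomSpec()
    deformation = deformation or DeformationSpec()
    manifest = manifest or CourseManifest()
    if seed is not None:
        spec = replace(spec, seed=int(seed))
        deformation = replace(deformation, seed=int(seed))

    ct, structs = generate_reference_case(spec)
    frames: dict[str, Frame] = {"bt1": Frame("bt1", ct, structs, None)}
    for i in range(2, manifest.bt_fractions + 1):
        f = generate_deformed_frame(spec, deformation, "BT_fraction", frame_index=i)
        f.name = f"bt{i}"
        frames[f.name] = f
    ebrt = generate_deformed_frame(spec, deformation, "EBRT", frame_index=1)
    ebrt.name = "ebrt"
    frames["ebrt"] = ebrt

    doses: dict[str, ScalarVolume] = {}
    if not with_doses:
        return Case(frames, doses, manifest)
    dwells = dwell_positions(spec)
    for plan in manifest.plans():
        frame = frames[plan.frame]
        if plan.label == "WP":
            doses[plan.label] = simulate_ebrt_wp(frame, plan.total_gy)
        elif plan.label == "CS":
            doses[plan.label] = simulate_ebrt_cs(
                frame,
                plan.total_gy,
                block_width_mm=manifest.cs_block_width_mm,
                transmission=manifest.cs_transmission,
            )
        else:
            doses[plan.label] = simulate_bt_dose(
                frame, dwells, prescription_gy=plan.total_gy
            )
    return Case(frames, doses, manifest)


def degenerate_case(
    spec: PhantomSpec | None = None,
    manifest: CourseManifest | None = None,
) -> Case:
    """Zero-deformation limit: every frame is a copy of the reference.

    In this limit the most exposed subvolumes coincide exactly across
    plans, so DIR-based accumulation and DVH parameter addition must agree
    — the regime in which the co-located-hotspot assumption behind DVH
    addition is exact.
    """
    spec = spec or PhantomSpec()
    manifest = manifest or CourseManifest()
    ct, structs = generate_reference_case(spec)
    frames = {"bt1": Frame("bt1", ct, structs, None)}
    for i in range(2, manifest.bt_fractions + 1):
        frames[f"bt{i}"] = Frame(f"bt{i}", ct.copy(), structs.copy(), None)
    frames["ebrt"] = Frame("ebrt", ct.copy(), structs.copy(), None)
    dwells = dwell_positions(spec)
    doses: dict[str, ScalarVolume] = {}
    for plan in manifest.plans():
        frame = frames[plan.frame]
        if plan.label == "WP":
            doses[plan.label] = simulate_ebrt_wp(frame, plan.total_gy)
        elif plan.label == "CS":
            doses[plan.label] = simulate_ebrt_cs(
                frame, plan.total_gy,
                block_width_mm=manifest.cs_block_width_mm,
                transmission=manifest.cs_transmission,
            )
        else:
            doses[plan.label] = simulate_bt_dose(
                frame, dwells, prescription_gy=plan.total_gy
            )
    return Case(frames, doses, manifest)


def save_case(case: Case, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, frame in case.frames.items():
        fdir = directory / "frames" / name
        write_volume(frame.ct, fdir / "ct.nii.gz")
        write_structures(frame.structures, fdir / "masks")
        if frame.gt_field is not None:
            write_field(frame.gt_field, fdir / "gt_field.nii.gz")
    for label, dose in case.doses.items():
        write_volume(dose, directory / "doses" / f"{label.lower()}.nii.gz")
    m = case.manifest
    manifest_json = {
        "reference": case.reference,
        "alpha_beta_gy": m.alpha_beta_gy,
        "course": {
            "wp_total_gy": m.wp_total_gy,
            "wp_fractions": m.wp_fractions,
            "cs_total_gy": m.cs_total_gy,
            "cs_fractions": m.cs_fractions,
            "cs_block_width_mm": m.cs_block_width_mm,
            "cs_transmission": m.cs_transmission,
            "bt_fractions": m.bt_fractions,
            "bt_prescription_gy": m.bt_prescription_gy,
        },
        "plans": [
            {
                "label": p.label,
                "frame": p.frame,
                "total_gy": p.total_gy,
                "n_fractions": p.n_fractions,
                "include_in_addition": p.include_in_addition,
                "dose": f"doses/{p.label.lower()}.nii.gz",
            }
            for p in m.plans()
        ],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest_json, indent=1))


def load_case(directory: str | Path) -> Case:
    directory = Path(directory)
    manifest_json = json.loads((directory / "manifest.json").read_text())
    c = manifest_json["course"]
    manifest = CourseManifest(
        wp_total_gy=c["wp_total_gy"],
        wp_fractions=c["wp_fractions"],
        cs_total_gy=c["cs_total_gy"],
        cs_fractions=c["cs_fractions"],
        cs_block_width_mm=c["cs_block_width_mm"],
        cs_transmission=c["cs_transmission"],
        bt_fractions=c["bt_fractions"],
        bt_prescription_gy=c["bt_prescription_gy"],
        alpha_beta_gy=manifest_json["alpha_beta_gy"],
    )
    frames = {}
    for fdir in sorted((directory / "frames").iterdir()):
        name = fdir.name
        ct = read_volume(fdir / "ct.nii.gz")
        structs = read_structures(fdir / "masks", ct.grid)
        gt_path = fdir / "gt_field.nii.gz"
        gt = read_field(gt_path) if gt_path.exists() else None
        frames[name] = Frame(name, ct, structs, gt)
    doses = {}
    for p in manifest_json["plans"]:
        doses[p["label"]] = read_volume(directory / p["dose"])
    return Case(frames, doses, manifest, reference=manifest_json["reference"])
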