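"""Rigid fusion and deformable image registration (DIR) to the BT1 frame.

Two DIR parameter settings mirror the two clinical configurations:

* **intensity** mode drives the registration with CT intensities alone,
  restricted to the body contour (the only structure used);
* **hybrid** mode adds a structure-overlap term for uterus, rectum,
  bladder and body, combining intensity and anatomical information.

Both minimise one documented energy on a dense displacement field ``u``
(pull-back convention, defined on the fixed/reference grid)::

    E(u) = w_img * S_img(u) + w_struct * S_struct(u) + w_reg * R(u)

with ``S_img = 1 - mean local normalized cross-correlation`` of HU inside
the body, ``S_struct = mean over structures of (1 - soft Dice)`` between
the warped moving and fixed probability maps (squared-denominator form,
``2Σpq/(Σp²+Σq²)``, which is exactly 1 at a perfect match), and ``R`` the
discrete bending energy (squared Laplacian) of ``u``.  Optimisation is a
multi-resolution Gaussian-smoothed gradient descent with a backtracking
accept test, so the objective is non-increasing across iterations at each
pyramid level, and fully deterministic (zero-field initialisation, fixed
iteration counts, no randomness).

This is the package's own class surrogate for commercial hybrid DIR: the
two settings differ purely in ``w_struct = 0`` versus ``w_struct > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .grids import (
    HU_AIR,
    DisplacementField,
    Grid,
    RigidTransform,
    ScalarVolume,
    StructureSet,
    warp_volume,
)

HYBRID_STRUCTURES = ("uterus", "rectum", "bladder", "body")


@dataclass(frozen=True)
class DirConfig:
    """Parameters of one DIR setting.

    ``w_struct`` is forced to zero in intensity mode.  Iteration counts are
    per pyramid level (coarse → fine); ``downsample`` gives the level
    factors.  ``smooth_sigma_vox`` is the Gaussian width applied to the
    update field each iteration (a smoothness preconditioner),
    ``lncc_sigma_vox`` the window of the local correlation.
    """

    mode: str = "hybrid"  # {"intensity", "hybrid"}
    w_img: float = 1.0
    w_struct: float = 1.0
    w_reg: float = 1.0
    downsample: tuple[int, ...] = (4, 2, 1)
    iterations: tuple[int, ...] = (80, 40, 10)
    smooth_sigma_vox: float = 2.0
    lncc_sigma_vox: float = 3.0
    step_mm: float = 2.0
    max_backtracks: int = 4

    def __post_init__(self) -> None:
        if self.mode not in ("intensity", "hybrid"):
            raise ValueError(f"unknown DIR mode '{self.mode}'")
        if min(self.w_img, self.w_struct, self.w_reg) < 0:
            raise ValueError("weights must be non-negative")
        if len(self.downsample) != len(self.iterations):
            raise ValueError("one iteration count per pyramid level is required")
        if self.mode == "intensity" and self.w_struct != 0.0:
            object.__setattr__(self, "w_struct", 0.0)

    @property
    def structures(self) -> tuple[str, ...]:
        return ("body",) if self.mode == "intensity" else HYBRID_STRUCTURES


def intensity_config(**kw) -> DirConfig:
    kw.setdefault("mode", "intensity")
    kw.setdefault("w_struct", 0.0)
    return DirConfig(**kw)


def hybrid_config(**kw) -> DirConfig:
    kw.setdefault("mode", "hybrid")
    return DirConfig(**kw)


# ---------------------------------------------------------------------------
# basic operations
# ---------------------------------------------------------------------------


def replace_applicator_hu(ct: ScalarVolume, applicator: np.ndarray,
                          value: float = HU_AIR) -> ScalarVolume:
    """Replace CT values inside the applicator mask by −1000 HU.

    High-HU applicator voxels exist only on the BT frames; masking them to
    air removes a structure the moving EBRT frame cannot match.
    """
    applicator = np.asarray(applicator, dtype=bool)
    if applicator.shape != ct.values.shape:
        raise ValueError("applicator mask grid does not match the CT grid")
    out = ct.values.copy()
    out[applicator] = value
    return ScalarVolume(out, ct.grid)


def dice(deformed: np.ndarray, reference: np.ndarray) -> float:
    """Dice similarity coefficient ``|A∩B| / ((|A|+|B|)/2)`` by voxel count."""
    a = np.asarray(deformed, dtype=bool)
    b = np.asarray(reference, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise ValueError("DSC is undefined for two empty masks")
    inter = int(np.count_nonzero(a & b))
    return 2.0 * inter / (na + nb)


def warp_mask(mask: np.ndarray, field: DisplacementField,
              grid: Grid | None = None) -> np.ndarray:
    """Warp a binary mask: linear interpolation then threshold at 0.5."""
    mask = np.asarray(mask)
    grid = grid or field.grid
    if tuple(mask.shape) != tuple(grid.shape):
        raise ValueError("mask shape does not match its grid")
    warped = warp_volume(ScalarVolume(mask.astype(np.float32), grid), field,
                         mode="linear", fill=0.0)
    return warped.values >= 0.5


# ---------------------------------------------------------------------------
# rigid fusion
# ---------------------------------------------------------------------------


def _mask_centroid(mask: np.ndarray, grid: Grid) -> np.ndarray:
    com = np.asarray(ndimage.center_of_mass(mask))
    return np.asarray(grid.origin) + com * np.asarray(grid.spacing)


def _crop_bbox(masks: list[np.ndarray], grid: Grid, margin_mm: float = 30.0):
    union = np.zeros(grid.shape, dtype=bool)
    for m in masks:
        union |= m
    idx = np.where(union)
    slices, origin = [], []
    for a in range(3):
        pad = int(np.ceil(margin_mm / grid.spacing[a]))
        lo = max(int(idx[a].min()) - pad, 0)
        hi = min(int(idx[a].max()) + pad + 1, grid.shape[a])
        slices.append(slice(lo, hi))
        origin.append(grid.origin[a] + lo * grid.spacing[a])
    sub = Grid(tuple(s.stop - s.start for s in slices), grid.spacing, tuple(origin))
    return tuple(slices), sub


def rigid_register(
    moving: StructureSet,
    fixed: StructureSet,
    match_on: str = "uterus",
    max_translation_mm: float = 20.0,
    max_rotation_deg: float = 15.0,
) -> RigidTransform:
    """Rigid fusion maximising overlap of the ``match_on`` structure.

    The search is seeded by centroid alignment and refined by Powell
    minimisation of a soft (Gaussian-smoothed) Dice objective inside the
    stated bounds; the returned transform never scores a lower hard DSC
    than the identity.  This automates the clinical manual shift-and-rotate
    fusion step, which has no published parameters to copy.
    """
    for ss, tag in ((moving, "moving"), (fixed, "fixed")):
        if match_on not in ss or not ss[match_on].any():
            raise ValueError(f"structure '{match_on}' empty or missing in {tag} set")
    grid = fixed.grid
    mov = moving[match_on]
    fix = fixed[match_on]
    slices, sub = _crop_bbox([mov, fix], grid)
    mov_c = mov[slices].astype(np.float32)
    fix_c = fix[slices].astype(np.float32)
    fix_s = ndimage.gaussian_filter(fix_c, 1.5)
    mov_vol = ScalarVolume(ndimage.gaussian_filter(mov_c, 1.5), sub)

    center = _mask_centroid(mov, grid)
    t0 = _mask_centroid(fix, grid) - center
    t0 = np.clip(t0, -max_translation_mm, max_translation_mm)

    mesh = sub.world_mesh(dtype=np.float64)
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    sum_fix = float(fix_s.sum())

    def soft_neg_dice(params: np.ndarray) -> float:
        rot = np.clip(params[:3], -max_rotation_deg, max_rotation_deg)
        tra = np.clip(params[3:], -max_translation_mm, max_translation_mm)
        T = RigidTransform(tuple(rot), tuple(tra), tuple(center))
        src = T.inverse_points(pts)
        coords = [
            (src[:, a].reshape(sub.shape) - sub.origin[a]) / sub.spacing[a]
            for a in range(3)
        ]
        w = ndimage.map_coordinates(mov_vol.values, coords, order=1,
                                    mode="grid-constant", cval=0.0, prefilter=False)
        num = 2.0 * float((w * fix_s).sum())
        den = float(w.sum()) + sum_fix
        return -(num / (den + 1e-9))

    x0 = np.concatenate([np.zeros(3), t0])
    res = minimize(soft_neg_dice, x0, method="Powell",
                   options={"maxiter": 2000, "xtol": 0.05, "ftol": 1e-6})
    rot = np.clip(res.x[:3], -max_rotation_deg, max_rotation_deg)
    tra = np.clip(res.x[3:], -max_translation_mm, max_translation_mm)

    candidates = [
        RigidTransform(center_mm=tuple(center)),
        RigidTransform((0.0, 0.0, 0.0), tuple(t0), tuple(center)),
        RigidTransform(tuple(rot), tuple(tra), tuple(center)),
    ]
    from .grids import apply_rigid

    best, best_dsc = None, -1.0
    for T in candidates:
        warped = apply_rigid(
            ScalarVolume(mov_c, sub), T, mode="linear", fill=0.0
        ).values >= 0.5
        try:
            d = dice(warped, fix_c >= 0.5)
        except ValueError:
            d = 0.0
        if d > best_dsc + 1e-12:
            best, best_dsc = T, d
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# deformable registration
# ---------------------------------------------------------------------------


def _downsample(arr: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return arr.astype(np.float32, copy=True)
    sm = ndimage.gaussian_filter(arr.astype(np.float32), factor / 2.0)
    return ndimage.zoom(sm, 1.0 / factor, order=1, prefilter=False,
                        grid_mode=True, mode="nearest").astype(np.float32)


def _upsample_field(u: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    if u.shape[:3] == shape:
        return u
    out = np.empty(shape + (3,), dtype=np.float32)
    zoom = [shape[a] / u.shape[a] for a in range(3)]
    for c in range(3):
        out[..., c] = ndimage.zoom(u[..., c], zoom, order=1, prefilter=False,
                                   grid_mode=True, mode="nearest")
    return out


class _Level:
    """One pyramid level: images, probability maps and the energy terms."""

    def __init__(self, fixed: np.ndarray, moving: np.ndarray,
                 fixed_probs: dict[str, np.ndarray],
                 moving_probs: dict[str, np.ndarray],
                 body: np.ndarray, spacing: np.ndarray, config: DirConfig):
        self.f = fixed
        self.m = moving
        self.fp = fixed_probs
        self.mp = moving_probs
        self.body = body > 0.25
        self.n_body = max(int(self.body.sum()), 1)
        self.sp = spacing
        self.cfg = config
        self.sig = config.lncc_sigma_vox
        f = fixed
        self.mu_f = ndimage.gaussian_filter(f, self.sig, truncate=2.0)
        self.cf = f - self.mu_f
        self.B = ndimage.gaussian_filter(self.cf * self.cf, self.sig, truncate=2.0)
        idx = np.meshgrid(*[np.arange(n, dtype=np.float32) for n in f.shape],
                          indexing="ij")
        self.idx = idx
        self.sum_fp2 = {k: float((v * v).sum()) for k, v in fixed_probs.items()}
        self.eps = 1e-6

    def _coords(self, u: np.ndarray) -> list[np.ndarray]:
        return [self.idx[a] + u[..., a] / self.sp[a] for a in range(3)]

    def _warp(self, arr: np.ndarray, coords, cval: float) -> np.ndarray:
        return ndimage.map_coordinates(arr, coords, order=1, mode="grid-constant",
                                       cval=cval, prefilter=False)

    def energy_terms(self, u: np.ndarray):
        coords = self._coords(u)
        mw = self._warp(self.m, coords, HU_AIR)
        # local normalized cross-correlation inside the body
        mu_m = ndimage.gaussian_filter(mw, self.sig, truncate=2.0)
        cm = mw - mu_m
        A = ndimage.gaussian_filter(self.cf * cm, self.sig, truncate=2.0)
        C = ndimage.gaussian_filter(cm * cm, self.sig, truncate=2.0)
        denom = np.sqrt(self.B * C + self.eps)
        cc = A / denom
        s_img = 1.0 - float(cc[self.body].sum()) / self.n_body

        s_struct = 0.0
        warped_probs = {}
        if self.cfg.w_struct > 0:
            # squared-denominator soft Dice: exactly 1 when the warped and
            # fixed probability maps coincide, so a perfect match is a
            # stationary point even for non-binary maps
            for name, mp in self.mp.items():
                wp = self._warp(mp, coords, 0.0)
                warped_probs[name] = wp
                num = 2.0 * float((wp * self.fp[name]).sum())
                den = float((wp * wp).sum()) + self.sum_fp2[name] + self.eps
                s_struct += 1.0 - num / den
            s_struct /= len(self.mp)

        lap = np.empty_like(u)
        for c in range(3):
            lap[..., c] = ndimage.laplace(u[..., c])
        r = float(np.mean(lap**2))
        E = (self.cfg.w_img * s_img + self.cfg.w_struct * s_struct
             + self.cfg.w_reg * r)
        cache = (coords, mw, cm, A, C, denom, warped_probs, lap)
        return E, cache

    def gradient(self, u: np.ndarray, cache) -> np.ndarray:
        coords, mw, cm, A, C, denom, warped_probs, lap = cache
        g = np.zeros_like(u)
        grad_mw = np.gradient(mw, *self.sp)

        if self.cfg.w_img > 0:
            # d(1 - cc)/d m  ≈ -(cf - (A/C) cm) / sqrt(B C)   (local approx.)
            dccdm = (self.cf - (A / (C + self.eps)) * cm) / denom
            w = np.where(self.body, -dccdm / self.n_body, 0.0)
            for a in range(3):
                g[..., a] += self.cfg.w_img * w * grad_mw[a]

        if self.cfg.w_struct > 0:
            ns = len(self.mp)
            for name, mp in self.mp.items():
                wp = warped_probs[name]
                num = 2.0 * float((wp * self.fp[name]).sum())
                den = float((wp * wp).sum()) + self.sum_fp2[name] + self.eps
                # d(1 - dice)/d wp per voxel
                dd = -2.0 * (self.fp[name] * den - num * wp) / (den * den)
                gw = self._warp_gradient(mp, coords)
                for a in range(3):
                    g[..., a] += self.cfg.w_struct * dd * gw[a] / ns

        if self.cfg.w_reg > 0:
            n = lap[..., 0].size
            for c in range(3):
                g[..., c] += self.cfg.w_reg * 2.0 * ndimage.laplace(lap[..., c]) / n
        return g

    def _warp_gradient(self, arr: np.ndarray, coords) -> list[np.ndarray]:
        w = self._warp(arr, coords, 0.0)
        return np.gradient(w, *self.sp)


def deformable_register(
    moving_ct: ScalarVolume,
    fixed_ct: ScalarVolume,
    moving_structs: StructureSet,
    fixed_structs: StructureSet,
    config: DirConfig | None = None,
    log: list | None = None,
) -> DisplacementField:
    """Deformable registration of a rigidly pre-aligned frame to the reference.

    Both frames must live on the same (reference) grid and applicator HU
    must already be replaced on BT frames.  Returns the displacement field
    on the fixed grid (pull-back convention).  ``log`` (optional list)
    collects per-level objective traces.
    """
    config = config or DirConfig()
    if moving_ct.grid != fixed_ct.grid:
        raise ValueError("moving and fixed CT must share the reference grid")
    for name in config.structures:
        for ss, tag in ((moving_structs, "moving"), (fixed_structs, "fixed")):
            if name not in ss:
                raise ValueError(
                    f"{config.mode} mode requires structure '{name}' in the {tag} set"
                )

    grid = fixed_ct.grid
    spacing = np.asarray(grid.spacing, dtype=np.float64)
    f_full = fixed_ct.values.astype(np.float32)
    m_full = moving_ct.values.astype(np.float32)
    fprob_full = {n: fixed_structs[n].astype(np.float32) for n in config.structures}
    mprob_full = {n: moving_structs[n].astype(np.float32) for n in config.structures}
    body_full = fixed_structs["body"].astype(np.float32)

    u = None
    for li, (factor, iters) in enumerate(zip(config.downsample, config.iterations)):
        f = _downsample(f_full, factor)
        m = _downsample(m_full, factor)
        body = _downsample(body_full, factor)
        fp = {n: _downsample(v, factor) for n, v in fprob_full.items()}
        mp = {n: _downsample(v, factor) for n, v in mprob_full.items()}
        if config.w_struct > 0:
            # slight blur gives the Dice term a capture range beyond one voxel
            fp = {n: ndimage.gaussian_filter(v, 1.0) for n, v in fp.items()}
            mp = {n: ndimage.gaussian_filter(v, 1.0) for n, v in mp.items()}
        level = _Level(f, m, fp, mp, body, spacing * factor, config)

        u = (np.zeros(f.shape + (3,), dtype=np.float32) if u is None
             else _upsample_field(u, f.shape))
        E, cache = level.energy_terms(u)
        trace = [E]
        for _ in range(iters):
            if not np.isfinite(E):
                raise FloatingPointError(
                    f"non-finite DIR objective at level {li} ({factor}x)"
                )
            g = level.gradient(u, cache)
            for c in range(3):
                g[..., c] = ndimage.gaussian_filter(g[..., c],
                                                    config.smooth_sigma_vox,
                                                    truncate=2.0)
            gmax = float(np.abs(g).max())
            if gmax <= 0:
                break
            step = config.step_mm / gmax
            accepted = False
            for _ in range(config.max_backtracks + 1):
                u_try = u - np.float32(step) * g
                E_try, cache_try = level.energy_terms(u_try)
                if E_try < E:
                    u, E, cache = u_try, E_try, cache_try
                    accepted = True
                    break
                step *= 0.5
            trace.append(E)
            if not accepted:
                break
        if log is not None:
            log.append({"level": li, "factor": factor, "objective": trace})

    assert u is not None
    u = _upsample_field(u, tuple(grid.shape))
    return DisplacementField(u, grid)


# ---------------------------------------------------------------------------
# accuracy evaluation against ground truth
# ---------------------------------------------------------------------------


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boundary shell of a binary mask (mask minus its erosion)."""
    mask = np.asarray(mask, dtype=bool)
    return mask & ~ndimage.binary_erosion(mask)


def registration_tre(
    gt_field: DisplacementField,
    est_field: DisplacementField | None,
    rigid: RigidTransform | None,
    eval_mask: np.ndarray,
    gt_inverse: DisplacementField | None = None,
) -> float:
    """Mean target registration error (mm) at the given evaluation voxels.

    The ground-truth field ``g`` maps frame coordinates to reference
    coordinates (``frame(x) = ref(x + g(x))``).  The true correspondence of
    a reference point ``p`` is ``q = inv(x + g(x))(p)``; the estimate is
    ``F⁻¹(p + u(p))`` for rigid transform ``F`` and DIR field ``u``
    (``u = 0`` when evaluating rigid alignment alone).
    """
    from .phantom import invert_field

    grid = gt_field.grid
    inv = gt_inverse if gt_inverse is not None else invert_field(gt_field)
    mesh = grid.world_mesh(dtype=np.float64)
    sel = np.asarray(eval_mask, dtype=bool)
    p = np.stack([mesh[a][sel] for a in range(3)], axis=-1)
    q_true = p + np.stack([inv.offsets[..., a][sel] for a in range(3)], axis=-1)

    if est_field is not None:
        upts = np.stack([est_field.offsets[..., a][sel] for a in range(3)], axis=-1)
        moved = p + upts
    else:
        moved = p
    q_est = rigid.inverse_points(moved) if rigid is not None else moved
    return float(np.mean(np.linalg.norm(q_est - q_true, axis=-1)))
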