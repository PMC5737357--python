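"""End-to-end course pipeline and method-comparison reporting.

``run_course`` executes the full workflow on one case: rigid uterus
fusion → applicator HU replacement → deformable registration in both
settings → EQD2 conversion → dose warping → summation on the reference
frame → D_0.1/1/2 cm³ extraction, plus the DVH-parameter-addition
baseline, for two scopes (BT fractions alone, and BT + EBRT).

``registration_study`` runs the registration stage alone over several
seeded phantom cases and tabulates DSC and target registration error per
frame/structure/method — the synthetic counterpart of a cohort DIR
accuracy table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .accumulate import FractionPlan, accumulate, eqd2_convert
from .dvh import d_cc, dvh_parameter_addition
from .grids import (
    DisplacementField,
    RigidTransform,
    ScalarVolume,
    StructureSet,
    apply_rigid,
    read_field,
    write_field,
)
from .phantom import (
    Case,
    DeformationSpec,
    Frame,
    PhantomSpec,
    generate_case,
)
from .registration import (
    DirConfig,
    dice,
    deformable_register,
    hybrid_config,
    intensity_config,
    registration_tre,
    replace_applicator_hu,
    surface_voxels,
    warp_mask,
)

EVAL_STRUCTURES = ("uterus", "rectum", "bladder")
METRIC_VOLUMES_CM3 = (0.1, 1.0, 2.0)
SCOPES = ("BT_only", "BT_plus_EBRT")
DIFF_COLUMNS = (
    ("addition", "intensity"),
    ("addition", "hybrid"),
    ("hybrid", "intensity"),
)


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the full pipeline; DIR settings are per mode."""

    intensity: DirConfig = dc_field(default_factory=intensity_config)
    hybrid: DirConfig = dc_field(default_factory=hybrid_config)
    modes: tuple[str, ...] = ("intensity", "hybrid")
    metric_volumes_cm3: tuple[float, ...] = METRIC_VOLUMES_CM3
    accumulation_order: str = "eqd2_then_warp"
    rigid_match_on: str = "uterus"

    def dir_config(self, mode: str) -> DirConfig:
        if mode == "intensity":
            return self.intensity
        if mode == "hybrid":
            return self.hybrid
        raise ValueError(f"unknown DIR mode '{mode}'")


@dataclass
class FrameRegistration:
    """Registration products for one non-reference frame."""

    frame: str
    rigid: RigidTransform
    aligned_ct: ScalarVolume
    aligned_structs: StructureSet
    fields: dict[str, DisplacementField]
    dsc: dict[str, dict[str, float]]  # method -> structure -> DSC
    tre_mm: dict[str, float]  # method -> mean surface TRE (nan if no truth)


@dataclass
class AccumulationReport:
    """Machine twin of a per-case method-comparison table.

    ``metrics[scope][organ][volume][method]`` holds D_x cm³ in Gy_EQD2 for
    methods {addition, intensity, hybrid}; ``differences`` the pairwise
    columns; ``dsc`` the per-frame registration accuracy table.
    """

    metrics: dict
    differences: dict
    dsc: pd.DataFrame
    scopes: tuple[str, ...] = SCOPES
    provenance: dict = dc_field(default_factory=dict)

    def metric(self, scope: str, organ: str, volume_cm3: float, method: str) -> float:
        return self.metrics[scope][organ][volume_cm3][method]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for scope, organs in self.metrics.items():
            for organ, vols in organs.items():
                for vol, methods in vols.items():
                    row = {"scope": scope, "organ": organ, "volume_cm3": vol}
                    row.update(methods)
                    for a, b in DIFF_COLUMNS:
                        row[f"{a}-{b}"] = self.differences[scope][organ][vol][(a, b)]
                    rows.append(row)
        return pd.DataFrame(rows)


def _rigid_align_frame(
    frame: Frame, reference: Frame, match_on: str
) -> tuple[RigidTransform, ScalarVolume, StructureSet]:
    rigid = _register_or_identity(frame, reference, match_on)
    grid = reference.ct.grid
    ct = apply_rigid(frame.ct, rigid, mode="linear", fill=-1000.0, target=grid)
    masks = {}
    for name, mask in frame.structures.masks.items():
        warped = apply_rigid(
            ScalarVolume(mask.astype(np.float32), frame.structures.grid),
            rigid, mode="linear", fill=0.0, target=grid,
        )
        masks[name] = warped.values >= 0.5
    return rigid, ct, StructureSet(masks, grid, validate=False)


def _register_or_identity(frame: Frame, reference: Frame, match_on: str):
    from .registration import rigid_register

    return rigid_register(frame.structures, reference.structures, match_on)


def register_case(
    case: Case, config: PipelineConfig | None = None, compute_tre: bool = True
) -> dict[str, FrameRegistration]:
    """Rigid + deformable registration of every non-reference frame."""
    config = config or PipelineConfig()
    ref = case.frames[case.reference]
    fixed_ct = replace_applicator_hu(ref.ct, ref.structures["applicator"]) \
        if "applicator" in ref.structures else ref.ct

    eval_mask = np.zeros(ref.ct.shape, dtype=bool)
    for name in EVAL_STRUCTURES:
        eval_mask |= surface_voxels(ref.structures[name])

    out: dict[str, FrameRegistration] = {}
    for name, frame in case.frames.items():
        if name == case.reference:
            continue
        rigid, aligned_ct, aligned_structs = _rigid_align_frame(
            frame, ref, config.rigid_match_on
        )
        if "applicator" in aligned_structs and aligned_structs["applicator"].any():
            aligned_ct = replace_applicator_hu(
                aligned_ct, aligned_structs["applicator"]
            )
        dsc: dict[str, dict[str, float]] = {"rigid": {}}
        for s in EVAL_STRUCTURES:
            dsc["rigid"][s] = dice(aligned_structs[s], ref.structures[s])
        tre: dict[str, float] = {}
        gt_inv = None
        if compute_tre and frame.gt_field is not None:
            from .phantom import invert_field

            gt_inv = invert_field(frame.gt_field)
            tre["rigid"] = registration_tre(frame.gt_field, None, rigid,
                                            eval_mask, gt_inverse=gt_inv)
        fields = {}
        for mode in config.modes:
            field = deformable_register(
                aligned_ct, fixed_ct, aligned_structs, ref.structures,
                config.dir_config(mode),
            )
            fields[mode] = field
            dsc[mode] = {
                s: dice(warp_mask(aligned_structs[s], field), ref.structures[s])
                for s in EVAL_STRUCTURES
            }
            if compute_tre and frame.gt_field is not None:
                tre[mode] = registration_tre(frame.gt_field, field, rigid,
                                             eval_mask, gt_inverse=gt_inv)
        out[name] = FrameRegistration(
            name, rigid, aligned_ct, aligned_structs, fields, dsc, tre
        )
    return out


def _scope_plans(case: Case, scope: str) -> list:
    plans = case.manifest.plans()
    if scope == "BT_only":
        return [p for p in plans if p.label.startswith("BT")]
    if scope == "BT_plus_EBRT":
        return plans
    raise ValueError(f"unknown scope '{scope}'")


def run_course(
    case: Case,
    config: PipelineConfig | None = None,
    registrations: dict[str, FrameRegistration] | None = None,
) -> AccumulationReport:
    """Full workflow on one case; deterministic for a given case + config."""
    config = config or PipelineConfig()
    ref = case.frames[case.reference]
    if registrations is None:
        registrations = register_case(case, config, compute_tre=False)
    alpha_beta = case.manifest.alpha_beta_gy

    # rigid-aligned plan doses on the reference grid
    aligned_dose: dict[str, ScalarVolume] = {}
    for p in case.manifest.plans():
        dose = case.doses[p.label]
        if p.frame == case.reference:
            aligned_dose[p.label] = dose
        else:
            rigid = registrations[p.frame].rigid
            aligned_dose[p.label] = apply_rigid(
                dose, rigid, mode="linear", fill=0.0, target=ref.ct.grid
            )

    metrics: dict = {}
    diffs: dict = {}
    for scope in SCOPES:
        prescriptions = _scope_plans(case, scope)
        metrics[scope] = {}
        diffs[scope] = {}

        accumulated: dict[str, ScalarVolume] = {}
        for mode in config.modes:
            plans = [
                FractionPlan(p.label, aligned_dose[p.label], p.n_fractions,
                             p.frame, p.include_in_addition)
                for p in prescriptions
            ]
            fields: dict[str, DisplacementField | None] = {case.reference: None}
            for p in prescriptions:
                if p.frame != case.reference:
                    fields[p.frame] = registrations[p.frame].fields[mode]
            acc = accumulate(plans, fields, alpha_beta_gy=alpha_beta,
                             order=config.accumulation_order)
            accumulated[mode] = acc.volume

        for organ in ("rectum", "bladder"):
            metrics[scope][organ] = {}
            diffs[scope][organ] = {}
            ref_mask = ref.structures[organ]
            for vol in config.metric_volumes_cm3:
                values = {}
                # DVH parameter addition on each plan's native frame
                doses_eqd2, masks, included = [], [], []
                for p in prescriptions:
                    native = case.frames[p.frame]
                    plan = FractionPlan(p.label, case.doses[p.label],
                                        p.n_fractions, p.frame,
                                        p.include_in_addition)
                    doses_eqd2.append(eqd2_convert(plan, alpha_beta))
                    masks.append(native.structures[organ])
                    included.append(p.include_in_addition)
                values["addition"] = dvh_parameter_addition(
                    doses_eqd2, masks, vol, included
                )
                for mode in config.modes:
                    values[mode] = d_cc(accumulated[mode], ref_mask, vol)
                metrics[scope][organ][vol] = values
                diffs[scope][organ][vol] = {
                    (a, b): values[a] - values[b]
                    for a, b in DIFF_COLUMNS
                    if a in values and b in values
                }

    rows = []
    for name, fr in registrations.items():
        for method, per_struct in fr.dsc.items():
            for s, v in per_struct.items():
                rows.append({
                    "frame": name, "structure": s, "method": method, "dsc": v,
                    "tre_mm": fr.tre_mm.get(method, np.nan),
                })
    dsc_table = pd.DataFrame(rows)
    return AccumulationReport(
        metrics, diffs, dsc_table,
        provenance={"alpha_beta_gy": alpha_beta,
                    "order": config.accumulation_order,
                    "modes": list(config.modes)},
    )


def registration_study(
    seeds: list[int],
    modes: tuple[str, ...] = ("intensity", "hybrid"),
    spec: PhantomSpec | None = None,
    deformation: DeformationSpec | None = None,
    config: PipelineConfig | None = None,
    compute_tre: bool = True,
) -> pd.DataFrame:
    """DSC/TRE over seeded phantom courses.

    Returns one row per (seed, frame, structure, method); rigid rows carry
    the pre-DIR accuracy.  This is the synthetic counterpart of a cohort
    registration-accuracy table.
    """
    config = config or PipelineConfig(modes=modes)
    if tuple(config.modes) != tuple(modes):
        config = PipelineConfig(
            intensity=config.intensity, hybrid=config.hybrid, modes=modes,
            metric_volumes_cm3=config.metric_volumes_cm3,
            accumulation_order=config.accumulation_order,
        )
    rows = []
    for seed in seeds:
        case = generate_case(spec=spec, deformation=deformation, seed=seed,
                             with_doses=False)
        regs = register_case(case, config, compute_tre=compute_tre)
        for name, fr in regs.items():
            for method, per_struct in fr.dsc.items():
                for s, v in per_struct.items():
                    rows.append({
                        "seed": seed, "frame": name, "structure": s,
                        "method": method, "dsc": v,
                        "tre_mm": fr.tre_mm.get(method, np.nan),
                    })
    return pd.DataFrame(rows)


def cohort_summary(reports: list[AccumulationReport]) -> pd.DataFrame:
    """Mean ± SD per (scope, organ, metric, method/difference column)."""
    if not reports:
        raise ValueError("at least one report is required")
    scopes = reports[0].scopes
    if any(r.scopes != scopes for r in reports):
        raise ValueError("reports with mixed scopes cannot be summarised")
    frames = [r.to_frame() for r in reports]
    stacked = pd.concat(frames, keys=range(len(frames)))
    value_cols = [c for c in stacked.columns
                  if c not in ("scope", "organ", "volume_cm3")]
    grouped = stacked.groupby(["scope", "organ", "volume_cm3"])[value_cols]
    mean = grouped.mean().add_suffix("_mean")
    sd = grouped.std(ddof=1).fillna(0.0).add_suffix("_sd")
    return pd.concat([mean, sd], axis=1).reset_index()


# ---------------------------------------------------------------------------
# stage persistence for the CLI
# ---------------------------------------------------------------------------


def save_registrations(regs: dict[str, FrameRegistration], directory: str | Path
                       ) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, fr in regs.items():
        fdir = directory / name
        fdir.mkdir(exist_ok=True)
        (fdir / "rigid.json").write_text(json.dumps({
            "rotation_deg": list(fr.rigid.rotation_deg),
            "translation_mm": list(fr.rigid.translation_mm),
            "center_mm": list(fr.rigid.center_mm),
        }, indent=1))
        for mode, field in fr.fields.items():
            write_field(field, fdir / f"field_{mode}.nii.gz")
        for method, per_struct in fr.dsc.items():
            for s, v in per_struct.items():
                rows.append({"frame": name, "structure": s, "method": method,
                             "dsc": v, "tre_mm": fr.tre_mm.get(method, np.nan)})
    pd.DataFrame(rows).to_csv(directory / "dsc.csv", index=False)


def load_registrations(case: Case, directory: str | Path,
                       config: PipelineConfig | None = None
                       ) -> dict[str, FrameRegistration]:
    config = config or PipelineConfig()
    directory = Path(directory)
    ref = case.frames[case.reference]
    out = {}
    dsc_table = pd.read_csv(directory / "dsc.csv")
    for name, frame in case.frames.items():
        if name == case.reference:
            continue
        fdir = directory / name
        rj = json.loads((fdir / "rigid.json").read_text())
        rigid = RigidTransform(tuple(rj["rotation_deg"]),
                               tuple(rj["translation_mm"]),
                               tuple(rj["center_mm"]))
        fields = {}
        for mode in config.modes:
            path = fdir / f"field_{mode}.nii.gz"
            if path.exists():
                fields[mode] = read_field(path)
        sub = dsc_table[dsc_table["frame"] == name]
        dsc = {}
        tre = {}
        for method, g in sub.groupby("method"):
            dsc[method] = dict(zip(g["structure"], g["dsc"]))
            tre_vals = g["tre_mm"].dropna()
            if len(tre_vals):
                tre[method] = float(tre_vals.iloc[0])
        grid = ref.ct.grid
        ct = apply_rigid(frame.ct, rigid, mode="linear", fill=-1000.0, target=grid)
        masks = {
            n: apply_rigid(ScalarVolume(m.astype(np.float32),
                                        frame.structures.grid),
                           rigid, mode="linear", fill=0.0, target=grid
                           ).values >= 0.5
            for n, m in frame.structures.masks.items()
        }
        out[name] = FrameRegistration(
            name, rigid, ct, StructureSet(masks, grid, validate=False),
            fields, dsc, tre,
        )
    return out
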