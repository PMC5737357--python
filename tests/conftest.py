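"""Shared fixtures: small grids, a fast coarse phantom, and the heavy
session-scoped registration study used by the accuracy tests."""

from __future__ import annotations

import numpy as np
import pytest

import dirdose as dd
from dirdose.phantom import degenerate_case
from dirdose.pipeline import PipelineConfig, registration_study, run_course

STUDY_SEEDS = [1, 2, 3, 4, 5]


@pytest.fixture
def small_grid() -> dd.Grid:
    return dd.Grid((12, 10, 8), (2.0, 2.0, 2.0))


@pytest.fixture
def coarse_spec() -> dd.PhantomSpec:
    """Same anatomy at 5 mm voxels — fast enough for per-test DIR runs."""
    return dd.PhantomSpec(shape=(48, 48, 32), spacing=(5.0, 5.0, 5.0))


@pytest.fixture(scope="session")
def study_df():
    """DSC + TRE over five seeded phantom courses, all methods.

    Covers every deformed frame (three BT fractions and the EBRT frame)
    registered to the reference with rigid fusion alone, intensity-based
    DIR and hybrid DIR.
    """
    return registration_study(STUDY_SEEDS, modes=("intensity", "hybrid"),
                              compute_tre=True)


@pytest.fixture(scope="session")
def degenerate_report():
    """Full pipeline on the zero-deformation case (all frames = reference)."""
    case = degenerate_case()
    return run_course(case, PipelineConfig())


@pytest.fixture(scope="session")
def default_case():
    """One complete seeded course with all plan doses (no registration)."""
    return dd.generate_case(seed=1)


def brute_force_d_cc(doses: np.ndarray, voxel_volume_cm3: float,
                     volume_cm3: float) -> float:
    """Independent sort-and-scan oracle for the hottest-subvolume dose.

    Walks the descending dose list one voxel at a time, accumulating voxel
    volume, and linearly interpolates within the voxel that crosses the
    requested volume.
    """
    ordered = sorted(np.asarray(doses, dtype=float).ravel(), reverse=True)
    cum = 0.0
    previous = ordered[0]
    for dose in ordered:
        if cum + voxel_volume_cm3 >= volume_cm3 - 1e-15:
            frac = (volume_cm3 - cum) / voxel_volume_cm3
            return previous + frac * (dose - previous)
        cum += voxel_volume_cm3
        previous = dose
    raise ValueError("requested volume exceeds the organ volume")
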