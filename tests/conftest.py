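import numpy as np
import pytest

from rbedose.grids import PatientCase, PlanMeta, StructureMask, VoxelGrid
from rbedose.phantom import PhantomSpec, generate_case, generate_cohort


def make_case(dose, letd=None, spacing=(2.0, 2.0, 2.0), masks=None, plan=None,
              patient_id="T01"):
    """Build a tiny in-memory case from raw arrays (tests only)."""
    dose = np.asarray(dose, dtype=float)
    dose_grid = VoxelGrid(values=dose, spacing_mm=spacing, units="Gy")
    letd = np.zeros_like(dose) if letd is None else np.asarray(letd, dtype=float)
    letd_grid = VoxelGrid(values=letd, spacing_mm=spacing, units="keV/um")
    if masks is None:
        masks = {"heart": np.ones_like(dose, dtype=bool)}
    mask_objs = {
        name: StructureMask(name=name, selected=sel, grid_ref=dose_grid)
        for name, sel in masks.items()
    }
    return PatientCase(
        patient_id=patient_id,
        physical_dose=dose_grid,
        letd=letd_grid,
        masks=mask_objs,
        plan=plan or PlanMeta(),
    )


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_case(default_spec):
    """One synthetic phantom case with the default geometry, seed 1."""
    return generate_case(default_spec, seed=1)


@pytest.fixture(scope="session")
def cohort():
    """The 20-case synthetic cohort (seed 7) used for cohort-level checks."""
    return generate_cohort(20, seed=7)
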