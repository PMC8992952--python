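"""Synthetic distal-edge phantom cases for en-face breast proton beams.

Real clinical dose/LETd grids for this treatment site are not publicly
distributable, so the pipeline is exercised on analytic phantoms that
reproduce the statistical structure the downstream analysis consumes:

* a slab-shaped target (CTV) receiving a uniform physical dose of
  prescription / 1.1 (50 GyRBE at RBE 1.1 over 25 fractions by default),
* a sigmoid distal dose falloff along the beam axis (z) with a configurable
  d80-20 distance (default 6 mm, typical of a single-field distal edge at
  breast depths),
* a dose-averaged LET that ramps from ~2 to ~4 keV/um across the target
  depth and peaks at ~8 keV/um about 2 mm beyond the distal target face —
  the end-of-range LET elevation that drives the variable-RBE enhancement —
  then stays near the peak through the falloff,
* an ellipsoidal heart immediately distal to the target, with a nested
  ventricle ellipsoid and a thin LAD tube on its anterior surface,
* multiplicative Gaussian noise on the dose (0.5% by default, the usual
  Monte Carlo statistical uncertainty), seeded and reproducible.

One effective beam axis is used even though clinical plans combine two
en-face fields: for the distal-edge physics seen by the heart a single
axis produces the same phenomenology.

A cohort is generated by sweeping the heart--target gap, which monotonically
controls how much of the distal falloff the heart intercepts and hence the
mean heart dose; gaps are solved by bisection so the realized MHD values at
RBE = 1.1 span a requested range (default 0.39-2.44 GyRBE, a typical
spread for left-sided breast/chest-wall cohorts with nodal coverage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .grids import PatientCase, PlanMeta, StructureMask, VoxelGrid

__all__ = [
    "PhantomSpec",
    "generate_case",
    "generate_cohort",
    "analytic_dose",
    "analytic_letd",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and field parameters of one synthetic case.

    Distances in mm, doses in Gy(RBE), LET in keV/um.
    """

    shape: tuple[int, int, int] = (60, 60, 60)
    spacing_mm: float = 2.0
    # target slab: depth extent along the beam axis (z) and lateral half-width
    ctv_z_mm: tuple[float, float] = (6.0, 38.0)
    ctv_lateral_halfwidth_mm: float = 40.0
    field_margin_mm: float = 4.0           # beam footprint beyond the CTV laterally
    # heart: ellipsoid whose proximal surface sits heart_gap_mm beyond the CTV face
    heart_semiaxes_mm: tuple[float, float, float] = (30.0, 26.0, 18.0)
    heart_gap_mm: float = 8.0
    ventricle_scale: float = 0.55
    ventricle_offset_mm: tuple[float, float, float] = (0.0, -4.0, 2.0)
    lad_radius_mm: float = 2.5
    lad_arc_fraction: float = 0.7
    # plan
    prescription_GyRBE: float = 50.0
    n_fractions: int = 25
    rbe_clinical: float = 1.1
    # distal falloff and LET structure
    falloff_d80_20_mm: float = 6.0
    letd_proximal: float = 2.0
    letd_distal_edge: float = 4.0
    letd_peak: float = 8.0
    letd_peak_offset_mm: float = 2.0
    letd_peak_decay_per_mm: float = 0.02
    letd_dose_floor_Gy: float = 0.10
    noise_sd_fraction: float = 0.005

    def __post_init__(self) -> None:
        if not (self.letd_proximal <= self.letd_distal_edge <= self.letd_peak):
            raise ValueError("require letd_proximal <= letd_distal_edge <= letd_peak")
        if self.falloff_d80_20_mm <= 0:
            raise ValueError("falloff_d80_20_mm must be > 0")
        if self.heart_gap_mm <= 0:
            raise ValueError("heart_gap_mm must be > 0: the heart may not touch the CTV")
        if self.ctv_z_mm[0] >= self.ctv_z_mm[1]:
            raise ValueError("ctv_z_mm must be an increasing (proximal, distal) pair")
        if any(n < 2 for n in self.shape):
            raise ValueError("grid shape must be at least 2 voxels per axis")

    @property
    def ctv_distal_z_mm(self) -> float:
        return self.ctv_z_mm[1]

    @property
    def physical_ctv_dose_Gy(self) -> float:
        return self.prescription_GyRBE / self.rbe_clinical

    @property
    def center_xy_mm(self) -> tuple[float, float]:
        cx = self.spacing_mm * (self.shape[0] - 1) / 2.0
        cy = self.spacing_mm * (self.shape[1] - 1) / 2.0
        return cx, cy

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.spacing_mm * np.arange(n) for n in self.shape)  # type: ignore


def _axial_profile(spec: PhantomSpec, z: np.ndarray) -> np.ndarray:
    """Relative depth dose: 1 through the target, sigmoid falloff beyond.

    The falloff 2 / (1 + exp(k u)) is continuous with the plateau at the
    distal face (u = 0) and k = ln(6) / d80-20 fixes the 80%-to-20% distance.
    """
    k = math.log(6.0) / spec.falloff_d80_20_mm
    u = z - spec.ctv_distal_z_mm
    out = np.ones_like(z, dtype=np.float64)
    distal = u > 0
    out[distal] = 2.0 / (1.0 + np.exp(k * u[distal]))
    return out


def _lateral_footprint(spec: PhantomSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    cx, cy = spec.center_xy_mm
    half = spec.ctv_lateral_halfwidth_mm + spec.field_margin_mm
    return ((np.abs(x - cx) <= half)[:, None] & (np.abs(y - cy) <= half)[None, :])


def analytic_dose(spec: PhantomSpec) -> VoxelGrid:
    """Noise-free physical dose field evaluated at voxel centers."""
    x, y, z = spec.axes_mm()
    lat = _lateral_footprint(spec, x, y).astype(np.float64)
    ax = _axial_profile(spec, z)
    values = spec.physical_ctv_dose_Gy * lat[:, :, None] * ax[None, None, :]
    return VoxelGrid(values=values, spacing_mm=(spec.spacing_mm,) * 3, units="Gy")


def _letd_depth_curve(spec: PhantomSpec, z: np.ndarray) -> np.ndarray:
    z0, z1 = spec.ctv_z_mm
    out = np.full_like(z, spec.letd_proximal, dtype=np.float64)
    in_ctv = (z >= z0) & (z <= z1)
    out[in_ctv] = spec.letd_proximal + (spec.letd_distal_edge - spec.letd_proximal) * (
        (z[in_ctv] - z0) / (z1 - z0)
    )
    u = z - z1
    rising = (u > 0) & (u <= spec.letd_peak_offset_mm)
    out[rising] = spec.letd_distal_edge + (spec.letd_peak - spec.letd_distal_edge) * (
        u[rising] / spec.letd_peak_offset_mm
    )
    past = u > spec.letd_peak_offset_mm
    out[past] = np.maximum(
        spec.letd_peak - spec.letd_peak_decay_per_mm * (u[past] - spec.letd_peak_offset_mm),
        spec.letd_distal_edge,
    )
    return out


def analytic_letd(spec: PhantomSpec) -> VoxelGrid:
    """Dose-averaged LET field; zero where the dose is below the scoring floor."""
    x, y, z = spec.axes_mm()
    lat = _lateral_footprint(spec, x, y)
    curve = _letd_depth_curve(spec, z)
    values = lat[:, :, None] * curve[None, None, :]
    scored = analytic_dose(spec).values >= spec.letd_dose_floor_Gy
    values = np.where(scored, values, 0.0)
    return VoxelGrid(values=values, spacing_mm=(spec.spacing_mm,) * 3, units="keV/um")


def _ellipsoid_mask(axes, center, semiaxes) -> np.ndarray:
    x, y, z = axes
    q = (
        ((x - center[0]) / semiaxes[0])[:, None, None] ** 2
        + ((y - center[1]) / semiaxes[1])[None, :, None] ** 2
        + ((z - center[2]) / semiaxes[2])[None, None, :] ** 2
    )
    return q <= 1.0


def _heart_center(spec: PhantomSpec) -> tuple[float, float, float]:
    cx, cy = spec.center_xy_mm
    cz = spec.ctv_distal_z_mm + spec.heart_gap_mm + spec.heart_semiaxes_mm[2]
    return cx, cy, cz


def _lad_mask(spec: PhantomSpec, axes) -> np.ndarray:
    """Thin tube following the anterior (beam-facing) heart surface at mid-x."""
    cx, cy, cz = _heart_center(spec)
    a, b, c = spec.heart_semiaxes_mm
    t = np.linspace(-spec.lad_arc_fraction, spec.lad_arc_fraction, 121)
    curve = np.stack(
        [np.full_like(t, cx), cy + b * t, cz - c * np.sqrt(1.0 - t**2)], axis=1
    )
    x, y, z = axes
    # restrict the distance computation to a bounding box around the curve
    pad = spec.lad_radius_mm + 2 * spec.spacing_mm
    lo = curve.min(axis=0) - pad
    hi = curve.max(axis=0) + pad
    ix = np.where((x >= lo[0]) & (x <= hi[0]))[0]
    iy = np.where((y >= lo[1]) & (y <= hi[1]))[0]
    iz = np.where((z >= lo[2]) & (z <= hi[2]))[0]
    mask = np.zeros(spec.shape, dtype=bool)
    if not (ix.size and iy.size and iz.size):
        return mask
    pts = np.stack(np.meshgrid(x[ix], y[iy], z[iz], indexing="ij"), axis=-1)
    d2 = ((pts[..., None, :] - curve[None, None, None, :, :]) ** 2).sum(axis=-1)
    within = d2.min(axis=-1) <= spec.lad_radius_mm**2
    mask[np.ix_(ix, iy, iz)] = within
    return mask


def _masks(spec: PhantomSpec, grid: VoxelGrid) -> dict[str, StructureMask]:
    axes = spec.axes_mm()
    x, y, z = axes
    cx, cy = spec.center_xy_mm
    half = spec.ctv_lateral_halfwidth_mm
    z0, z1 = spec.ctv_z_mm
    ctv = (
        (np.abs(x - cx) <= half)[:, None, None]
        & (np.abs(y - cy) <= half)[None, :, None]
        & ((z >= z0) & (z <= z1))[None, None, :]
    )
    heart_center = _heart_center(spec)
    heart = _ellipsoid_mask(axes, heart_center, spec.heart_semiaxes_mm)
    vent_center = tuple(hc + off for hc, off in zip(heart_center, spec.ventricle_offset_mm))
    vent_axes = tuple(spec.ventricle_scale * s for s in spec.heart_semiaxes_mm)
    ventricles = _ellipsoid_mask(axes, vent_center, vent_axes)
    lad = _lad_mask(spec, axes)
    out = {}
    for name, sel in (("CTV", ctv), ("heart", heart), ("ventricles", ventricles), ("LAD", lad)):
        out[name] = StructureMask(name=name, selected=sel, grid_ref=grid)
        out[name].require_nonempty()
    return out


def generate_case(spec: PhantomSpec, seed: int, patient_id: str = "P01",
                  ) -> PatientCase:
    """One deterministic synthetic case: analytic fields + seeded dose noise."""
    dose = analytic_dose(spec)
    letd = analytic_letd(spec)
    rng = np.random.default_rng(seed)
    if spec.noise_sd_fraction > 0:
        noisy = dose.values * (
            1.0 + spec.noise_sd_fraction * rng.standard_normal(dose.values.shape)
        )
        dose = dose.with_values(np.maximum(noisy, 0.0))
    masks = _masks(spec, dose)
    plan = PlanMeta(
        prescription_GyRBE=spec.prescription_GyRBE,
        n_fractions=spec.n_fractions,
        rbe_clinical=spec.rbe_clinical,
    )
    return PatientCase(
        patient_id=patient_id, physical_dose=dose, letd=letd, masks=masks, plan=plan
    )


def _analytic_mhd_1p1(spec: PhantomSpec) -> float:
    """Mean heart dose at RBE 1.1 from the noise-free analytic field."""
    dose = analytic_dose(spec)
    heart = _ellipsoid_mask(spec.axes_mm(), _heart_center(spec), spec.heart_semiaxes_mm)
    return spec.rbe_clinical * float(dose.values[heart].mean())


_GAP_BOUNDS_MM = (1.0, 40.0)


def _solve_gap(base: PhantomSpec, target_mhd_1p1: float) -> float:
    """Bisection for the heart gap realizing a target MHD(1.1); MHD is
    strictly decreasing in the gap."""
    lo, hi = _GAP_BOUNDS_MM
    f_lo = _analytic_mhd_1p1(replace(base, heart_gap_mm=lo))
    f_hi = _analytic_mhd_1p1(replace(base, heart_gap_mm=hi))
    if not (f_hi <= target_mhd_1p1 <= f_lo):
        raise ValueError(
            f"target MHD {target_mhd_1p1:.3f} GyRBE unattainable; attainable range "
            f"for this geometry is [{f_hi:.3f}, {f_lo:.3f}] GyRBE"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _analytic_mhd_1p1(replace(base, heart_gap_mm=mid)) > target_mhd_1p1:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    return 0.5 * (lo + hi)


def generate_cohort(
    n: int,
    base_spec: PhantomSpec | None = None,
    mhd_target_range: tuple[float, float] = (0.39, 2.44),
    seed: int = 0,
) -> tuple[list[PatientCase], pd.DataFrame]:
    """A cohort of ``n`` cases whose MHD(1.1) values span ``mhd_target_range``.

    Group labels alternate chest wall ("CW") / intact breast ("breast") so
    both groups cover the dose range.  The manifest records one row per case:
    patient id, group, solved heart gap, noise seed, and the realized
    MHD(1.1) computed from the generated (noisy) grid.
    """
    if n < 2:
        raise ValueError("need n >= 2 cases to span an MHD range")
    base = base_spec or PhantomSpec()
    lo, hi = mhd_target_range
    if not 0 < lo < hi:
        raise ValueError("mhd_target_range must be increasing and positive")
    targets = np.linspace(lo, hi, n)
    rng = np.random.default_rng(seed)
    noise_seeds = rng.integers(0, 2**31 - 1, size=n)

    cases: list[PatientCase] = []
    rows = []
    for i, (target, case_seed) in enumerate(zip(targets, noise_seeds)):
        gap = _solve_gap(base, float(target))
        spec = replace(base, heart_gap_mm=gap)
        pid = f"P{i + 1:02d}"
        group = "CW" if i % 2 == 0 else "breast"
        case = generate_case(spec, seed=int(case_seed), patient_id=pid)
        heart = case.mask("heart")
        realized = base.rbe_clinical * float(
            case.physical_dose.values[heart.selected].mean()
        )
        cases.append(case)
        rows.append({
            "patient_id": pid,
            "group": group,
            "heart_gap_mm": gap,
            "seed": int(case_seed),
            "target_mhd_1p1_GyRBE": float(target),
            "realized_mhd_1p1_GyRBE": realized,
        })
    manifest = pd.DataFrame(rows)
    return cases, manifest
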