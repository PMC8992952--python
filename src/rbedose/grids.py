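"""Voxel grids, structure masks and patient-case bundles.

All volumes live on a regular 3-D lattice indexed ``(x, y, z)`` with 0-based
indices; the world position of a voxel center is ``origin + index * spacing``
(the MetaImage convention).  Dose grids carry physical Gy unless produced by
the RBE engine, in which case they are tagged GyRBE; the two are never
converted implicitly.

MetaImage (.mhd/.raw) is the on-disk format for every volume.  A case bundle
is a directory with fixed member names::

    dose.mhd / dose.raw          physical dose (Gy)
    letd.mhd / letd.raw          dose-averaged LET (keV/um)
    mask_<name>.mhd/.raw         binary structure masks (heart, ventricles, LAD, CTV, ...)
    plan.txt                     key=value plan metadata
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "VoxelGrid",
    "StructureMask",
    "PlanMeta",
    "PatientCase",
    "GridFormatError",
    "AlignmentError",
    "read_metaimage",
    "write_metaimage",
    "load_case",
    "save_case",
]

#: unit tags that must hold non-negative values
_NONNEGATIVE_UNITS = {"Gy", "GyRBE", "keV/um"}

_GEOM_ATOL_MM = 1e-6


class GridFormatError(ValueError):
    """A volume file is structurally inconsistent (shape, payload, dimension)."""


class AlignmentError(ValueError):
    """Grids in one case do not share shape/spacing/origin."""


@dataclass(frozen=True)
class VoxelGrid:
    """Scalar field on a regular 3-D lattice.

    Parameters
    ----------
    values
        float array of shape ``(nx, ny, nz)``.
    spacing_mm, origin_mm
        voxel spacing and position of the center of voxel (0, 0, 0), in mm.
    units
        tag carried with the data: ``"Gy"``, ``"GyRBE"``, ``"keV/um"`` or
        ``"1"`` (dimensionless).  Dose and LET grids must be non-negative.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = "1"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))
        if vals.ndim != 3:
            raise GridFormatError(f"values must be 3-D, got ndim={vals.ndim}")
        if any(n < 1 for n in vals.shape):
            raise GridFormatError(f"shape must be positive, got {vals.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise GridFormatError(f"spacing_mm must be > 0, got {self.spacing_mm}")
        if not np.all(np.isfinite(vals)):
            raise GridFormatError("values contain non-finite entries")
        if self.units in _NONNEGATIVE_UNITS and vals.min() < 0:
            raise GridFormatError(f"{self.units} grid contains negative values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis (0=x, 1=y, 2=z)."""
        n = self.shape[axis]
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(n)

    def same_geometry(self, other: "VoxelGrid", atol_mm: float = _GEOM_ATOL_MM) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= atol_mm for a, b in zip(self.spacing_mm, other.spacing_mm))
            and all(abs(a - b) <= atol_mm for a, b in zip(self.origin_mm, other.origin_mm))
        )

    def with_values(self, values: np.ndarray, units: str | None = None) -> "VoxelGrid":
        return replace(self, values=values, units=self.units if units is None else units)


@dataclass(frozen=True)
class StructureMask:
    """Boolean voxel selection aligned to a reference grid geometry."""

    name: str
    selected: np.ndarray
    grid_ref: VoxelGrid

    def __post_init__(self) -> None:
        sel = np.asarray(self.selected, dtype=bool)
        object.__setattr__(self, "selected", sel)
        if sel.shape != self.grid_ref.shape:
            raise AlignmentError(
                f"mask '{self.name}' shape {sel.shape} != grid shape {self.grid_ref.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.selected.sum())

    @property
    def volume_cc(self) -> float:
        return self.n_voxels * self.grid_ref.voxel_volume_cc

    def require_nonempty(self) -> None:
        if self.n_voxels == 0:
            raise ValueError(f"mask '{self.name}' selects no voxels")


@dataclass(frozen=True)
class PlanMeta:
    """Prescription metadata: total prescription in GyRBE at the clinical RBE."""

    prescription_GyRBE: float = 50.0
    n_fractions: int = 25
    rbe_clinical: float = 1.1

    def __post_init__(self) -> None:
        if self.prescription_GyRBE <= 0:
            raise ValueError("prescription_GyRBE must be > 0")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.rbe_clinical <= 0:
            raise ValueError("rbe_clinical must be > 0")


@dataclass(frozen=True)
class PatientCase:
    """One patient's physical dose, LETd map, structure masks and plan."""

    patient_id: str
    physical_dose: VoxelGrid
    letd: VoxelGrid
    masks: dict[str, StructureMask] = field(default_factory=dict)
    plan: PlanMeta = field(default_factory=PlanMeta)

    def __post_init__(self) -> None:
        if not self.physical_dose.same_geometry(self.letd):
            raise AlignmentError(f"case {self.patient_id}: letd grid misaligned with dose grid")
        for name, mask in self.masks.items():
            if not self.physical_dose.same_geometry(mask.grid_ref):
                raise AlignmentError(f"case {self.patient_id}: mask '{name}' misaligned")

    def mask(self, name: str) -> StructureMask:
        try:
            return self.masks[name]
        except KeyError:
            raise KeyError(f"case {self.patient_id} has no mask '{name}'; "
                           f"available: {sorted(self.masks)}") from None


# ---------------------------------------------------------------------------
# MetaImage I/O
# ---------------------------------------------------------------------------

def write_metaimage(grid: VoxelGrid, path: str | Path) -> None:
    """Write a grid as an uncompressed MetaImage pair (.mhd + .raw).

    The units tag is recorded as the MetaImage ``Comment`` header field so the
    pair round-trips through :func:`read_metaimage`.
    """
    path = Path(path)
    # SimpleITK arrays are indexed (z, y, x); our convention is (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values.T))
    img.SetSpacing(grid.spacing_mm)
    img.SetOrigin(grid.origin_mm)
    img.SetMetaData("Comment", f"units={grid.units}")
    sitk.WriteImage(img, str(path), useCompression=False)


_COMMENT_RE = re.compile(r"^Comment\s*=\s*units=(.+?)\s*$", re.MULTILINE)


def _units_from_header(path: Path) -> str:
    # SimpleITK writes the Comment field but does not expose it on read;
    # recover the tag from the header text directly.
    try:
        m = _COMMENT_RE.search(path.read_text(errors="replace"))
    except OSError:
        return "1"
    return m.group(1) if m else "1"


def read_metaimage(path: str | Path, units: str | None = None) -> VoxelGrid:
    """Read a MetaImage header + raw payload into a :class:`VoxelGrid`.

    ``units`` overrides the tag stored in the header's ``Comment`` field.
    """
    path = Path(path)
    if not path.exists():
        raise GridFormatError(f"no such MetaImage header: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # sitk wraps payload/shape problems as RuntimeError
        raise GridFormatError(f"cannot read MetaImage {path.name}: {exc}") from exc
    if img.GetDimension() != 3:
        raise GridFormatError(
            f"{path.name}: expected a 3-D image, got NDims={img.GetDimension()}"
        )
    values = sitk.GetArrayFromImage(img).astype(np.float64).T
    if units is None:
        units = _units_from_header(path)
    return VoxelGrid(
        values=values,
        spacing_mm=tuple(img.GetSpacing()),
        origin_mm=tuple(img.GetOrigin()),
        units=units,
    )


# ---------------------------------------------------------------------------
# Case bundles
# ---------------------------------------------------------------------------

def _read_plan(path: Path) -> PlanMeta:
    kv: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise GridFormatError(f"{path.name}: malformed line {line!r}")
        k, v = (part.strip() for part in line.split("=", 1))
        kv[k] = v
    try:
        return PlanMeta(
            prescription_GyRBE=float(kv["prescription_GyRBE"]),
            n_fractions=int(kv["n_fractions"]),
            rbe_clinical=float(kv.get("rbe_clinical", "1.1")),
        )
    except KeyError as exc:
        raise GridFormatError(f"{path.name}: missing required key {exc}") from None


def _write_plan(plan: PlanMeta, path: Path) -> None:
    path.write_text(
        f"prescription_GyRBE = {plan.prescription_GyRBE:g}\n"
        f"n_fractions = {plan.n_fractions}\n"
        f"rbe_clinical = {plan.rbe_clinical:g}\n"
    )


def load_case(bundle: str | Path, patient_id: str | None = None) -> PatientCase:
    """Load a case bundle directory into an aligned :class:`PatientCase`.

    Alignment (shape exact; spacing and origin within 1e-6 mm) is verified for
    every grid against the dose grid; the first offending grid is named in the
    raised :class:`AlignmentError`.
    """
    bundle = Path(bundle)
    if not bundle.is_dir():
        raise GridFormatError(f"case bundle is not a directory: {bundle}")
    for member in ("dose.mhd", "letd.mhd", "plan.txt"):
        if not (bundle / member).exists():
            raise GridFormatError(f"case bundle {bundle.name} is missing {member}")

    dose = read_metaimage(bundle / "dose.mhd", units="Gy")
    letd = read_metaimage(bundle / "letd.mhd", units="keV/um")
    if not dose.same_geometry(letd):
        raise AlignmentError(f"{bundle.name}: letd.mhd is misaligned with dose.mhd")

    masks: dict[str, StructureMask] = {}
    for mask_path in sorted(bundle.glob("mask_*.mhd")):
        name = mask_path.stem[len("mask_"):]
        grid = read_metaimage(mask_path, units="1")
        if not dose.same_geometry(grid):
            raise AlignmentError(f"{bundle.name}: {mask_path.name} is misaligned with dose.mhd")
        masks[name] = StructureMask(name=name, selected=grid.values > 0.5, grid_ref=dose)
    if not masks:
        raise GridFormatError(f"case bundle {bundle.name} contains no mask_*.mhd volumes")

    plan = _read_plan(bundle / "plan.txt")
    return PatientCase(
        patient_id=patient_id or bundle.name,
        physical_dose=dose,
        letd=letd,
        masks=masks,
        plan=plan,
    )


def save_case(case: PatientCase, bundle: str | Path) -> Path:
    """Write a :class:`PatientCase` as a bundle directory readable by load_case."""
    bundle = Path(bundle)
    bundle.mkdir(parents=True, exist_ok=True)
    write_metaimage(case.physical_dose, bundle / "dose.mhd")
    write_metaimage(case.letd, bundle / "letd.mhd")
    for name, mask in case.masks.items():
        grid = VoxelGrid(
            values=mask.selected.astype(np.float64),
            spacing_mm=case.physical_dose.spacing_mm,
            origin_mm=case.physical_dose.origin_mm,
            units="1",
        )
        write_metaimage(grid, bundle / f"mask_{name}.mhd")
    _write_plan(case.plan, bundle / "plan.txt")
    return bundle
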