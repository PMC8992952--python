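"""DVH and LET analytics over structure masks.

Conventions (fixed once, documented here):

* ``Vx`` counts voxels with dose **>= threshold** (closed comparison), as a
  fraction of the structure's voxel count, in percent.
* ``Dxcc`` is computed voxel-wise without partial-voxel interpolation: voxel
  doses inside the structure are sorted descending and the dose of the voxel
  at which the accumulated volume first reaches the requested hot volume is
  returned.  On a 2 mm grid one voxel is 0.008 cc, which bounds the
  granularity of the result.
* DVH curves are cumulative, absolute dose on the x axis, relative volume
  (percent) on the y axis; the curve evaluated at a bin edge equals
  :func:`v_threshold` at the same edge.
* Voxel volume is the product of grid spacings; masks are binary, with no
  anti-aliasing of partial voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .grids import AlignmentError, StructureMask, VoxelGrid

__all__ = [
    "DVHCurve",
    "LETHistogram",
    "LineProfile",
    "mean_dose",
    "v_threshold",
    "d_hot_volume",
    "dvh",
    "letd_histogram",
    "line_profile",
]


def _masked_values(grid: VoxelGrid, mask: StructureMask) -> np.ndarray:
    if not grid.same_geometry(mask.grid_ref):
        raise AlignmentError(f"mask '{mask.name}' is not aligned with the grid")
    mask.require_nonempty()
    return grid.values[mask.selected]


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram for one structure."""

    dose_edges: np.ndarray       # Gy(RBE), increasing, starting at 0
    volume_fraction: np.ndarray  # % of structure volume receiving >= edge

    def __post_init__(self) -> None:
        edges = np.asarray(self.dose_edges, dtype=np.float64)
        vf = np.asarray(self.volume_fraction, dtype=np.float64)
        object.__setattr__(self, "dose_edges", edges)
        object.__setattr__(self, "volume_fraction", vf)
        if edges.shape != vf.shape:
            raise ValueError("dose_edges and volume_fraction must have equal length")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("dose_edges must be strictly increasing")
        if np.any(np.diff(vf) > 1e-12):
            raise ValueError("volume_fraction must be non-increasing")

    def at(self, dose: float) -> float:
        """Volume fraction (%) at an arbitrary dose, by step-function lookup."""
        idx = np.searchsorted(self.dose_edges, dose, side="right") - 1
        if idx < 0:
            return 100.0
        return float(self.volume_fraction[idx])


@dataclass(frozen=True)
class LETHistogram:
    """LETd histogram over mask voxels above a dose cutoff."""

    bin_edges: np.ndarray   # keV/um
    percent: np.ndarray     # % of counted voxels per bin
    n_counted: int
    dose_cutoff_Gy: float

    @property
    def empty(self) -> bool:
        """True when no voxel survived the dose cutoff (all-zero histogram)."""
        return self.n_counted == 0


@dataclass(frozen=True)
class LineProfile:
    distance_mm: np.ndarray   # from start point
    positions_mm: np.ndarray  # (n, 3) world coordinates
    values: np.ndarray


def mean_dose(dose: VoxelGrid, mask: StructureMask) -> float:
    """Arithmetic mean dose over the selected voxels (uniform voxel volume)."""
    return float(_masked_values(dose, mask).mean())


def v_threshold(dose: VoxelGrid, mask: StructureMask, threshold: float) -> float:
    """Percent of structure volume receiving at least ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    vals = _masked_values(dose, mask)
    return 100.0 * float(np.count_nonzero(vals >= threshold)) / vals.size


def d_hot_volume(dose: VoxelGrid, mask: StructureMask, volume_cc: float) -> float:
    """Minimum dose within the hottest ``volume_cc`` of the structure."""
    if volume_cc <= 0:
        raise ValueError("volume_cc must be > 0")
    vals = _masked_values(dose, mask)
    vox_cc = dose.voxel_volume_cc
    if volume_cc > vals.size * vox_cc + 1e-12:
        raise ValueError(
            f"volume_cc={volume_cc:g} exceeds structure volume {vals.size * vox_cc:g} cc"
        )
    vals = np.sort(vals)[::-1]
    # dose of the voxel in which the running volume first reaches volume_cc
    idx = int(np.ceil(volume_cc / vox_cc - 1e-12)) - 1
    return float(vals[max(idx, 0)])


def dvh(dose: VoxelGrid, mask: StructureMask, bin_width: float = 0.1) -> DVHCurve:
    """Cumulative DVH with edges 0, bin_width, ... up to just past the max dose."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    vals = np.sort(_masked_values(dose, mask))
    n_edges = int(np.floor(vals[-1] / bin_width)) + 2
    edges = bin_width * np.arange(n_edges)
    vf = 100.0 * (vals.size - np.searchsorted(vals, edges, side="left")) / vals.size
    return DVHCurve(dose_edges=edges, volume_fraction=vf)


def letd_histogram(
    letd: VoxelGrid,
    dose: VoxelGrid,
    mask: StructureMask,
    dose_cutoff_Gy: float = 0.0,
    bin_width: float = 0.25,
) -> LETHistogram:
    """Histogram of LETd over mask voxels whose dose exceeds the cutoff.

    High LET is only biologically relevant where meaningful dose is
    delivered, so the histogram is restricted to voxels with
    dose > ``dose_cutoff_Gy``.  An empty selection yields an all-zero
    histogram flagged via :attr:`LETHistogram.empty`.
    """
    if dose_cutoff_Gy < 0:
        raise ValueError("dose_cutoff_Gy must be >= 0")
    if not letd.same_geometry(dose):
        raise AlignmentError("letd grid is not aligned with dose grid")
    sel = _masked_values(letd, mask)
    sel_dose = _masked_values(dose, mask)
    counted = sel[sel_dose > dose_cutoff_Gy]
    top = counted.max() if counted.size else bin_width
    edges = bin_width * np.arange(int(np.floor(top / bin_width)) + 2)
    counts, _ = np.histogram(counted, bins=edges)
    pct = 100.0 * counts / counted.size if counted.size else np.zeros_like(counts, dtype=float)
    return LETHistogram(
        bin_edges=edges, percent=pct, n_counted=int(counted.size), dose_cutoff_Gy=dose_cutoff_Gy
    )


def line_profile(
    grid: VoxelGrid,
    start_mm,
    end_mm,
    step_mm: float = 0.5,
) -> LineProfile:
    """Trilinearly interpolated profile along a segment, sampled every step_mm.

    Both endpoints must lie within the voxel-center bounding box of the grid.
    """
    start = np.asarray(start_mm, dtype=np.float64)
    end = np.asarray(end_mm, dtype=np.float64)
    axes = [grid.axis_coords_mm(i) for i in range(3)]
    for pt, label in ((start, "start"), (end, "end")):
        for ax in range(3):
            if not (axes[ax][0] - 1e-9 <= pt[ax] <= axes[ax][-1] + 1e-9):
                raise ValueError(
                    f"{label} point {pt.tolist()} is outside the grid along axis {ax}"
                )
    length = float(np.linalg.norm(end - start))
    n = max(int(np.floor(length / step_mm)) + 1, 2)
    t = np.linspace(0.0, 1.0, n) if length == 0 else np.arange(n) * step_mm / length
    t = np.clip(t, 0.0, 1.0)
    pts = start[None, :] + t[:, None] * (end - start)[None, :]
    interp = RegularGridInterpolator(axes, grid.values, method="linear", bounds_error=False,
                                     fill_value=None)
    return LineProfile(distance_mm=t * length, positions_mm=pts, values=interp(pts))
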