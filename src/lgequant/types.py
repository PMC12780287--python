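"""Domain types shared by every quantification algorithm.

Conventions
-----------
* Image grids are indexed ``(row, col, slice)``.  The physical in-plane
  position of voxel center ``(r, c)`` is ``x = c * spacing_col``,
  ``y = r * spacing_row`` in millimetres, i.e. pixel (0, 0) has its center at
  the origin of its slice plane.
* Contour and ROI polygons are ``(N, 2)`` arrays of ``(x, y)`` vertices in mm
  in that same frame.
* ``IR`` stacks are magnitude images and carry no negative intensities;
  ``PSIR`` stacks preserve the sign of the magnetization and may be negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "ContractError",
    "SliceStack",
    "SliceGeometry",
    "ContourSet",
    "RoiSet",
    "MyocardialMask",
    "InfarctSegmentation",
    "Component",
    "DEFAULT_DENSITY_G_PER_ML",
]

#: Myocardial tissue density used for g <-> mL conversion.  Volume filters in
#: the literature are stated in grams and cm^3 interchangeably; 1.05 g/mL is
#: the standard value.  Configurable wherever it matters.
DEFAULT_DENSITY_G_PER_ML = 1.05


class ContractError(ValueError):
    """Raised when an input violates a documented precondition."""


def _as_polygon_array(vertices) -> np.ndarray:
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ContractError("polygon must be an (N>=3, 2) array of (x, y) mm")
    return arr


def validate_simple_polygon(vertices, *, label: str = "polygon") -> np.ndarray:
    """Validate that a polygon is simple (non-self-intersecting)."""
    arr = _as_polygon_array(vertices)
    poly = _ShapelyPolygon(arr)
    if not poly.is_valid or poly.area <= 0:
        raise ContractError(f"{label} is not a simple polygon")
    return arr


@dataclass
class SliceStack:
    """A short-axis intensity stack with physical geometry.

    Parameters
    ----------
    voxels : float array, shape (rows, cols, slices)
    in_plane_spacing : (row_mm, col_mm)
    slice_thickness : mm (no slice gap)
    convention : "IR" or "PSIR"
    """

    voxels: np.ndarray
    in_plane_spacing: Tuple[float, float]
    slice_thickness: float
    convention: str = "IR"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[:, :, None]
        if self.voxels.ndim != 3 or self.voxels.shape[2] < 1:
            raise ContractError("stack must be 3D with at least one slice")
        self.in_plane_spacing = (
            float(self.in_plane_spacing[0]),
            float(self.in_plane_spacing[1]),
        )
        if min(self.in_plane_spacing) <= 0 or self.slice_thickness <= 0:
            raise ContractError("spacing and slice thickness must be positive")
        if self.convention not in ("IR", "PSIR"):
            raise ContractError("convention must be 'IR' or 'PSIR'")
        if self.convention == "IR" and np.any(self.voxels < 0):
            raise ContractError("IR stacks must not contain negative intensities")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]

    @property
    def voxel_volume_mm3(self) -> float:
        dr, dc = self.in_plane_spacing
        return dr * dc * self.slice_thickness

    def voxel_centers_mm(self) -> Tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinate grids for one slice plane."""
        nrow, ncol = self.voxels.shape[:2]
        dr, dc = self.in_plane_spacing
        x = np.arange(ncol) * dc
        y = np.arange(nrow) * dr
        xx, yy = np.meshgrid(x, y)
        return xx, yy


# Geometry carried alongside boolean masks so size bookkeeping does not need
# the full stack.
@dataclass(frozen=True)
class SliceGeometry:
    in_plane_spacing: Tuple[float, float]
    slice_thickness: float
    density: float = DEFAULT_DENSITY_G_PER_ML

    @property
    def voxel_volume_mm3(self) -> float:
        dr, dc = self.in_plane_spacing
        return dr * dc * self.slice_thickness

    @classmethod
    def of(cls, stack: SliceStack, density: float = DEFAULT_DENSITY_G_PER_ML):
        return cls(stack.in_plane_spacing, stack.slice_thickness, density)


@dataclass
class ContourSet:
    """Per-slice endocardial/epicardial polygons (vertices in mm).

    ``slices[k] = {"endo": (N,2) array or None, "epi": ... or None}``.
    The endocardium must lie strictly inside the epicardium wherever both
    exist.
    """

    slices: Dict[int, Dict[str, Optional[np.ndarray]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for idx, entry in self.slices.items():
            endo = entry.get("endo")
            epi = entry.get("epi")
            if endo is not None:
                entry["endo"] = validate_simple_polygon(endo, label=f"endo (slice {idx})")
            if epi is not None:
                entry["epi"] = validate_simple_polygon(epi, label=f"epi (slice {idx})")
            if endo is not None and epi is not None:
                p_endo = _ShapelyPolygon(entry["endo"])
                p_epi = _ShapelyPolygon(entry["epi"])
                if not p_epi.contains(p_endo):
                    raise ContractError(
                        f"endocardium not strictly inside epicardium on slice {idx}"
                    )

    def endo(self, slice_index: int) -> Optional[np.ndarray]:
        return self.slices.get(slice_index, {}).get("endo")

    def epi(self, slice_index: int) -> Optional[np.ndarray]:
        return self.slices.get(slice_index, {}).get("epi")


@dataclass
class RoiSet:
    """Per-slice infarct and remote ROI polygons (0 or more each)."""

    infarct: Dict[int, List[np.ndarray]] = field(default_factory=dict)
    remote: Dict[int, List[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, rois in (("infarct", self.infarct), ("remote", self.remote)):
            for idx, polys in rois.items():
                rois[idx] = [
                    validate_simple_polygon(p, label=f"{name} ROI (slice {idx})")
                    for p in polys
                ]

    @property
    def has_infarct_rois(self) -> bool:
        return any(len(v) > 0 for v in self.infarct.values())

    @property
    def has_remote_rois(self) -> bool:
        return any(len(v) > 0 for v in self.remote.values())


@dataclass
class MyocardialMask:
    """Boolean voxel mask of the LV wall plus the geometry to weigh it."""

    mask: np.ndarray
    geometry: SliceGeometry

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim == 2:
            self.mask = self.mask[:, :, None]

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mL(self) -> float:
        return self.voxel_count * self.geometry.voxel_volume_mm3 / 1000.0

    @property
    def mass_g(self) -> float:
        return self.volume_mL * self.geometry.density


@dataclass
class InfarctSegmentation:
    """Per-voxel infarct weight in [0, 1] with derived size bookkeeping.

    Binary methods use weights in {0, 1}; the intensity-weighted methods
    produce fractional weights that account for partial volume inside the
    infarct.  ``support`` is the set of voxels with any infarct weight.
    """

    weights: np.ndarray
    method: str
    infarct_volume_mL: float
    infarct_mass_g: float
    fraction_of_LV_percent: float
    thresholds: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.size and (w.min() < -1e-12 or w.max() > 1 + 1e-12):
            raise ContractError("segmentation weights must lie in [0, 1]")
        self.weights = np.clip(w, 0.0, 1.0)

    @property
    def support(self) -> np.ndarray:
        return self.weights > 0


@dataclass
class Component:
    """A 6-connected component of a binary support set."""

    indices: Tuple[np.ndarray, np.ndarray, np.ndarray]
    volume_mL: float
    mass_g: float
    mean_intensity: float
    touches_endocardium: bool
    slice_range: Tuple[int, int]

    @property
    def voxel_count(self) -> int:
        return len(self.indices[0])
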