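"""Myocardial geometry: contour rasterization, sectors, transmural depth,
connected components and infarct size bookkeeping.

Rasterization uses the voxel-center even-odd rule: a voxel belongs to the
wall iff its center lies inside the epicardial polygon and outside the
endocardial polygon.  Distances to the endo/epicardial boundaries are exact
Euclidean point-to-polyline distances in mm (in-plane).
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Tuple

import numpy as np
import shapely
from matplotlib.path import Path as _MplPath
from scipy import ndimage
from shapely.geometry import LinearRing

from .types import (
    Component,
    ContourSet,
    ContractError,
    DEFAULT_DENSITY_G_PER_ML,
    InfarctSegmentation,
    MyocardialMask,
    SliceGeometry,
    SliceStack,
)

__all__ = [
    "points_in_polygon",
    "rasterize_contours",
    "rasterize_rois",
    "sector_partition",
    "midmural_band",
    "endocardial_distance",
    "connected_components",
    "infarct_size",
    "make_segmentation",
    "SIX_CONNECTED",
]

#: 6-connectivity structuring element: 4-connected in-plane plus the two
#: through-plane neighbours.  Conservative against diagonal noise chains.
SIX_CONNECTED = ndimage.generate_binary_structure(3, 1)


def points_in_polygon(xy: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd point-in-polygon test for an (M, 2) array of points."""
    path = _MplPath(np.asarray(polygon, dtype=float), closed=False)
    return path.contains_points(np.asarray(xy, dtype=float))


def _slice_inside(stack_like, polygon: np.ndarray) -> np.ndarray:
    xx, yy = stack_like.voxel_centers_mm()
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    return points_in_polygon(pts, polygon).reshape(xx.shape)


def rasterize_contours(
    contours: ContourSet,
    stack: SliceStack,
    density: float = DEFAULT_DENSITY_G_PER_ML,
) -> MyocardialMask:
    """Rasterize endo/epi contours into a boolean myocardial mask.

    A slice without an epicardial contour contributes an empty mask plane; a
    slice with an epicardial but no endocardial contour is rejected only by
    operations that need a transmural axis.
    """
    mask = np.zeros(stack.shape, dtype=bool)
    for k in range(stack.n_slices):
        epi = contours.epi(k)
        if epi is None:
            continue
        inside_epi = _slice_inside(stack, epi)
        endo = contours.endo(k)
        if endo is None:
            mask[:, :, k] = inside_epi
        else:
            mask[:, :, k] = inside_epi & ~_slice_inside(stack, endo)
    return MyocardialMask(mask, SliceGeometry.of(stack, density))


def rasterize_rois(
    polygons_by_slice: Dict[int, List[np.ndarray]], stack: SliceStack
) -> np.ndarray:
    """Rasterize per-slice ROI polygons (union) to a boolean volume."""
    out = np.zeros(stack.shape, dtype=bool)
    for k, polys in polygons_by_slice.items():
        if k < 0 or k >= stack.n_slices:
            raise ContractError(f"ROI refers to slice {k} outside the stack")
        for poly in polys:
            out[:, :, k] |= _slice_inside(stack, poly)
    return out


def sector_partition(
    mask: MyocardialMask,
    stack: SliceStack,
    n_sectors: int,
    offset_deg: float = 0.0,
) -> np.ndarray:
    """Label each myocardial voxel with an angular sector 1..n_sectors.

    Sectors are equal angular bins around the per-slice centroid of the mask,
    anchored at the +x image axis plus ``offset_deg`` and advancing
    counter-clockwise.  Unmasked voxels get label 0; an empty slice stays
    unlabeled.
    """
    if n_sectors < 1:
        raise ContractError("n_sectors must be >= 1")
    labels = np.zeros(mask.mask.shape, dtype=int)
    xx, yy = stack.voxel_centers_mm()
    width = 2 * np.pi / n_sectors
    offset = np.deg2rad(offset_deg)
    for k in range(mask.mask.shape[2]):
        m = mask.mask[:, :, k]
        if not m.any():
            continue
        cx, cy = xx[m].mean(), yy[m].mean()
        theta = np.arctan2(yy[m] - cy, xx[m] - cx)
        bins = np.floor(((theta - offset) % (2 * np.pi)) / width).astype(int)
        labels[:, :, k][m] = np.minimum(bins, n_sectors - 1) + 1
    return labels


def _boundary_distance(polygon: np.ndarray, xy: np.ndarray) -> np.ndarray:
    ring = LinearRing(np.asarray(polygon, dtype=float))
    pts = shapely.points(xy[:, 0], xy[:, 1])
    return shapely.distance(pts, ring)


def endocardial_distance(
    mask: MyocardialMask, contours: ContourSet, stack: SliceStack
) -> np.ndarray:
    """In-plane Euclidean distance (mm) from voxel centers to the endocardial
    boundary; NaN on slices without an endo contour (flagged, not an error)."""
    out = np.full(mask.mask.shape, np.nan)
    xx, yy = stack.voxel_centers_mm()
    for k in range(mask.mask.shape[2]):
        m = mask.mask[:, :, k]
        if not m.any():
            continue
        endo = contours.endo(k)
        if endo is None:
            continue
        xy = np.column_stack([xx[m], yy[m]])
        plane = np.full(m.shape, np.nan)
        plane[m] = _boundary_distance(endo, xy)
        out[:, :, k] = plane
    return out


def transmural_depth(
    mask: MyocardialMask, contours: ContourSet, stack: SliceStack
) -> np.ndarray:
    """Normalized transmural depth d = d_endo / (d_endo + d_epi) per masked
    voxel (0 at the endocardium, 1 at the epicardium); NaN elsewhere."""
    out = np.full(mask.mask.shape, np.nan)
    xx, yy = stack.voxel_centers_mm()
    for k in range(mask.mask.shape[2]):
        m = mask.mask[:, :, k]
        if not m.any():
            continue
        endo, epi = contours.endo(k), contours.epi(k)
        if endo is None or epi is None:
            raise ContractError(
                f"transmural depth needs both contours on slice {k}"
            )
        xy = np.column_stack([xx[m], yy[m]])
        d_endo = _boundary_distance(endo, xy)
        d_epi = _boundary_distance(epi, xy)
        denom = d_endo + d_epi
        denom[denom == 0] = np.finfo(float).eps
        plane = np.full(m.shape, np.nan)
        plane[m] = d_endo / denom
        out[:, :, k] = plane
    return out


def midmural_band(
    mask: MyocardialMask,
    contours: ContourSet,
    stack: SliceStack,
    window: Tuple[float, float] = (0.25, 0.75),
) -> MyocardialMask:
    """Voxels whose normalized transmural depth lies inside ``window``.

    For walls too thin to populate the window the mid voxel layer (depth
    closest to the window center) is returned instead, so the band is never
    empty on a slice where the mask is non-empty.
    """
    lo, hi = window
    if not (0 <= lo < hi <= 1):
        raise ContractError("depth window must satisfy 0 <= lo < hi <= 1")
    depth = transmural_depth(mask, contours, stack)
    band = np.zeros_like(mask.mask)
    mid = 0.5 * (lo + hi)
    for k in range(mask.mask.shape[2]):
        m = mask.mask[:, :, k]
        if not m.any():
            continue
        d = depth[:, :, k]
        sel = m & (d >= lo) & (d <= hi)
        if not sel.any():
            dist = np.abs(d[m] - mid)
            sel = np.zeros_like(m)
            sel[m] = dist <= dist.min() + 1e-9
        band[:, :, k] = sel
    return MyocardialMask(band, mask.geometry)


def connected_components(
    support: np.ndarray,
    stack: SliceStack,
    endo_distance: Optional[np.ndarray] = None,
    density: float = DEFAULT_DENSITY_G_PER_ML,
    touch_tolerance_mm: Optional[float] = None,
) -> List[Component]:
    """Partition a binary support into 6-connected components.

    ``touches_endocardium`` is true when a component's minimum endocardial
    distance is within one in-plane voxel of the boundary (requires
    ``endo_distance``; False otherwise).
    """
    support = np.asarray(support, dtype=bool)
    labeled, n = ndimage.label(support, structure=SIX_CONNECTED)
    vox_vol = SliceGeometry(stack.in_plane_spacing, stack.slice_thickness).voxel_volume_mm3
    if touch_tolerance_mm is None:
        touch_tolerance_mm = max(stack.in_plane_spacing)
    comps: List[Component] = []
    for lbl in range(1, n + 1):
        idx = np.nonzero(labeled == lbl)
        count = len(idx[0])
        volume_mL = count * vox_vol / 1000.0
        touches = False
        if endo_distance is not None:
            d = endo_distance[idx]
            if np.any(np.isfinite(d)):
                touches = bool(np.nanmin(d) <= touch_tolerance_mm)
        comps.append(
            Component(
                indices=idx,
                volume_mL=volume_mL,
                mass_g=volume_mL * density,
                mean_intensity=float(stack.voxels[idx].mean()),
                touches_endocardium=touches,
                slice_range=(int(idx[2].min()), int(idx[2].max())),
            )
        )
    return comps


def infarct_size(
    weights: np.ndarray, mask: MyocardialMask
) -> Tuple[float, float, float]:
    """Infarct (volume mL, mass g, fraction of LV mass %) from voxel weights.

    Weights outside the myocardial mask are ignored; the fraction is linear in
    the weights and invariant under uniform spacing rescaling.
    """
    if mask.voxel_count == 0:
        raise ContractError("zero LV mass: empty myocardial mask")
    w = np.asarray(weights, dtype=float)
    if w.shape != mask.mask.shape:
        raise ContractError("weights and mask shapes differ")
    total = float(w[mask.mask].sum())
    volume_mL = total * mask.geometry.voxel_volume_mm3 / 1000.0
    mass_g = volume_mL * mask.geometry.density
    fraction = 100.0 * mass_g / mask.mass_g
    return volume_mL, mass_g, fraction


def make_segmentation(
    weights: np.ndarray,
    mask: MyocardialMask,
    method: str,
    thresholds: Optional[Dict[str, float]] = None,
) -> InfarctSegmentation:
    """Bundle weights with their derived sizes into an InfarctSegmentation."""
    w = np.where(mask.mask, np.asarray(weights, dtype=float), 0.0)
    volume_mL, mass_g, fraction = infarct_size(w, mask)
    return InfarctSegmentation(
        weights=w,
        method=method,
        infarct_volume_mL=volume_mL,
        infarct_mass_g=mass_g,
        fraction_of_LV_percent=fraction,
        thresholds=dict(thresholds or {}),
    )
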