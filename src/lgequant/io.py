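"""File I/O and run configuration.

Stacks, masks and weight maps travel as NIfTI-1 (spacing and slice thickness
in the header zooms, signal convention in the ``descrip`` field).  Contours
and ROIs travel as one JSON document of per-slice polygons in mm::

    {"0": {"endo": [[x, y], ...], "epi": [...],
           "infarct_rois": [[[x, y], ...], ...],
           "remote_rois": [...]}, "1": {...}}

Reports are JSON with the resolved configuration and its hash echoed, so a
run is reproducible from its report alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Dict, Optional, Tuple

import nibabel as nib
import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .model_based import MethodConfig
from .types import ContourSet, ContractError, RoiSet, SliceStack

__all__ = [
    "RunConfig",
    "read_stack",
    "write_stack",
    "read_geometry",
    "write_geometry",
    "write_report",
    "config_hash",
]


class RunConfig(BaseModel):
    """One segmentation run: method name, cutoffs, convention and seed."""

    model_config = ConfigDict(extra="forbid")

    method: str = "ewa"
    convention: Optional[str] = None  # None: taken from the stack file
    threshold: Optional[float] = None  # manual method only
    fwhm_anchor: str = "zero"
    fwhm_per_slice: bool = False
    nsd_n: float = 2.0
    seed: int = 0
    algorithm: MethodConfig = Field(default_factory=MethodConfig)


def config_hash(config: BaseModel) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_stack(stack: SliceStack, path: str | Path) -> None:
    dr, dc = stack.in_plane_spacing
    affine = np.diag([dc, dr, stack.slice_thickness, 1.0])
    img = nib.Nifti1Image(stack.voxels.astype(np.float64), affine)
    img.header.set_zooms((dc, dr, stack.slice_thickness))
    img.header["descrip"] = stack.convention.encode()
    nib.save(img, str(path))


def read_stack(path: str | Path, convention: Optional[str] = None) -> SliceStack:
    path = Path(path)
    if not path.exists():
        raise ContractError(f"stack file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:  # corrupt file
        raise ContractError(f"cannot read NIfTI stack {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise ContractError(f"{path}: expected a 2D or 3D image")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if len(zooms) < 3:  # 2D single-slice file: unit slice thickness
        zooms = (*zooms, 1.0)
    if any(z <= 0 for z in zooms):
        raise ContractError(f"{path}: non-positive voxel spacing in header")
    if convention is None:
        descrip = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="ignore")
        convention = descrip if descrip in ("IR", "PSIR") else "IR"
    dc, dr, dt = zooms
    return SliceStack(data, (dr, dc), dt, convention)


def _poly_to_list(poly: np.ndarray):
    return np.asarray(poly, dtype=float).tolist()


def write_geometry(contours: ContourSet, rois: RoiSet, path: str | Path) -> None:
    doc: Dict[str, Any] = {}
    slices = set(contours.slices) | set(rois.infarct) | set(rois.remote)
    for k in sorted(slices):
        entry: Dict[str, Any] = {}
        endo, epi = contours.endo(k), contours.epi(k)
        if endo is not None:
            entry["endo"] = _poly_to_list(endo)
        if epi is not None:
            entry["epi"] = _poly_to_list(epi)
        if rois.infarct.get(k):
            entry["infarct_rois"] = [_poly_to_list(p) for p in rois.infarct[k]]
        if rois.remote.get(k):
            entry["remote_rois"] = [_poly_to_list(p) for p in rois.remote[k]]
        doc[str(k)] = entry
    Path(path).write_text(json.dumps(doc))


def read_geometry(path: str | Path) -> Tuple[ContourSet, RoiSet]:
    path = Path(path)
    if not path.exists():
        raise ContractError(f"geometry file not found: {path}")
    doc = json.loads(path.read_text())
    slices: Dict[int, Dict[str, Optional[np.ndarray]]] = {}
    infarct: Dict[int, list] = {}
    remote: Dict[int, list] = {}
    for key, entry in doc.items():
        k = int(key)
        slc: Dict[str, Optional[np.ndarray]] = {}
        if "endo" in entry:
            slc["endo"] = np.asarray(entry["endo"], dtype=float)
        if "epi" in entry:
            slc["epi"] = np.asarray(entry["epi"], dtype=float)
        if slc:
            slices[k] = slc
        if entry.get("infarct_rois"):
            infarct[k] = [np.asarray(p, dtype=float) for p in entry["infarct_rois"]]
        if entry.get("remote_rois"):
            remote[k] = [np.asarray(p, dtype=float) for p in entry["remote_rois"]]
    return ContourSet(slices), RoiSet(infarct=infarct, remote=remote)


def write_report(results: Dict[str, Any], path: str | Path,
                 config: Optional[BaseModel] = None) -> None:
    """Write a JSON report; the resolved config and its hash are echoed."""
    doc = dict(results)
    if config is not None:
        doc["config"] = config.model_dump()
        doc["config_hash"] = config_hash(config)
    Path(path).write_text(json.dumps(_jsonable(doc), indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
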