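"""Synthetic short-axis LGE phantom with known ground truth.

The phantom emulates the image features the quantification algorithms key on:
an annular LV wall over several slices, a bright infarct sector of
configurable transmurality and angular extent (solid or patchy/insular), an
optional hypointense microvascular-obstruction (MVO) core open to the
endocardium, an optional moderately enhancing edema halo around the infarct,
a smooth multiplicative coil-sensitivity ramp, and Rician (IR magnitude) or
Gaussian (PSIR) noise.  Partial volume at class borders is modelled by 4x
in-plane supersampling of class membership; the noise-free sub-voxel infarct
fraction of each voxel's myocardial content is kept as the ground truth
weight, so the ground-truth infarct fraction plays the role of the ex-vivo
reference measurement.

It does not model MRI physics (inversion times, relaxation), motion or
ghosting artifacts, or realistic anatomy beyond the annular wall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Sequence, Tuple, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .geometry import infarct_size, rasterize_contours
from .types import ContourSet, ContractError, MyocardialMask, RoiSet, SliceStack

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "auto_infarct_roi",
    "auto_remote_roi",
    "sample_cohort",
    "annular_sector_polygon",
    "circle_polygon",
]

_BG, _REMOTE, _INFARCT, _MVO, _EDEMA = range(5)


class PhantomSpec(BaseModel):
    """Geometry, tissue-class intensities and noise model of one phantom.

    Defaults follow a typical 1.5T short-axis LGE protocol: 8 slices of
    8 mm with no gap at 1.5 x 1.5 mm in-plane, endocardial radius 20 mm and
    epicardial radius 30 mm, a 72 degree fully transmural infarct sector.
    Intensities are in arbitrary units with the viable (remote) wall near the
    noise floor and the infarct plateau at five-fold enhancement.
    """

    model_config = ConfigDict(extra="forbid")

    n_slices: int = Field(default=8, ge=1)
    n_rows: int = Field(default=64, ge=8)
    n_cols: int = Field(default=64, ge=8)
    in_plane_spacing: Tuple[float, float] = (1.5, 1.5)
    slice_thickness: float = Field(default=8.0, gt=0)

    endo_radius: Union[float, Tuple[float, ...]] = 20.0
    epi_radius: Union[float, Tuple[float, ...]] = 30.0

    infarct_extent_deg: float = Field(default=72.0, ge=0.0, lt=360.0)
    infarct_center_deg: float = 0.0
    transmurality: float = Field(default=1.0, gt=0.0, le=1.0)
    morphology: Literal["solid", "patchy"] = "solid"
    patch_density: float = Field(default=0.6, gt=0.0, le=1.0)
    patch_radius_mm: float = Field(default=2.0, gt=0.0)

    mvo_core_fraction: Optional[float] = Field(default=None, gt=0.0, le=1.0)
    mvo_extent_fraction: float = Field(default=0.6, gt=0.0, le=1.0)

    remote_mean: float = 20.0
    remote_sd: float = Field(default=5.0, ge=0.0)
    infarct_mean: float = 100.0
    infarct_sd: float = Field(default=5.0, ge=0.0)
    mvo_mean: float = 8.0
    background_mean: float = 0.0
    edema_halo_width_mm: Optional[float] = Field(default=None, gt=0.0)
    edema_mean: Optional[float] = None

    convention: Literal["IR", "PSIR"] = "IR"
    noise_model: Optional[Literal["rician", "gaussian"]] = None
    coil_amplitude: float = Field(default=0.0, ge=0.0, lt=1.0)

    roi_margin_mm: float = Field(default=0.0, ge=0.0)
    remote_roi_margin_deg: float = Field(default=20.0, ge=0.0)
    density: float = Field(default=1.05, gt=0.0)
    supersample: int = Field(default=4, ge=1)
    contour_vertices: int = Field(default=128, ge=16)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PhantomSpec":
        if self.infarct_mean <= self.remote_mean:
            raise ValueError("infarct mean must exceed remote mean")
        if min(self.in_plane_spacing) <= 0:
            raise ValueError("in-plane spacing must be positive")
        for s in range(self.n_slices):
            if self._endo_r(s) >= self._epi_r(s):
                raise ValueError("endocardial radius must be below epicardial")
        if self.convention == "IR":
            for name in ("remote_mean", "mvo_mean", "background_mean"):
                if getattr(self, name) < 0:
                    raise ValueError(f"IR phantoms need non-negative {name}")
        return self

    # per-slice radii (scalars may taper when given as sequences)
    def _radius(self, value, s: int) -> float:
        if isinstance(value, (tuple, list)):
            if len(value) != self.n_slices:
                raise ContractError("per-slice radii must match n_slices")
            return float(value[s])
        return float(value)

    def _endo_r(self, s: int) -> float:
        return self._radius(self.endo_radius, s)

    def _epi_r(self, s: int) -> float:
        return self._radius(self.epi_radius, s)

    @property
    def resolved_noise_model(self) -> str:
        if self.noise_model is not None:
            return self.noise_model
        return "rician" if self.convention == "IR" else "gaussian"

    @property
    def resolved_edema_mean(self) -> float:
        # acute peri-infarct edema enhances to an intermediate degree,
        # well below the infarct plateau
        if self.edema_mean is not None:
            return self.edema_mean
        return self.remote_mean + 0.4 * (self.infarct_mean - self.remote_mean)

    @classmethod
    def psir(cls, **overrides) -> "PhantomSpec":
        """PSIR variant: sign-preserving with a negative remote mean
        (default -0.2 x infarct mean) and Gaussian noise."""
        base = dict(convention="PSIR", remote_mean=-20.0, background_mean=-5.0,
                    mvo_mean=-15.0)
        base.update(overrides)
        return cls(**base)


@dataclass
class PhantomCase:
    """A generated phantom: stack, geometry, ROIs, and ground truth."""

    stack: SliceStack
    contours: ContourSet
    rois: RoiSet
    mask: MyocardialMask
    truth_weights: np.ndarray
    truth_fraction_percent: float
    spec: PhantomSpec

    @property
    def truth_support(self) -> np.ndarray:
        return self.truth_weights > 0


def circle_polygon(cx: float, cy: float, radius: float, n: int = 128) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + radius * np.cos(t), cy + radius * np.sin(t)])


def annular_sector_polygon(
    cx: float,
    cy: float,
    r_in: float,
    r_out: float,
    theta0: float,
    theta1: float,
    n_arc: int = 48,
) -> np.ndarray:
    """Polygon of the annular sector r_in..r_out, theta0..theta1 (radians)."""
    t = np.linspace(theta0, theta1, n_arc)
    outer = np.column_stack([cx + r_out * np.cos(t), cy + r_out * np.sin(t)])
    inner = np.column_stack([cx + r_in * np.cos(t[::-1]), cy + r_in * np.sin(t[::-1])])
    return np.vstack([outer, inner])


def _ang_diff(theta: np.ndarray, center: float) -> np.ndarray:
    return (theta - center + np.pi) % (2 * np.pi) - np.pi


def _slice_patches(spec: PhantomSpec, s: int, rng: np.random.Generator):
    """Seeded insular patch centers (x, y) within the infarct wedge."""
    endo_r, epi_r = spec._endo_r(s), spec._epi_r(s)
    depth_r = endo_r + spec.transmurality * (epi_r - endo_r)
    extent = np.deg2rad(spec.infarct_extent_deg)
    area = 0.5 * extent * (depth_r**2 - endo_r**2)
    n = int(round(spec.patch_density * area / (np.pi * spec.patch_radius_mm**2)))
    if n == 0:
        return np.empty((0, 2))
    theta = np.deg2rad(spec.infarct_center_deg) + extent * (rng.random(n) - 0.5)
    r = np.sqrt(rng.uniform(endo_r**2, depth_r**2, size=n))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _grid_center_mm(spec: PhantomSpec) -> Tuple[float, float]:
    dr, dc = spec.in_plane_spacing
    return (spec.n_cols - 1) / 2.0 * dc, (spec.n_rows - 1) / 2.0 * dr


def _class_fractions(
    spec: PhantomSpec, s: int, patches: np.ndarray
) -> np.ndarray:
    """Sub-voxel class area fractions, shape (5, rows, cols)."""
    dr, dc = spec.in_plane_spacing
    cx, cy = _grid_center_mm(spec)
    endo_r, epi_r = spec._endo_r(s), spec._epi_r(s)
    depth_r = endo_r + spec.transmurality * (epi_r - endo_r)
    half_extent = np.deg2rad(spec.infarct_extent_deg) / 2.0
    center = np.deg2rad(spec.infarct_center_deg)
    k = spec.supersample
    counts = np.zeros((5, spec.n_rows, spec.n_cols))
    offsets = (np.arange(k) + 0.5) / k - 0.5
    cols = np.arange(spec.n_cols) * dc
    rows = np.arange(spec.n_rows) * dr
    halo = spec.edema_halo_width_mm
    for oy in offsets:
        for ox in offsets:
            xx, yy = np.meshgrid(cols + ox * dc, rows + oy * dr)
            x, y = xx - cx, yy - cy
            r = np.hypot(x, y)
            theta = np.arctan2(y, x)
            adiff = np.abs(_ang_diff(theta, center))
            wall = (r >= endo_r) & (r <= epi_r)
            in_wedge = wall & (adiff <= half_extent) & (r <= depth_r) \
                if spec.infarct_extent_deg > 0 else np.zeros_like(wall)
            infarct = in_wedge
            if spec.morphology == "patchy" and spec.infarct_extent_deg > 0:
                if len(patches) == 0:
                    infarct = np.zeros_like(wall)
                else:
                    pts = np.column_stack([x[in_wedge], y[in_wedge]])
                    d2 = ((pts[:, None, :] - patches[None, :, :]) ** 2).sum(-1)
                    hit = (d2 <= spec.patch_radius_mm**2).any(axis=1)
                    infarct = np.zeros_like(wall)
                    infarct[in_wedge] = hit
            mvo = np.zeros_like(wall)
            if spec.mvo_core_fraction is not None and spec.infarct_extent_deg > 0:
                mvo_r = endo_r + spec.mvo_core_fraction * (depth_r - endo_r)
                mvo = infarct & (adiff <= spec.mvo_extent_fraction * half_extent) \
                    & (r <= mvo_r)
            edema = np.zeros_like(wall)
            if halo is not None and spec.infarct_extent_deg > 0:
                # arc/radial distance to the wedge region (small-halo approx)
                d_ang = np.maximum(0.0, adiff - half_extent) * np.clip(r, endo_r, None)
                d_rad = np.maximum(0.0, r - depth_r)
                d = np.hypot(d_ang, d_rad)
                edema = wall & ~in_wedge & (d <= halo)
            infarct_only = infarct & ~mvo
            remote = wall & ~infarct & ~edema
            counts[_BG] += ~wall
            counts[_REMOTE] += remote
            counts[_INFARCT] += infarct_only
            counts[_MVO] += mvo
            counts[_EDEMA] += edema
    return counts / float(k * k)


def _build_contours(spec: PhantomSpec) -> ContourSet:
    cx, cy = _grid_center_mm(spec)
    slices = {}
    for s in range(spec.n_slices):
        slices[s] = {
            "endo": circle_polygon(cx, cy, spec._endo_r(s), spec.contour_vertices),
            "epi": circle_polygon(cx, cy, spec._epi_r(s), spec.contour_vertices),
        }
    return ContourSet(slices)


def _coil_field(spec: PhantomSpec) -> np.ndarray:
    """Multiplicative linear sensitivity ramp along +x, amplitude as a
    fraction of unity at the lateral field-of-view edge."""
    if spec.coil_amplitude == 0:
        return np.ones((spec.n_rows, spec.n_cols))
    dr, dc = spec.in_plane_spacing
    cx, _ = _grid_center_mm(spec)
    x = np.arange(spec.n_cols) * dc - cx
    ramp = 1.0 + spec.coil_amplitude * x / x.max()
    return np.tile(ramp, (spec.n_rows, 1))


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate a phantom case; identical specs (incl. seed) are bit-identical."""
    rng = np.random.default_rng(spec.seed)
    contours = _build_contours(spec)
    means = np.array([
        spec.background_mean,
        spec.remote_mean,
        spec.infarct_mean,
        spec.mvo_mean,
        spec.resolved_edema_mean,
    ])
    sds = np.array([0.0, spec.remote_sd, spec.infarct_sd, spec.remote_sd, spec.remote_sd])
    field = _coil_field(spec)

    voxels = np.zeros((spec.n_rows, spec.n_cols, spec.n_slices))
    inf_frac = np.zeros_like(voxels)
    wall_frac = np.zeros_like(voxels)
    noise_model = spec.resolved_noise_model
    for s in range(spec.n_slices):
        patches = _slice_patches(spec, s, rng) if spec.morphology == "patchy" else np.empty((0, 2))
        frac = _class_fractions(spec, s, patches)
        mean_img = np.tensordot(means, frac, axes=1) * field
        sd_img = np.tensordot(sds, frac, axes=1)
        if noise_model == "rician":
            n1 = rng.standard_normal(mean_img.shape)
            n2 = rng.standard_normal(mean_img.shape)
            img = np.hypot(mean_img + sd_img * n1, sd_img * n2)
        else:
            img = mean_img + sd_img * rng.standard_normal(mean_img.shape)
        voxels[:, :, s] = img
        inf_frac[:, :, s] = frac[_INFARCT] + frac[_MVO]
        wall_frac[:, :, s] = frac[[_REMOTE, _INFARCT, _MVO, _EDEMA]].sum(axis=0)

    stack = SliceStack(voxels, spec.in_plane_spacing, spec.slice_thickness, spec.convention)
    mask = rasterize_contours(contours, stack, density=spec.density)

    # ground truth: infarct fraction of each voxel's myocardial content,
    # defined on mask voxels so the support is a subset of the mask
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(wall_frac > 0, inf_frac / np.maximum(wall_frac, 1e-12), 0.0)
    truth = np.where(mask.mask, np.clip(w, 0.0, 1.0), 0.0)
    _, _, truth_fraction = infarct_size(truth, mask)

    case = PhantomCase(
        stack=stack,
        contours=contours,
        rois=RoiSet(),
        mask=mask,
        truth_weights=truth,
        truth_fraction_percent=truth_fraction,
        spec=spec,
    )
    case.rois = RoiSet(
        infarct=auto_infarct_roi(case, margin_mm=spec.roi_margin_mm),
        remote=auto_remote_roi(case),
    )
    return case


def auto_infarct_roi(case: PhantomCase, margin_mm: float = 0.0) -> Dict[int, List[np.ndarray]]:
    """Infarct ROI per slice: the enhancing region (infarct wedge plus edema
    halo, as an observer would see it) dilated by ``margin_mm`` and kept
    within the wall; emitted only on slices where the truth support is
    non-empty (absent infarct => no ROI, so ROI-based methods report zero)."""
    spec = case.spec
    cx, cy = _grid_center_mm(spec)
    halo = spec.edema_halo_width_mm or 0.0
    half_extent = np.deg2rad(spec.infarct_extent_deg) / 2.0
    center = np.deg2rad(spec.infarct_center_deg)
    out: Dict[int, List[np.ndarray]] = {}
    for s in range(spec.n_slices):
        if not case.truth_support[:, :, s].any():
            continue
        endo_r, epi_r = spec._endo_r(s), spec._epi_r(s)
        depth_r = endo_r + spec.transmurality * (epi_r - endo_r)
        r_mid = 0.5 * (endo_r + depth_r)
        pad_ang = (halo + margin_mm) / r_mid
        r_out = min(epi_r, depth_r + halo + margin_mm)
        half = min(np.pi, half_extent + pad_ang)
        out[s] = [annular_sector_polygon(
            cx, cy, endo_r, r_out, center - half, center + half
        )]
    return out


def auto_remote_roi(case: PhantomCase) -> Dict[int, List[np.ndarray]]:
    """Semi-lunar remote ROI diametrically opposite the infarct, at least the
    configured angular margin away from infarct and edema borders."""
    spec = case.spec
    if spec.infarct_extent_deg > 300:
        raise ContractError("no clean remote region: infarct extent > 300 degrees")
    cx, cy = _grid_center_mm(spec)
    margin = np.deg2rad(spec.remote_roi_margin_deg)
    out: Dict[int, List[np.ndarray]] = {}
    for s in range(spec.n_slices):
        endo_r, epi_r = spec._endo_r(s), spec._epi_r(s)
        wall = epi_r - endo_r
        halo_ang = (spec.edema_halo_width_mm or 0.0) / (0.5 * (endo_r + epi_r))
        half_free = np.pi - np.deg2rad(spec.infarct_extent_deg) / 2.0 - halo_ang - margin
        half = min(np.deg2rad(75.0), half_free)
        if half <= 0:
            raise ContractError("no clean remote region after margins")
        center = np.deg2rad(spec.infarct_center_deg) + np.pi
        out[s] = [annular_sector_polygon(
            cx, cy,
            endo_r + 0.1 * wall, epi_r - 0.1 * wall,
            center - half, center + half,
        )]
    return out


def sample_cohort(
    n_cases: int,
    seed: int = 0,
    convention: str = "IR",
    **overrides,
) -> List[PhantomCase]:
    """A heterogeneous study cohort of noisy phantoms.

    Cases vary in infarct extent (40-120 deg), transmurality (0.5-1.0),
    morphology (3:1 solid:patchy) and acute edema halo width (2-4 mm),
    emulating a mixed acute/subacute population with a range of infarct
    sizes.  Per-case seeds derive from ``seed``; identical calls are
    bit-identical.
    """
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n_cases):
        params = dict(
            infarct_extent_deg=float(rng.uniform(40, 120)),
            infarct_center_deg=float(rng.uniform(0, 360)),
            transmurality=float(rng.uniform(0.5, 1.0)),
            morphology="patchy" if rng.random() < 0.25 else "solid",
            edema_halo_width_mm=float(rng.uniform(2.0, 4.0)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        params.update(overrides)
        if convention == "PSIR":
            spec = PhantomSpec.psir(**params)
        else:
            spec = PhantomSpec(**params)
        cases.append(generate_phantom(spec))
    return cases
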