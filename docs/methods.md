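# Methods

This note documents the models, assumptions, defaults and numerical choices
behind `lgequant`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Geometry and bookkeeping

All algorithms share one geometric substrate. Contours are per-slice
polygons in millimetres, with the center of pixel (0, 0) at the origin of
its slice plane. A voxel belongs to the myocardial mask iff its **center**
lies inside the epicardial polygon and outside the endocardial polygon
(even-odd rule); this is deterministic and directly checkable against a
ray-casting oracle, which the test suite does on random star-convex
contours. Distances to the endo/epicardial boundaries are exact Euclidean
point-to-polyline distances (shapely), so the FACT proximity rule ("within
2 mm of the endocardium") does not depend on rasterized border voxels.

Sizes use `volume = Σ wᵢ · v_voxel`, `mass = volume · ρ`, and
`fraction = 100 · mass / m_LV`. The myocardial density ρ defaults to
1.05 g/mL — the standard literature value; published volume filters mix
grams and cm³, and no single density is canonical, so ρ is configurable.
Connected components are 6-connected (4-connected in-plane plus the two
through-plane neighbours), a deliberately conservative choice that does not
chain diagonal noise voxels; the connectivity is exposed in the component
code should a user need 26-connectivity. Angular sectors are equal bins
around the per-slice mask centroid, anchored at the +x image axis
(configurable offset) — phantoms have no anatomical landmark to anchor to.
The midmural band is the set of voxels whose normalized transmural depth
`d = d_endo/(d_endo + d_epi)` lies in [0.25, 0.75]; on walls too thin to
populate the window the layer nearest d = 0.5 is returned so the band is
never empty where the wall exists.

## The quantifiers

**n-SD from remote.** Threshold `μ_r + n·σ_r` from the remote-ROI sample,
applied inside the infarct ROI. The sample SD uses the n−1 denominator
(configurable). Remote/ROI statistics pool over the whole stack by default;
original implementations are ambiguous between per-slice and per-volume
pooling, so both are provided. When no infarct ROI exists on any slice, no
infarct was visually identifiable and the size is zero by contract.

**FWHM.** The half-maximum threshold is `floor + (max − floor)/2`. The
zero anchor (`floor = 0`, i.e. threshold `max/2`) presumes a nulled,
non-negative myocardium and therefore refuses sign-preserving PSIR input;
the remote anchor uses `floor = μ_r`. Whether the maximum is taken per
volume or per slice is again not standardized; both modes exist (volume
pooling is the default). Two variants: `roi_max` (maximum within a drawn
infarct ROI — the variant used for method comparison) and `seed_grow`
(multi-pass region growing from a user seed: grow the 6-connected region at
the current half-maximum, recompute the maximum, repeat to a fixed point,
capped at 100 passes since the original pass structure is unspecified).
Note the anchoring direction: with a *positive* floor (imperfectly nulled
IR), anchoring at zero places the threshold too low and overestimates;
with a *negative* floor (PSIR), `max/2` lies above the remote-to-maximum
midpoint and the zero anchor undershoots instead. Either way the zero
anchor is wrong whenever the true floor is not zero, which is why the
refusal contract exists.

**Otsu.** Exhaustive maximization of between-class variance over cuts
between sorted distinct values, ties resolved to the lowest cut, upper
class defined by `I ≥ t`. Constant input has no bimodal split and is
rejected. Otsu always finds two classes, so it reports a positive fraction
even on infarct-free myocardium — a structural failure mode the harness
makes visible.

**FACT.** Automatic remote (see below) → candidates at `μ_r + 2σ_r` →
feature filters: component mass ≥ 0.1 g, minimum endocardial distance
≤ 2 mm, component mean intensity ≥ 50 % of the pooled mean over all
candidate voxels → remote-anchored FWHM inside the survivors → filters
re-applied → MVO inclusion. "Average of all potential infarct areas" is
read as the pooled voxel mean rather than the mean of component means
(simpler, stable under component splits; configurable threshold fraction).
The candidate average is not recomputed after the FWHM pass. All comparisons
retain components exactly at a cutoff (strict-below removal).

**Heiberg-08.** Five sectors per slice; the midmural half of the
lowest-mean sector defines remote. Threshold `μ_r + 1.8σ_r`, artifact
cleanup, removal of isolated volumes < 1.5 cm³, MVO inclusion, then linear
intensity weighting `w = clip((I − μ_r)/(I_max − μ_r), 0, 1)` with `I_max`
the maximal myocardial intensity of the stack. The anchor points of the
published "linear weighting" are not spelled out anywhere; anchoring at the
remote mean and the stack maximum makes a pure-remote voxel weigh 0 and a
plateau voxel weigh 1, which is the only choice consistent with the
method's partial-volume rationale. IR only: the weighting and thresholds
presume non-negative, nulled myocardium, so PSIR input is refused. MVO
detection keys on the *enhanced* support (weight > 0); supported voxels at
exactly the remote mean carry zero weight and do not count as an enclosing
infarct border (otherwise a zero-noise stack would fill its own
partial-volume rim).

**EWA.** Coil correction → two-Gaussian EM on the myocardial intensities →
infarct = posterior > 0.5 → cleanup and removal of components < 0.1 g →
MVO inclusion → linear weighting `w = clip((I − μ_n)/(μ_i − μ_n), 0, 1)`,
MVO voxels at weight 1. The constrained EM reduces published constraints to
mean ordering (`μ_i > μ_n`, enforced by relabeling, which leaves the
likelihood unchanged) plus an SD floor of 10⁻³ of the intensity range. The
fit is declared *degenerate* — no infarct evidence, size zero with a
warning — when Ashman's `D = (μ_i − μ_n)/√((σ_n² + σ_i²)/2) < 2` or the
infarct mixing weight falls below 1 %; D = 2 is the standard bimodality
separation boundary, and a single Gaussian split in two typically lands
near D ≈ 1.5–1.9.

**Automatic remote detection** (shared by FACT, Heiberg-08): per slice,
the sector with the lowest mean intensity; pooled midmural voxels of the
selected sectors give μ_r, σ_r. FACT's published description thresholds
"from remote" while using only LV contours and never defines remote; this
implementation reuses the sector rule. An optional sanity bound on σ_r
warns when the estimate is likely contaminated (e.g. circumferential
infarct leaves no viable sector).

**Coil correction.** The multiplicative sensitivity field is a low-order
polynomial (default total degree 2 in normalized x, y, z) fit to the log
intensities of the *viable* myocardial class. Enhancing voxels are
spatially coherent, and a polynomial would absorb a bright sector wholesale,
so the upper Otsu class is excluded from the fit up front and the remainder
is refined with iteratively reweighted least squares (Tukey bisquare,
scale = 1.4826·MAD floored at 10⁻³ of the log spread so exactly
piecewise-constant data cannot collapse the weights). Degree 2 rather than
1 because the log of a linear ramp `log(1 + a·u)` has curvature that a
plane underfits at a = 0.3. The centered log field is clipped to ±1.5
(≈ 4.5-fold dynamic range) as a guard rail, the image is divided by the
field, and the myocardial median is preserved. PSIR input is shifted into
the positive domain by `−min + 10⁻³·range` for the log fit and shifted
back afterwards. On a bias-free stack the procedure is an identity to
within 0.5 %, verified in the tests.

**MVO inclusion** (FACT, EWA, Heiberg-08). Microvascular obstruction is a
hypointense core inside enhancing infarct and counts as infarct. Per slice,
a 4-connected non-infarct myocardial component is filled when every
in-plane boundary neighbour is an infarct voxel or lies across the
endocardial border; touching viable wall or the epicardial side
disqualifies it. The purely threshold-based methods perform no MVO
handling, matching their published behaviour.

**Artifact cleanup** (Heiberg-08, EWA). The published pipelines cite a
level-set exclusion step whose formulation is not described alongside the
algorithm tables; this package substitutes a deterministic equivalent of
its *function* — discard discontiguous artifacts: keep components
3D-connected to the largest candidate or above a 0.1 g mass floor, then one
in-plane opening–closing pass with a 3×3 cross. Exact level-set evolution
is out of scope.

## The phantom

The generator emulates the image features the algorithms key on, not MRI
physics. Defaults describe a typical 1.5 T short-axis LGE protocol: 8
slices of 8 mm with no gap, 1.5 × 1.5 mm in-plane on a 64×64 grid, annular
wall with endocardial radius 20 mm and epicardial 30 mm (per-slice radii
may taper). The infarct is an angular wedge from the endocardium outward
to the configured transmural depth — default 72° and fully transmural, so
the analytic truth is 20 % of LV mass and every recovery bias is read
against a round number. Patchy morphology scatters seeded disks (default
radius 2 mm, density 0.6) inside the wedge, mimicking insular mixes of
viable and non-viable tissue; patchy truth is strictly below solid truth at
equal wedge parameters. Options add a hypointense MVO core (subendocardial,
open to the endocardium, enclosed by infarct laterally) and a peri-infarct
edema halo of configurable width whose intensity defaults to
`μ_r + 0.4·(μ_i − μ_r)` — acute edema enhances to an intermediate degree,
and no quantitative consensus value exists, so the level is a free
parameter between the class means.

Intensities: class means default to remote 20, infarct 100 (five-fold
enhancement over a near-nulled wall), class SDs 5. Sub-voxel class
membership is computed on a 4× in-plane supersampling grid; the voxel mean
and noise SD are area-weighted mixtures of the class parameters (partial
volume), the mean is multiplied by a linear lateral coil ramp of
configurable amplitude, and noise is applied per convention — Rician for IR
magnitude (`√((μ+σZ₁)² + (σZ₂)²)`, guaranteeing non-negativity) and
additive Gaussian for PSIR. The PSIR preset sets the remote mean to
−0.2 × infarct mean to exercise the zero-anchoring contracts. The
ground-truth weight of a voxel is its infarct area **as a fraction of its
myocardial content** (infarct subsamples / wall subsamples): the LV-mass
denominator counts mask voxels at full volume, so this definition makes
the noise-free truth fraction an unbiased estimator of the analytic wedge
fraction (within 0.5 %-points on the default grid) and keeps binary
methods comparable at the arc boundaries.

Auto-drawn ROIs mirror observer behaviour: the infarct ROI is the
enhancing region (wedge plus edema halo — an observer cannot distinguish
enhancing edema from infarct) dilated by a configurable margin and kept
within the wall, emitted only on slices with true enhancement; the remote
ROI is a semi-lunar annular sector diametrically opposite the infarct, at
least 20° away from infarct and edema, spanning the middle 80 % of the
wall. Infarcts wider than 300° leave no clean remote sector and are
rejected.

The heterogeneous study cohort (`sample_cohort`) draws extent from
U(40°, 120°), transmurality from U(0.5, 1), morphology 3:1 solid:patchy,
and edema width from U(2, 4) mm, emulating a mixed acute/subacute
population. The edema halo is what drives the characteristic *n*-SD
overestimation ordering: a 2-SD threshold sits below the edema intensity
and sweeps the halo in; 6 SD clips most of it; FWHM and the EM-based
methods anchor near the infarct plateau and exclude it.

What passing tests on this phantom do **not** show: behaviour under real
anatomy (trabeculation, papillary variation, breath-hold misregistration),
surface-coil fields that are not low-order polynomials, imperfect nulling
drift across slices, or human contouring variability. The phantom
isolates algorithmic behaviour; it cannot certify clinical accuracy.

## Numerical choices

* Threshold comparisons are inclusive (`≥`) everywhere, making uniform
  plateaus deterministic (a uniform ROI is entirely selected by FWHM).
* Mass/volume cutoffs remove strictly below the cutoff; a component exactly
  at the cutoff is retained (comparisons carry a 10⁻⁹ g slack against
  float rounding).
* EM converges when the log-likelihood gain drops below 10⁻⁸ or at 200
  iterations; the trace is recorded per iteration and is non-decreasing up
  to 10⁻⁹ floating-point slack.
* Otsu's between-class variance is computed from cumulative sums over the
  sorted sample — numerically identical to the brute-force definition but
  O(n log n).
* Lin's CCC uses population (n-denominator) moments as in the original
  formulation; a flag switches to n−1. The limits-of-agreement multiplier
  is fixed at 1.96. The bias test is a two-sided one-sample *t*-test of
  the differences; all-zero differences give p = 1, constant non-zero
  differences give p = 0 (degenerate SD = 0 cases bypass the t
  distribution).
* Phantom generation, cohort sampling and every segmentation are
  deterministic given the seed; identical seeds give bit-identical stacks
  and reports.

## Problem sizes

The test suite and the acceptance script run phantoms at the default
64×64×8 grid (≈ 5700 myocardial voxels), cohorts of 20 cases, EM recovery
at n = 10,000 over 20 seeds, and Otsu oracle comparison over 100 samples of
up to 2000 values — sizes at which every oracle is exact and the full suite
completes in well under a minute of compute.

## Known limitations

* The FACT/Heiberg-08/EWA reimplementations follow the published step
  tables; where those tables are silent (remote definition for FACT, level
  set formulation, weighting anchors, FWHM pooling scope), this package
  makes the documented choice above and exposes it in configuration. Exact
  numerical agreement with the original vendor implementations is not
  claimed.
* `include_mvo` is purely topological; it does not model the temporal
  dynamics that distinguish MVO from slow-filling core on real images.
* The seeded region-growing FWHM variant depends on the seed voxel when the
  enhancing region is disconnected, as in the original formulation.
* PSIR support treats the signed values as-is; vendor-specific intensity
  offsets must be removed upstream.
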