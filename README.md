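# lgequant

Infarct quantification for late gadolinium enhancement (LGE) cardiac MRI.

After gadolinium contrast, infarcted myocardium retains the agent and
appears bright on T1-weighted short-axis images, while viable ("remote")
wall is nulled and dark. Many algorithms turn that contrast into an infarct
size, reported as a percentage of left-ventricular (LV) mass — and they
disagree with each other enough that the choice of algorithm materially
changes trial results. `lgequant` implements the widely used quantifiers as
one tested library so their behaviour can be compared under controlled
conditions:

| method | idea | input | conventions |
|---|---|---|---|
| *n*-SD from remote | threshold at `μ_remote + n·σ_remote` (n = 2, 3, 5, 6) | remote + infarct ROI | IR, PSIR |
| FWHM | threshold at half of the maximal infarct intensity, anchored at 0 or at `μ_remote`; ROI-max and seeded region-growing variants | infarct ROI or seed | IR (zero anchor) |
| Otsu | cut maximizing between-class variance of the myocardial histogram | contours only | IR, PSIR |
| manual | user-supplied threshold inside the myocardium | threshold | IR, PSIR |
| FACT | 2-SD candidates → feature filters (≥ 0.1 g, ≤ 2 mm from endocardium, ≥ 50 % of pooled candidate intensity) → remote-anchored FWHM → filters again → MVO fill | contours only | IR, PSIR |
| Heiberg-08 | 5 sectors/slice, midmural half of the darkest sector as remote → 1.8-SD threshold → cleanup, drop volumes < 1.5 cm³ → MVO fill → linear intensity weighting | contours only | IR |
| EWA | coil-sensitivity correction → two-Gaussian EM on myocardial intensities → posterior classification → cleanup → MVO fill → linear intensity weighting | contours only | IR, PSIR |

Weighted methods report `Σ wᵢ · v_voxel · ρ / m_LV` with
`wᵢ = clip((Iᵢ − μ_normal)/(μ_infarct − μ_normal), 0, 1)`, so partial-volume
voxels count fractionally; binary methods count every supra-threshold voxel
fully.

Because no public ex-vivo reference dataset exists at desk scale, the
package ships a **synthetic short-axis phantom**: an annular LV wall
(default 8 slices, 1.5 × 1.5 × 8 mm, endo 20 mm / epi 30 mm) with a bright
infarct sector of configurable transmurality, extent and morphology (solid
or patchy/insular), optional hypointense MVO core and peri-infarct edema
halo, multiplicative coil ramp, and Rician (IR) or Gaussian (PSIR) noise.
Partial volume is modelled by 4× in-plane supersampling, and the noise-free
sub-voxel infarct fraction is retained as ground truth — it plays the role
of the ex-vivo reference. An **agreement harness** then produces the
standard comparison statistics: modified Bland–Altman bias ± SD against the
reference, 95 % limits of agreement (bias ± 1.96 SD), Lin's concordance
correlation coefficient, OLS regression and a one-sample *t*-test of the
bias.

Audience: imaging scientists and cardiology researchers who need a
reference implementation of these algorithms, a ground-truth testbed for
new quantifiers, or the agreement statistics themselves.

## Worked example

```python
from lgequant import PhantomSpec, generate_phantom, segment_nsd, segment_ewa

case = generate_phantom(PhantomSpec(seed=7))
print(f"truth: {case.truth_fraction_percent:.2f} % of LV mass")
seg = segment_nsd(case.stack, case.mask, case.rois, n=2)
print(f"2-SD:  {seg.fraction_of_LV_percent:.2f} %")
seg = segment_ewa(case.stack, case.contours)
print(f"EWA:   {seg.fraction_of_LV_percent:.2f} %")
```

```
truth: 19.79 % of LV mass
2-SD:  19.77 %
EWA:   18.88 %
```

The 72° fully transmural default wedge covers 72/360 = 20 % of the annulus;
both methods recover it to within a fraction of a percentage point on this
clean solid infarct. The scripts in `examples/` walk through each
capability; `examples/04_agreement_harness.py` runs every method over a
heterogeneous 12-case cohort (varying extent, transmurality, morphology and
edema) and prints the comparison table:

```
   method   ccc  slope  intercept   bias  sd_diff  loa_low  loa_high  p_value
      ewa 0.880  1.194     -2.844 -0.311    3.019   -6.228     5.607    0.728
heiberg08 0.931  0.729      3.421 -0.110    1.741   -3.523     3.303    0.831
     fwhm 0.943  1.004      1.576  1.633    0.726    0.210     3.057    0.000
      2sd 0.371  0.824     10.232  7.938    3.231    1.604    14.271    0.000
      3sd 0.434  0.879      8.803  7.226    2.854    1.631    12.820    0.000
      5sd 0.595  0.971      5.905  5.526    2.050    1.508     9.545    0.000
      6sd 0.739  1.000      4.053  4.052    1.472    1.167     6.938    0.000
     otsu 0.762  0.781      5.702  2.843    2.236   -1.540     7.226    0.001
     fact 0.990  1.033     -0.358  0.067    0.754   -1.412     1.545    0.766
```

The intensity-weighted and feature-based methods (EWA, Heiberg-08, FACT)
and FWHM track the reference closely; the *n*-SD family overestimates —
most at 2 SD, least at 6 SD — because low thresholds sweep up the
enhancing edema halo and noise, and Otsu reports infarct even when none is
present.

## Command line

```bash
lgequant phantom generate --seed 3 --out case/        # stack + truth + geometry
lgequant segment run --method ewa --stack case/stack.nii \
    --contours case/geometry.json --report report.json
lgequant phantom cohort --n 20 --seed 1 --out cohort/
lgequant compare --cases cohort/ --methods all --out table.csv
```

Stacks travel as NIfTI-1, contours/ROIs as per-slice polygon JSON in mm,
reports as JSON with the resolved configuration and seed echoed.

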