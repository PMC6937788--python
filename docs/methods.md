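# Methods

This note documents the models, conventions and numerical choices behind
`lvflow`, what the synthetic data do and do not emulate, and the known
limitations.

## Data model and conventions

Velocity components are stored per cardiac frame on a regular grid,
`(x, y, z, frame)`, in cm/s along the grid axes; the cavity mask shares the
grid.  Voxel indices are 0-based, continuous positions are in mm at voxel
centers (world = index × spacing), and co-registration of the velocity and
cine grids is assumed upstream — the reader rejects any grid mismatch rather
than resampling silently.  The cardiac cycle is periodic with duration
`rr_interval`; frame *k* samples time *k·T/N*.  The apex→base direction is a
property of the segmentation (`slice_axis`, `apex_to_base_sign`) and is
applied analytically at computation time; stored data are orientation-neutral
and never mutated.  Speeds above the velocity-encoding limit are flagged in a
quality report but not rejected, since clipping would bias flow sums.

## Background phase correction

Phase-contrast velocity offsets are modeled as a temporally constant,
spatially smooth field: a 3rd-order 3-D polynomial (20 terms
{x^a y^b z^c : a+b+c ≤ 3}) fitted per component to the temporal-mean
velocity of static tissue by least squares, then subtracted from every
frame.  Choices worth noting:

* **Fit target = temporal mean.**  Background error is time-constant, so the
  correction provably never alters temporal fluctuations (v − mean_t v is
  preserved up to round-off).
* **Normalized coordinates.**  The basis is evaluated in [−1, 1] per axis
  tied to the grid extent; a raw-mm cubic design is numerically
  ill-conditioned.  A condition number above 1e8 (e.g. static voxels confined
  to a plane) raises with the offending geometry reported.
* **Static-tissue criterion.**  There is no canonical definition of "static
  tissue"; we use the temporal SD of the velocity *vector*,
  √(Σ_c Var_t v_c), thresholded at a configurable percentile (default 30th)
  of in-body voxels.  The vector-fluctuation form (rather than the SD of the
  speed) makes the statistic invariant under constant offsets — the very
  artifact being estimated.  A 1e-9 cm/s absolute tolerance absorbs variance
  round-off in effectively constant voxels.  Phantom tests bypass the
  heuristic with the known exterior mask.

Maxwell-term and velocity-aliasing corrections are out of scope (assumed
handled at reconstruction).

## Regional through-plane flow

The ED long-axis extent runs from the center of the apical-most to the
basal-most in-mask slice; it is divided into three equal-length physical
thirds (closed-open from apex, basal interval closed at the top) and each
slice is labeled by its center coordinate.  Slice flow is
`mean(v⊥ over in-mask voxels) × (in-mask voxel count × in-plane voxel area)`
in cm³/s, ×0.06 for L/min.  The cross-sectional area is the *per-frame* mask
area, following the time-resolved segmentation, not the ED area.  Regional
curves weight member slices equally (not by area); slices empty at a given
frame are skipped and logged.  Peak systolic/diastolic flows are the
max/|min| of the regional curve, earliest frame on ties.

Kinetic energy is whole-LV only: the squared-velocity sum is dominated by
high-velocity voxels, which makes regional KE (particularly the slow-flow
apex) too noise-sensitive to be meaningful.  `KE_avg` is the cycle average of
Σ ½ρV|v|² over in-mask voxels (ρ = 1.06 g/cm³; erg → μJ ×0.1), indexed to
EDV.

## Pathline compartments

Pathlines are emitted at the centers of ED-mask voxels (density 1, 1/2 or
1/4 with in-plane decimation; each seed carries the blood volume it
represents) and integrated with classic fixed-step RK4, step = frame
interval / substeps (default 10; fixed step for bit-reproducibility).
Velocity is sampled trilinearly in space and linearly in cardiac phase with
periodic wrap, so a spatially linear, temporally piecewise-linear field is
integrated essentially exactly.  Trajectories leaving the grid are clipped
and frozen; non-finite velocities invalidate (and exclude) the pathline.

End diastole/systole default to the frames of maximum/minimum cavity volume
(earliest on ties), overridable in config.  Inside/outside is evaluated
against the temporally nearest mask frame with nearest-voxel lookup — masks
are discrete in time, and this convention is ours.  Classification: blood
*entered* if outside the LV at the previous-ES end of the backward trace and
*left* if outside at the ES end of the forward trace, giving direct
(entered ∧ left), retained inflow (entered ∧ ¬left), delayed ejection
(¬entered ∧ left) and residual volume (¬entered ∧ ¬left).  Any mask
boundary crossing whose slice is labeled mid or apex excludes the pathline
as a wall transit; crossings in the base third — including beyond the
basal-most slice (valve plane) and through the lateral boundary of a basal
slice — count as valid transits.  Compartment percentages are volume
weighted over non-excluded pathlines and sum to 100 by construction; the
excluded share is reported over all emitted pathlines as a QC figure (on
patient data roughly a quarter of pathlines can be discarded this way; on
the phantoms it is near zero).

Note a consequence of the moving-wall convention visible in the deforming
phantom: stationary blood near the wall is overtaken by the contracting
mask and registers as a wall crossing, which is exactly the situation the
mid/apex exclusion rule is designed to discard.

## Cavity function and infarct size

Volumes are voxel counts × voxel volume per frame (Simpson-style slice
summation; no surface fitting).  EDV/ESV are the curve extremes, SV their
difference, EF = 100·SV/EDV, CO = SV·HR/1000.  Papillary-muscle and
outflow-tract handling follows whatever convention the input mask used.
Infarct size is the mean of 17 AHA-segment transmurality scores (0–4)
divided by four, as a percentage; it is monotone in every segment score and
bounded in [0, 100].

## Cohort statistics

Each flow parameter is modeled as
`outcome ~ 1 + group + age + sex + heart_rate` (OLS; group AMI=1, sex M=1,
so flow reductions in the infarct group appear as negative group
coefficients).  CIs and p-values use the t distribution on residual degrees
of freedom.  **No multiple-testing correction is applied across the 11
parameters** — each model is tested separately at α = 0.05; interpret
accordingly.  Welch's unequal-variance t-test is used for continuous
demographics (the pooled variant is a defensible alternative; the choice is
documented, not inferred), chi-squared without continuity correction for sex
proportions, and flow parameters are summarized as median ± IQR with
linear-interpolation quartiles (they are not assumed normal).  Spearman's
rho is the Pearson correlation of mid-ranks; its two-sided p-value uses the
t approximation for n > 10 and exact enumeration of all n! pairings for
n ≤ 10 (vectorized in chunks).

## Synthetic phantoms: what they emulate and what they do not

**Deforming half-ellipsoid ventricle.**  Wall radius
`r_w(z,t) = R(t)·√(1 − ((L−z)/L)²)`, `R(t) = R0(1 − α sin²(πt/T))`; the
first half-cycle is systolic, so ED is frame 0 and systolic flow is
positive under the apex→base convention.  Axial velocity is uniform per
cross-section and chosen so slice flux exactly balances the apical volume
change (`Q(z,t) = −∂V/∂t`, closed form); radial velocity `v_r = (R′/R)·r`
follows the wall.  Defaults (R0 = 2 cm, L = 8 cm, α = 0.2, 20 frames,
1.25 mm isotropic grid) give EDV ≈ 67 mL and EF = 1 − (1−α)² = 36%;
cohort materialization uses α ≈ 0.45 (controls) vs 0.25 (infarct) so EF
lands near 70% vs 44%, with R0 ≈ 1.7 cm and L = 7 cm to fit the reduced
grid, and the cycle length follows each subject's heart rate.

**Plug-flow cylinder.**  Static mask, spatially uniform axial velocity:
positive during systole (total displacement d_out), negative during
diastole (d_in).  Because motion is a rigid axial shift, the compartments
reduce to exact 1-D slab overlaps: direct = min(d_in,d_out)/L, retained =
max(0, d_in−d_out)/L, delayed = max(0, d_out−d_in)/L, residual = rest.  Two
discretization choices make the oracle exact rather than merely close: the
per-frame velocity samples are chosen so the tracker's piecewise-linear
time interpolation integrates to exactly ±d (RK4 is exact for polynomial
integrands when steps align with frame boundaries), and the axial mask
interval is half-open so L/Δz voxel slabs tile the length exactly.

**Cohort simulator.**  Outcomes = baseline + covariate effects + planted
group effect + Gaussian residual.  Covariate distributions default to a
young-volunteer control group (40±16 y, 60±10 bpm, 10/19 male) versus an
older infarct group (66±12 y, 79±15 bpm, 11/12 male), so the unadjusted
group contrast is confounded by construction and the default planted
effects (e.g. −3.9 L/min mid-ventricular systolic flow, −41 points direct
flow) are recoverable only by the adjusted model.  Default residual SD is
1 outcome unit; neither reconstruction noise level has a published value,
so image-noise SD is a free parameter (cohort materialization uses
0.5 cm/s).

Not emulated: MR physics (k-space sampling, VENC aliasing, eddy currents
beyond the cubic term), valve geometry, trabeculation, diastolic/systolic
asymmetry of real filling patterns, turbulence, and registration error.
Passing phantom tests therefore demonstrates correctness of the *analysis*
(geometry, integration, classification, statistics), not robustness to
acquisition artifacts.

## Problem sizes and numerical tolerances

Phantom validation runs at the full 1.25 mm / 20-frame study resolution;
the 31-subject cohort demonstration uses a 2.5 mm grid, quarter-density
seeding and 4 substeps, which keeps a full double run around two minutes
while leaving all group effects detectable.  Tolerances in the validation
suite: slice flow within 3% of the analytic peak (voxelized area error),
EDV within 2%, EF within 2 points, compartment fractions within 2
percentage points, noiseless phase-coefficient recovery to 1e-8 relative,
RK4 rotation closure to 1e-4 cm at h = 0.01 s.  "Exact" float assertions
are made at 1e-12 where subtraction reorders rounding.

## Known limitations

* Strain covariates are accepted as pre-computed inputs only; no
  feature-tracking is implemented.
* The regional average weights slices equally; area weighting is a
  defensible alternative for strongly tapered ventricles.
* Wall-crossing detection is limited by the temporal resolution of the mask
  (nearest-frame lookup) and by the sampling stride of the trajectory.
* The low-noise second reconstruction used for pathline tracking in
  practice is accepted as an optional input; producing it is out of scope.
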