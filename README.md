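# lvflow — regional left-ventricular 4D-flow analysis

`lvflow` analyzes time-resolved, three-directionally encoded velocity fields
of the left ventricle (4D-flow MRI) together with a time-resolved cavity
segmentation, and asks *where* in the ventricle blood transport is impaired.
It is aimed at cardiovascular imaging researchers studying regional flow
changes after anterior myocardial infarction, where blood stasis in the LV
apex is a suspected substrate for thrombus formation.

The pipeline computes, per subject:

* **Regional through-plane flow.** The LV long axis is split at end diastole
  into three equal-length segments — base, mid-ventricle, apex.  For each
  short-axis slice and cardiac frame, flow `Q = v̄⊥ · A` (mean through-plane
  velocity × luminal cross-sectional area), with apex→base positive; the
  regional curve averages the member slices, and peak systolic (max) and
  diastolic (|min|) flows are extracted per region.
* **Kinetic energy indexed to EDV.**
  `KE_avg = (1/N_t) Σ_t Σ_vox ½ ρ V_vox |v_vox|²` with ρ = 1.06 g/cm³,
  reported in μJ and divided by end-diastolic volume (KEi_EDV, μJ/mL).
* **Flow compartments.** Pathlines are emitted from every ED cavity voxel and
  integrated forwards and backwards in time (end systole to end systole,
  classic fixed-step RK4, trilinear + periodic-linear velocity sampling).
  End-diastolic blood is split into *direct flow*, *retained inflow*,
  *delayed ejection flow* and *residual volume*; pathlines crossing the wall
  in the mid-ventricle or apex are excluded.
* **Cavity function** (EDV/ESV/SV/EF/CO by voxel counting) and **infarct
  size** (17-segment transmurality scores, averaged and divided by four).

At the cohort level, each of the 11 flow parameters (3×2 regional peaks,
KEi_EDV, 4 compartment percentages) is compared between groups with an OLS
model `flow ~ group + age + sex + heart_rate`; regional flows are correlated
with heart rate and standard CMR measures (Spearman), and demographics are
compared with Welch t-tests / chi-squared.

Because clinical 4D-flow datasets are rarely shareable, the package includes
a first-class synthetic generator: a deforming half-ellipsoid ventricle with
closed-form slice flux and volume curves, a plug-flow cylinder whose
compartment fractions reduce to exact 1-D slab overlaps, planted cubic
background-phase offsets, velocity noise, and a two-group cohort simulator
with covariate-confounded planted effects.  Every stage of the pipeline is
validated against these analytic truths.

## Worked example

```bash
# synthesize a 31-subject cohort (19 controls, 12 infarct subjects) with
# per-subject phantom image data, then analyze it
lvflow simulate --n-control 19 --n-ami 12 --seed 5 -o cohort/
lvflow analyze-cohort cohort/ -o results/ --substeps 4
lvflow report results/
```

`analyze-cohort` prints

```
{"out_dir": "results", "n_subjects": 31, "n_failed": 0}
```

and `results/flow_summary.csv` contains one row per flow parameter; from the
run above (rounded):

```
parameter               control_median  ami_median   delta  ci_low  ci_high  p_value
peak_systolic_flow_base           4.37        3.80   -2.15   -2.97    -1.33   <0.001
kei_edv                           2.05        1.31   -1.58   -2.13    -1.03   <0.001
direct_flow_pct                  73.66       47.05  -25.58  -31.27   -19.90   <0.001
residual_volume_pct              25.23       49.99   23.96   18.25    29.68   <0.001
```

`delta` is the covariate-adjusted AMI-minus-control difference: the phantom
cohort plants weaker contraction in the infarct group, and the pipeline
recovers reduced regional flow, reduced KEi_EDV and a shift from direct flow
toward residual volume, mirroring the qualitative physiology.  The
per-subject table (`subjects.csv`), demographics comparison and Spearman
correlation table are written alongside, plus a `manifest.json` with the
config hash and seeds needed to reproduce the run exactly.

All quantities can equally be computed in Python; see
`lvflow.pipeline.analyze_subject` and the module docstrings.

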