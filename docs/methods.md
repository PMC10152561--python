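# Methods

## Quotient-diagram analysis of intrathecal immunoglobulin synthesis

Albumin is produced only outside the CNS, so the CSF/serum albumin quotient
Q_alb is a pure barrier-function marker; immunoglobulin quotients Q_Ig mix
barrier passage with possible local synthesis.  The package separates the
two with the hyperbolic discrimination function

    Q_lim(Q_alb) = a · sqrt(Q_alb² + b²) − c

using the canonical class constants (a, b², c): IgG (0.93, 6×10⁻⁶,
1.7×10⁻³), IgA (0.77, 23×10⁻⁶, 3.1×10⁻³), IgM (0.67, 120×10⁻⁶, 7.1×10⁻³).
All three are configurable (`ReiberConstants`); the defaults are the widely
used reference values.  Barrier dysfunction is Q_alb above the age-adjusted
limit (4 + age/15)×10⁻³, with the coefficient pair likewise configurable.
A quotient above Q_lim yields the intrathecal fraction
(1 − Q_lim/Q_Ig)·100 % and the absolute CSF-local concentration
(Q_Ig − Q_lim)·Ig_serum (mg/L) — a concentration, not a daily synthesis
rate.  Quotients are held as plain dimensionless numbers internally; the
clinical ×10³ convention is applied only in reports, which avoids
double-scaling errors.  Oligoclonal-band status is carried as data; no
computation is defined on it.

Numerics: the isolines of constant intrathecal fraction f are
Q_lim/(1 − f/100), so fraction→isoline→fraction round-trips are exact to
floating precision; this is asserted at 10⁻¹² relative tolerance.  Q_lim is
strictly increasing and convex in Q_alb for all positive constants, checked
on a dense grid.

## Voxel-wise CSF-distance gradient

Per patient, on one axis-aligned co-registered grid:

1. CSF mask: probability map thresholded at **0.95** (inclusive ≥); the
   conservative threshold avoids overestimating CSF spaces.  Oblique affines
   are rejected at load — registration/resampling is upstream of this tool.
2. NAWM = white matter ∧ ¬(lesions).
3. Distance map: exact Euclidean distance transform (scipy), voxel center to
   nearest CSF voxel center, honouring anisotropic spacing, in mm.
4. Exclusions: all voxels with distance < **2 mm** are dropped (strict <, so
   voxels at exactly 2 mm survive); lesion voxels whose distance to the
   nearest non-lesion voxel center is < **1.5 mm** are dropped (inward edge
   erosion).  The erosion reading targets lesion-edge partial volume, which
   the CSF band does not cover; the alternative reading (lesion voxels
   within 1.5 mm of CSF) is available as `lesion_rule: csf_distance` and is
   subsumed by the 2 mm band.  On a 1 mm grid a sphere of radius 1.4 mm
   contributes no voxels under the erosion rule.
5. Voxel table: one record (patient, class, distance, ADC) per surviving
   voxel; lesion labels take precedence over NAWM and the two lesion classes
   must be disjoint.

The gradient per tissue class is the Spearman rank correlation of ADC with
distance (the package's default correlational method; Pearson is available)
together with the ordinary-least-squares slope in mm²/s per mm, which
quantifies the linear decline whatever the correlation method.  Voxels are
pooled across patients within a group; a per-patient summary level exists
for median/IQR tables (each patient's class median first, then the
across-patient summary — the unit for paired within-patient comparisons).

Group comparison uses the independent-samples Fisher r-to-z statistic with
the pooled voxel counts.  Caveat, stated deliberately: voxels within a
patient are not independent, so these z values overstate effective evidence;
they are used as a within-study comparison device, not as population
inference.  The IgG dichotomization splits patients at the cohort median
quotient; ties go to "low", and for even n the median is the midpoint of the
central order statistics.  Both z-matrix orientations (between groups within
class, between classes within group) are emitted; matrices are
skew-symmetric with zero diagonal, and degenerate |r| = 1 entries (possible
in noiseless simulations) are excluded from comparison.

## Nonparametric cohort statistics

Rank-sum (Mann–Whitney U), signed-rank (Wilcoxon) and Pearson chi-squared
tests back the group tables, implemented over scipy with explicit
small-sample rules: exact enumeration when the pooled sample is ≤ 12 without
ties (rank-sum) or there are ≤ 12 non-zero tie-free differences
(signed-rank), otherwise the normal approximation with midrank-tie and
continuity corrections.  Chi-squared uses no continuity correction by
default, so identical count rows give p = 1.0 exactly.  Quartiles use linear
interpolation of order statistics.  p-values are reported unadjusted, as is
conventional for descriptive cohort tables; a Holm flag exists.

## Synthetic phantom

Geometry: an ellipsoidal ventricle (default semi-axes 10×14×10 mm at the
grid center) and a 2 mm CSF shell just inside the grid boundary give inner
and outer CSF surfaces; a 3 mm cortical band sits inside the shell; the rest
is white matter with spherical lesions labelled iron-rim (IRL) or non-rim.
Default grid 64³ voxels at 1 mm isotropic.

Signal: ADC(v) = baseline[class] − slope[class] · min(d(v), range) + ε with
ε ~ N(0, noise_sd), where d(v) is the **continuous** geometric distance of
the voxel center to the nearest CSF surface (exact point-to-ellipsoid
distance via a bisection solver, verified against an independent optimizer
to 10⁻⁸ mm).  Imposing the decline on true distance rather than on the
discrete transform makes distance-transform discreteness part of what the
recovery experiments measure.  Defaults: baselines 1.15/1.05/0.85 ×10⁻³
mm²/s for IRL/non-rim/NAWM (preserving the empirical severity ordering with
lesions more damaged than NAWM); decline slopes 10/8/6 ×10⁻⁶ mm²/s per mm
(about 1% of baseline per mm, the order of reported periventricular
gradients); gradient range 20 mm (keeps ADC positive everywhere on the
default grid); noise SD 1×10⁻⁴ mm²/s (typical ADC voxel noise).  The
probability maps are binary by default (optionally smoothed), so the 0.95
threshold recovers the true CSF mask exactly.

Cohort: two groups of 51 profiles ("IRL+"/"IRL−") with intrathecal-IgG
prevalences 37/51 ≈ 0.73 and 28/51 ≈ 0.55; Q_alb log-normal around a median
of 5×10⁻³ (log-SD 0.4); given synthesis, the intrathecal fraction is uniform
on [5, 65] % and the profile is built by inverting the hyperbola
(Q_IgG = Q_lim/(1 − f/100)), so classification round-trips exactly.  Serum
concentrations are normal with physiologic means (albumin 42 g/L, IgG
10 g/L, IgA 2.2 g/L, IgM 1 g/L).  IgA/IgM synthesis prevalences are 0.09 and
0.28 in both groups.  The joint study simulation images a subset of each
group (default 5 per group — imaging the whole cohort adds cost without
changing the contrast) and scales decline slopes ×1.5 in patients with
intrathecal IgG synthesis, coupling humoral CNS inflammation to a steeper
damage gradient.  These distributional choices are generator conventions,
not estimates; anything not fixed above is a stated default in the spec
dataclasses.

What the phantom does **not** emulate: MRI physics (bias fields, k-space,
rim susceptibility), cortical folding, registration error, non-spherical
lesions, spatially correlated noise.  Passing tests therefore demonstrate
correctness of the computational chain under the stated generative model,
not robustness to real-data artifacts.

## Validation experiments and their design

- **Distance transform**: compared voxel-by-voxel against the all-pairs
  minimum on 20 random 16³ masks, isotropic and (1,1,3) mm spacing;
  agreement is exact (< 10⁻⁹ mm).
- **Slope recovery** (noiseless, 64³, 1 mm): the recovery layout
  (`recovery_phantom_spec`) stacks three spheres per lesion class over a wide
  distance range whose nearest CSF is the flat outer shell.  Reason: the
  voxel-center distance transform carries a sub-voxel offset against the
  continuous surface whose mean differs between flat (exactly 0.5 mm) and
  curved (≈0.42 mm) surfaces; a narrow-span lesion sample mixing surface
  types inherits an offset–distance covariance worth 1–3% of the slope.
  With the wide-span flat-surface layout, lesion-class recovery is exact and
  NAWM recovers within 0.8%; with the default periventricular lesion layout
  the same pipeline recovers lesion slopes only to ~1.5–3%, which is a
  resolution limit of 1 mm voxel-center distances, not a pipeline error.
- **Group contrast**: two groups with identical geometry and noise but
  two-fold different decline slopes, 10 patients per group (fresh noise per
  patient), 20 seeded replicates.  The steep group must correlate more
  strongly and every between-group z must exceed 1.96; group size was set by
  a power calculation targeting E[z] ≥ 5 for the weakest (non-rim) class.
- **Determinism**: the full CLI chain writes byte-identical tables across
  runs with the same seed; all floats are formatted with a fixed `%.10g`.

## Known limitations

- Axis-aligned grids only; no resampling, no oblique affines.
- Fisher comparisons use voxel counts; no within-patient clustering
  correction (none is defined in the emulated design).
- The continuous-vs-voxel-center distance offset above (~½ voxel) shifts
  intercepts and limits slope recovery for small, surface-type-mixed
  samples at 1 mm resolution.
- The cohort generator draws classes independently per patient; it imposes
  no correlation between barrier dysfunction and synthesis.
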