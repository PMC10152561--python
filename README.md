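# csfgrad

Analysis pipeline for two linked questions in multiple sclerosis imaging and
CSF laboratory work:

1. **Is there intrathecal immunoglobulin synthesis?**  From paired CSF/serum
   concentrations the package computes the dimensionless quotients
   Q_alb = albumin_CSF/albumin_serum and Q_Ig = Ig_CSF/Ig_serum, the
   age-dependent barrier limit Q_alb^lim = (4 + age/15)×10⁻³, and the
   hyperbolic discrimination limit of the Reiber quotient diagram,

       Q_lim(Q_alb) = a·√(Q_alb² + b²) − c,

   per immunoglobulin class (IgG, IgA, IgM).  A measured Q_Ig above Q_lim
   indicates synthesis inside the CNS, quantified as the intrathecal fraction
   (1 − Q_lim/Q_Ig)·100 % and as the absolute locally produced concentration
   (Q_Ig − Q_lim)·Ig_serum in mg/L.

2. **Is tissue damage graded by distance to the CSF?**  On co-registered
   volumes the package binarizes the CSF probability map (threshold 0.95),
   derives normal-appearing white matter (NAWM) by subtracting lesion masks
   from white matter, computes the exact Euclidean distance of every voxel to
   the CSF space in mm, applies partial-volume exclusions (first 2 mm around
   the CSF border; lesion voxels within 1.5 mm of their lesion edge), and
   tabulates (distance, ADC) per voxel for iron-rim lesions, non-rim lesions
   and NAWM.  The damage gradient is the Spearman correlation of ADC with
   distance (plus an OLS slope in mm²/s per mm); group differences in the
   gradient (e.g. patients with high vs low IgG quotient, split at the
   cohort median) are tested with the Fisher r-to-z statistic
   z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)).

Because no patient data ship with the package, a synthetic module generates
brain-like phantoms (ellipsoidal ventricle, outer CSF shell, cortical band,
spherical lesions) whose ADC field carries a *known* linear decline with
true distance to CSF, and two-group laboratory cohorts whose profiles are
constructed by inverting the Reiber hyperbola — so every downstream number
has a ground truth.

## Worked example

```python
from csfgrad import reiber as rb

q_alb = rb.compute_quotient(201.5, 42.6)   # CSF mg/L over serum g/L
print(round(q_alb * 1e3, 2))               # 4.73  (clinical ×10³ scale)
print(round(rb.q_lim("IgG", 5e-3) * 1e3, 3))  # 3.478
print(rb.intrathecal_fraction(6e-3, 3e-3))    # 50.0  (% of CSF IgG made in CNS)
print(rb.absolute_intrathecal_synthesis(6e-3, 3.478e-3, 10.0))  # 25.22 mg/L
```

The full simulated study runs as numbered drivers (or the equivalent
`csfgrad` CLI subcommands `simulate`, `reiber`, `gradient`, `cohort`,
`report`):

```bash
python analysis/01_simulate.py              # cohort + phantom volumes -> results/sim
python analysis/02_reiber_classification.py # classification + Reibergram
python analysis/03_gradient_analysis.py     # distance-ADC gradients + Fisher z
python analysis/04_cohort_report.py         # two-group laboratory table
```

A run of `02_reiber_classification.py` prints, for instance:

```
IRL+: intrathecal IgG synthesis in 36/51 (71%), median Q_IgG 4.05×10⁻³, ...
IRL-: intrathecal IgG synthesis in 25/51 (49%), median Q_IgG 3.61×10⁻³, ...
```

i.e. the rim-lesion group shows the higher prevalence of intrathecal IgG
synthesis that was imposed by the generator (71% vs 49% here), and
`04_cohort_report.py` flags exactly that row as the group difference
(chi-squared p ≈ 0.026).  `03_gradient_analysis.py` prints negative
distance–ADC correlations for every tissue class together with the
between-group z-matrix.

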