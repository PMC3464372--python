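# Methods

## Scope

`stereovalid` re-creates, in silico, the standard validation design for an
automated subcortical volumetry method: manual Cavalieri point-counting
stereology by two raters versus an automated volume estimate, compared by
absolute-agreement ICCs on a reliability sub-sample, whole-sample ICCs,
hemispheric asymmetry, and patient-versus-control ANOVAs. The automated
method itself (atlas segmentation) is out of scope and is modelled as an
observation process, not re-implemented.

## Phantoms

Superellipsoids |x/a|ᵉ + |y/b|ᵉ + |z/c|ᵉ ≤ 1 with closed-form volume
8abc·Γ(1+1/e)³/Γ(1+3/e). The closed form is the point of the family: every
unbiasedness and precision claim is tested against an analytic oracle rather
than against another voxel count. Defaults: semi-axes (15, 10, 9) mm,
exponent 2.2 (mildly boxier than an ellipsoid, thalamus-like compactness),
1 mm isotropic voxels, per-subject random orientation within ±30°. A voxel is
foreground iff its centre is inside the solid, so the voxel-count volume
converges to the analytic volume as voxels shrink (tested at 1.0 / 0.5 /
0.25 mm). When a target volume is given, semi-axes are rescaled isotropically
so the analytic volume matches it exactly.

Note on lattice effects: a lattice-aligned sphere rasterised at 1 mm carries
a ~1% lattice-count fluctuation (the classic lattice-point problem), which is
a property of rasterisation, not of the estimator; closed-form comparisons at
sub-percent tolerance therefore use 0.5 mm voxels.

## Cohorts

Per-hemisphere true volumes are truncated-normal (truncation at 0 is a safety
net — at the default means/SDs it essentially never binds). Defaults encode a
62-control / 10-patient study with control means (SD) of 7507.8 (805.6) /
7482.6 (767.2) mm³ left/right and patient means of 6843.2 (746.6) /
6763.3 (824.0) mm³ — a bilateral ~9% atrophy. Left and right are separate
phantoms whose latent normals are correlated at 0.7 by default; this
correlation is a modelling choice made once for realistic asymmetry scatter
(no empirical value exists for it), not a fitted quantity.

Seed splitting: a master seed roots a `numpy.random.SeedSequence`; stage,
subject, hemisphere and observer indices form the spawn key, so any single
measurement is reproducible in isolation.

## Observer models

Human raters are modelled at the mask level: the boundary is displaced along
its normal by a zero-mean Gaussian random field with ~5 mm correlation length
(human boundary disagreement is spatially coherent, not i.i.d. voxel flips),
implemented as {x : sdf(x) ≤ field(x)} on the signed Euclidean distance with
the half-voxel interface convention. The perturbation is unbiased to first
order (verified by Monte Carlo within 2%). A multiplicative volume bias is
applied by shifting the threshold to hit the target voxel count. Because the
displacement is quantised to voxels, amplitudes below ~0.2 mm at 1 mm voxels
produce almost no change — boundary noise is effective from roughly a fifth
of the voxel size upward. If a perturbation splits the mask, it is redrawn
(up to 5 times) before failing.

The automated method is a volume-level observer: true volume × (1 + bias)
plus Gaussian noise. Default magnitudes — rater boundary SDs 0.15 / 0.35 mm,
rater-2 bias +1.6%, automated SD 200 mm³ with −1.1% bias — come from a
grid-search calibration (`calibrate_observers`) against reliability-study
ICC targets in the high-agreement (>0.9) regime, with biases mirroring the
systematic offsets such studies report. The three printed pairwise targets
are not exactly representable by any additive-noise model (the rater-pair
ICC exceeds what the two automated-method pairs allow), so the calibration is
best-effort by design and the defaults are fixed once; no study-level claim
in the test suite depends on hitting the targets exactly.

## Stereology

Sections are the full systematic series through the mask's array extent at
interval d with a uniform random offset; interior and flanking zero-count
sections are retained (the CE's serial products need them; the estimate is
invariant to them). Test points form a square grid of spacing u with offsets
uniform on [0, u)²; a point counts iff the half-open voxel box containing it
is foreground. Everything is computed in world millimetres, so anisotropic
voxel spacing is handled for free. Defaults u = 3.12 mm, d = 1 mm.

Grid-offset policy: classically one grid offset serves the whole stack.
That choice correlates section-area errors, and on a 7400 mm³ phantom at the
default density it inflates the empirical CE to ~3.6% while the
Gundersen–Jensen prediction (whose noise term assumes independent grids per
section) stays near 0.8%. The package provides both variants;
the study pipeline defaults to per-section re-randomisation
(`per_section_grid=True`, empirical CE ~1.0%, matching the prediction within
the standard factor-of-two tolerance and consistent with rater reliabilities
in the >0.95 range, which shared-offset sampling noise alone would preclude).
Predicted-versus-empirical CE comparisons are made in the per-section regime.

CE options: smoothness class m = 1 by default (smooth compact body);
shape coefficient b/√a = 4.0 (mildly elongated profiles; 3.545 is a circle) —
not empirically identified, low sensitivity. A negative between-section
variance estimate (possible for short noisy series) is floored at 0. With
fewer than 3 structure-hitting sections the serial terms are uninformative
and a noise-only CE is returned with a warning.

## Statistics

ICC(A,1) from the two-way mean squares; the same formula serves the two-way
mixed and two-way random readings — the choice affects interpretation, not
arithmetic. The point estimate is reported unclipped (a pure function of the
mean squares; pathological anti-agreement tables can fall below −1), while
confidence bounds use the F-distribution method with Satterthwaite degrees of
freedom and are kept within [−1, 1]. Degenerate tables (no between-subject
variance) raise rather than return a number. ANOVA and the pooled t test are
computed from sums of squares with exact F/t reference distributions; zero
within-group variance with unequal means is reported as F = ∞, p = 0 with a
degeneracy flag. Asymmetry is the signed percentage 100(L−R)/((L+R)/2).
Multiple comparisons over the four atrophy contrasts (2 hemispheres × 2
methods) default to Bonferroni, Holm optional.

The whole-sample ICC uses rater 1 versus the automated method with patients
and controls pooled (n = 72 under defaults), matching the usual reporting of
such studies.

## What a green test does and does not establish

The synthetic world has compact, smoothly perturbed, single-component
structures and normally distributed volumes. Green tests establish the
correctness of the estimator, the CE predictor's calibration on such bodies,
the exactness of the statistics, and the internal consistency of the
study-level simulation (e.g. that manual and automated methods agree on
atrophy detection in ≥80% of replicate cohorts at the configured effect
sizes). They do not establish anything about MR contrast, partial-volume
effects, real anatomical boundary ambiguity, or the behaviour of any specific
segmentation software; printed agreement figures from real studies are used
only as generative targets, never asserted as outputs.

## Replicate-sensitivity fast path

`replicate_sensitivity` runs 200 replicate cohorts at the volume level
(shared true volumes per replicate, per-method additive noise). The manual
method's effective volume noise is not assumed: it is measured at run time by
pushing one phantom through the full boundary-perturbation + point-counting
chain repeatedly and taking the SD of the resulting estimates. This keeps the
200-replicate power analysis honest while avoiding 200 × 144 mask-level
measurements.

## Known limitations

- Boundary-noise quantisation (above) makes very small rater noise
  indistinguishable from zero at 1 mm voxels.
- The voxel-centre point-in-structure rule ties the estimator's expectation
  to the voxelised volume; rasterisation bias (sub-percent at 1 mm for
  thalamus-scale bodies) is outside the estimator's control.
- `optimize_density` selects over a user-supplied coarse-to-fine ladder; it
  does not search the continuous (u, d) plane.
- The observer calibration targets are under-determined (see above); the
  shipped defaults are one defensible point, not a unique solution.
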