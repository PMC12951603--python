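# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic study does and does not emulate.

## Data model and units

All coordinates are 3D, millimetres, right-handed. Forces are newtons, so
stresses are N mm⁻² (MPa) and FE strength scores are 1/(N mm⁻²). Missing
values are encoded as empty CSV fields, never zero. Landmark files use an
NTS-dialect text matrix: comment lines start with a quote character,
separators may be whitespace or commas, and the header is either the
classic `1 <k>L 3 0 dim=3` form or a bare `<k> 3` pair. Dentary files
carry a `" curves m1 m2 m3 m4` comment naming the per-curve point counts;
exact header conventions of digitiser exports vary, so the reader is
deliberately permissive and the writer round-trips through it losslessly.

## Linear morphometrics

The PCA is a correlation-matrix PCA (centred, unit-variance, SVD).
Component signs are fixed so the SVL loading is non-negative on every
axis (ties broken by PL) — sign conventions otherwise differ between SVD
implementations and make loadings irreproducible.

The MANOVA is sequential (type I) in the fixed order method, location,
method:location, matching the degrees-of-freedom layout of a standard
`manova()` summary. Per term the Pillai trace is V = tr(H(H+E)⁻¹) with H
the sequential hypothesis SSCP and E the full-model residual SSCP, and
Rao's approximation gives F = (V/(s−V))·df₂/df₁ with s = min(p, q),
df₁ = s(2m+s+1), df₂ = s(2n'+s+1), m = (|p−q|−1)/2, n' = (df_res−p−1)/2.
The Pillai trace is invariant under any nonsingular linear map of the
response block, so running it on scaled measurements or on full-rank PC
scores is equivalent (asserted numerically in the tests, and cross-checked
against R's `manova()` on a fixture).

The per-population method distance is the Euclidean distance between
method-group mean score vectors over all PC axes; its null is built by
permuting specimens within the population (randomising the reduced-model
residuals of the no-method-effect model), with the add-one rule
p = (#{null ≥ observed}+1)/(n_perm+1). Permutation p-values are therefore
never zero; the floor is 1/(n_perm+1).

Shrinkage percentage difference is signed:
100·(alcohol mean − fieldwork mean)/fieldwork mean. Spearman correlations
against preservation age use exact enumeration of rank permutations for
tie-free n ≤ 9 and the large-sample approximation (flagged in the output)
otherwise.

## Geometric morphometrics

Semilandmark curves are downsampled to equal arc-length spacing along the
piecewise-linear curve; endpoints are anatomical anchors and never move.
Sliding repositions semilandmarks to equidistant positions along their
specimen's original high-density curve each iteration and re-runs GPA
(10 iterations by default). The equidistant criterion — rather than
bending-energy or Procrustes-distance minimisation — is the method of the
`equidistantCurve` family; it is idempotent along the source curve, so the
iterations report a stabilised summed Procrustes distance rather than a
continuing optimisation.

GPA removes translation (centroid), scale (unit centroid size) and
rotation (SVD-based least squares against an iteratively updated
consensus). Reflections are disallowed (determinant +1); left/right
standardisation is the data producer's responsibility. Convergence: the
consensus moves by < 1e-10, or 100 iterations — both recorded in the run
log. Shape PCA acts directly on the flattened aligned coordinates
(covariance PCA, no tangent-space projection: at the dispersions in this
study the variance fractions are insensitive to the projection, and adding
it would introduce a second, unobservable convention). Axis signs make
each axis's largest-magnitude loading positive.

Procrustes ANOVA uses the shared RRPP engine (below) with the fixed term
order size (log centroid size), location, size:location. The order is a
convention; it is stated here because sequential SS depend on it.

## The RRPP engine

All permutation linear models (Procrustes ANOVA, the bite∼size×method
models, the morphospace distance test) share one implementation:
sequential design blocks are incrementally orthonormalised, so the term SS
is ‖Qₜ'Y‖², and under residual randomisation the permuted statistic
depends only on the permuted reduced-model residual matrix (the fitted
reduced part is annihilated by the projectors). That reduces the
permutation loop to dense matrix products and makes 999 permutations cheap
at any of this package's problem sizes. Conventions: add-one p-values;
pseudo-F uses the full-model residual mean square for every term; the
effect size Z standardises the observed F against the permuted F
distribution (observed included); a "Full model" row tests all terms
jointly against the intercept-only model.

## Warping, scaling, orientation

The TPS uses the 3D biharmonic kernel U(r) = r with the side condition
P'w = 0, giving exact control-point interpolation and exact reproduction
of affine targets (the r kernel is conditionally negative definite in 3D,
so the reported bending energy is −w'Kw, zero iff the map is affine).
Duplicate or coplanar control points raise a singular-system error — the
synthetic template deliberately keeps its fixed landmarks off the sampled
curves for this reason.

Average population size is the mean of per-specimen anterior–posterior
landmark distances (landmarks 1 and 3) in original mm coordinates, per
sample (total or males). Canonical orientation builds an orthonormal frame
from landmark-based direction estimates (long axis from anterior→posterior
landmarks; dorsal direction from a coronoid-region landmark, orthogonalised)
and is idempotent. Male-average shapes subset the joint Procrustes fit
rather than re-running GPA on males alone; the alternative would change
the consensus slightly but not the downstream comparisons.

## Mechanical advantage

The in-lever is the muscle's moment arm: the perpendicular distance from
the hinge to the muscle's line of action, measured in a 2D projection
plane (lateral x–y by default; the pterygoideus internus uses the lingual
x–z plane). This is the quantity the lever model actually needs; the
literal hinge-to-insertion distance is available as
`in_lever_mode="insertion_distance"` for comparison with protocols that
measured that instead. The out-lever is the hinge-to-bite-point distance
in the same plane, identical across muscles sharing a plane. The default
force proportions (0.481, 0.316, 0.102, 0.102) sum to 1.001 because they
are published rounded percentages; they are used as printed, and the
configuration validator accepts weight sums within 0.01 of 1.

## Finite elements

Tetrahedralisation: the surface is subdivided until no edge exceeds the
target, a body-centred interior lattice at the target spacing is kept
where it lies inside the surface and at least half a spacing away from it,
and the Delaunay tetrahedralisation of the combined points is clipped to
elements whose centroid lies inside the surface (ray-parity containment,
vectorised and bucketed on a 2D grid). On the analytic fixtures this
reproduces the enclosed volume to well within 2% at a tenth-radius edge.

Elements are linear (constant-strain) tetrahedra; the material is
isotropic linear elastic, E = 17 000 MPa, ν = 0.3, homogeneous over the
whole mesh including teeth. The solver supports prescribed (possibly
nonzero) displacements and nodal forces, uses a sparse LU factorisation,
and reports strain energy and external work so equilibrium can be
asserted. Verification: exact patch test, uniaxial bar stress/displacement
within 1% of closed form, cantilever tip deflection within 10% of
FL³/(3EI) with error decreasing under refinement.

Load cases are a reconstruction of standard lizard-jaw FE practice:
dentary — posterior cut face fully fixed, unit −y force at the bite point;
mandible with muscles — articular region (posterior 8% of the length)
fixed, bite-point node constrained vertically, nodal forces at the four
insertion regions along each line of action totalling 1 N, split by the
muscle force proportions; mandible without muscles — articular region
fixed, unit bite load. The strength score is the reciprocal of the
volume-weighted median (configurable quantile) of element von Mises
stress; the statistic used is recorded with every result, and the ranking
of a thick versus thinned jaw is robust across the 0.5/0.75/0.9 quantiles.
The default characteristic edge is 4% of jaw length: at that resolution
the stress summary changes by < 5% under further refinement on the
fixtures, and a full eight-population run stays around half a minute.

## Validation statistics

All quantities are natural-logged before analysis; population average bite
is the mean of logged individual forces (not the log of the arithmetic
mean — Jensen's gap makes these differ). Kendall τ-b uses tie corrections;
tie-free vectors with n ≤ 8 get an exact two-sided p from the full n!
permutation null and the concordant-pair count T is reported, otherwise a
tie-corrected z. The bite∼size×method model uses the RRPP engine with the
order size, method, size:method; "method retained" means the method term
or the interaction has p ≤ 0.05, in which case the two data sources do not
share a single bite∼size relationship. α = 0.05 with no multiple-testing
correction. Z-scoring standardises bite within each method group (n−1
denominator) to remove the incommensurable units (N versus dimensionless
MA versus 1/(N mm⁻²)) before re-fitting; note that when the two sources'
*size* scales also differ by a constant factor (as in the synthetic
anatomy, where dentary length is a fixed fraction of head size), the
sequential method term can remain significant after z-scoring even when
slopes agree — the size:method interaction is the informative term for
slope equality, and both p-values are always reported together with the
full table. A Shapiro–Wilk check is reported to motivate the permutation
route; it never gates any result.

## The synthetic study

The generator's defaults are the study conditions: eight islet
populations with the study's fieldwork (229), alcohol (74) and male
sample sizes; per-measurement alcohol shrinkage factors with SVL most
affected (0.93) and PL least (0.995); collection years 1931–1980; bite
forces log-linear in measured SVL with slope 2 (muscle cross-section
scaling), intercept set to give ~10 N at 60 mm SVL, and log-scale scatter
0.15; individual size spread 0.06 and population mean-size spread 0.05 on
the log scale; landmark noise 0.02 mm on a 12 mm template jaw. Where the
source material states no value these were chosen once as field-realistic
magnitudes and are documented here rather than tuned.

The template jaw is a convex tapered wedge (12 mm mandible, 7 mm dentary
segment) with 16 mandible landmarks and 7 dentary landmarks + 4
high-density curves placed at distinct loci on its surface. Population
mean shapes deform the template by a small random affine map plus a
long-wavelength dorsoventral bow and an explicit corpus-depth factor
(injectable, for ordering-recovery experiments); individuals add isotropic
Gaussian landmark noise. Muscle insertions and lines of action are defined
through landmark roles, so they deform with each population's geometry.

What the generator does *not* emulate: real mandible anatomy (teeth,
coronoid process, curvature of the tooth row), digitising error structure
(real landmark error is anisotropic and correlated along curves),
collection-biased sampling, and any quantitative match to real *Podarcis*
shape statistics. Passing tests therefore demonstrate that the pipeline's
inference machinery is correct and calibrated under its assumed model —
not that the biological conclusions transfer to any particular dataset.

## Problem sizes and determinism

Default analyses use 999 permutations; calibration experiments in the test
suite use 199 permutations per fit (the p ≤ 0.05 rejection rule is exact
at multiples of 1/200) over 500 replicates, and parameter-recovery
experiments use 100 replicates of a four-islet study — sizes chosen so the
whole suite runs in a couple of minutes while keeping Monte-Carlo bands
tight. Every stochastic step takes an explicit seeded generator; the
pipeline is a pure function of (inputs, config, seed) and repeated runs
are byte-identical, with seed and versions recorded in the run log.

## Known limitations

- The FE boundary conditions are a documented reconstruction, not a
  published protocol; absolute strength values are therefore comparative,
  not calibrated to any external experiment.
- Linear tetrahedra are stiff in bending; the verification suite bounds
  the error on beam fixtures, but thin-structure accuracy depends on the
  edge-length setting.
- The Delaunay-with-clipping tetrahedraliser assumes surfaces without
  deep concavities (the jaw templates are near-convex); strongly concave
  geometries would need a constrained tetrahedraliser.
- Exact Kendall and Spearman p-values are limited to n ≤ 8 / n ≤ 9;
  beyond that the tie-corrected normal approximations are used.
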