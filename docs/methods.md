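# Methods

`krillselect` predicts and estimates the size selectivity of Antarctic
krill (*Euphausia superba*) in diamond-mesh trawl netting from a
morphological description of the animal.  This note documents the models,
the numerical choices, and what the synthetic study conditions do and do
not emulate.

## Morphological model

A krill attempting to pass a mesh head- or tail-first presents two
decisive transverse cross sections: CS1 (anterior, containing the maximum
body width) and CS2 (posterior).  A third outline, CS3, describes the
curled contact mode and is supported structurally but carries no default
length regressions.  Each cross section is modelled as a closed
three-parameter curve: half-width `c1` (mm), half-height `c2` (mm) and a
dimensionless flex `c3`.  Three families are implemented:

* `flexellipse_1` — `x = c1 cos t`, `y = c2 sin t + c3 sin^2 t`
  (vertical egg asymmetry, valid `|c3| < c2`); the default for CS1;
* `flexellipse_3` — `x = c1 cos t (1 - c3 sin t)`, `y = c2 sin t`
  (width tapering with height, `|c3| < 1`); the default for CS2;
* `flexdrope_2` — `x = c1 cos t (1 - c3 (1 + sin t)/2)`, `y = c2 sin t`
  (one-sided drop taper, `|c3| < 1`); the default for CS3.

These parametrizations are this package's own; the historical
cross-section equation set they emulate is not publicly archived.  They
preserve the parameter roles (`c1` half-width, `c2` half-height, `c3`
flex) because each discretised boundary is affinely normalised to a
bounding box of exactly `2*c1 x 2*c2`.  That normalisation is what allows
the downstream coefficient models and length regressions to drive every
family through the same two size parameters.  The family is selected per
cross section by least squares on radial residuals about the outline
centroid, ranked by AIC (`n ln(RSS/n) + 2k`, `k = 3`), ties broken by R².

Shape parameters are predicted from cross-section width `b` and height
`h` by bilinear models `c = a0 + a1 b + a2 h + a3 b h`, fitted by OLS
with backward elimination (largest p-value removed while p > 0.05; the
intercept is eligible; numerically negligible terms on noise-free data
are dropped first).  The shipped reference coefficients for krill retain
no intercepts; e.g. CS1 has `c1 = 0.5224 b` and
`c2 = 0.4403 b + 0.2069 h`.

Body length L (mm, "Discovery" measure) maps to `b` and `h` at each
cross section through linear regressions (reference slopes ~0.10-0.14,
intercepts near zero).  The virtual population draws Gaussian residuals
around these regressions with per-dimension standard deviations chosen
so the regressions' published R² values are reproduced at the reference
length spread (sd 7.7 mm): `sd = slope * 7.7 * sqrt(1/R^2 - 1)`, about
0.34 mm for CS1 width.  Setting all sds to zero gives a deterministic,
seed-independent population whose penetration outcomes are knife-edge in
length.

## Mesh geometry and penetration

A diamond mesh of stretched inside size `m` (twice the bar length) and
opening angle `oa` has transverse opening `w = m sin(oa/2)` and
along-length opening `h = m cos(oa/2)`; `oa = 90°` is a square opening.
The mesh length axis is taken along the towing direction, so an attack
angle `a < 90°` projects the opening to `h' = h sin a` with `w`
unchanged.

The exoskeleton does not compress, so a cross section passes iff some
in-plane rotation and translation place its outline inside the opening.
Because the opening is convex, only the outline's convex hull matters,
and because a diamond has two parallel-edge pairs, a feasible translation
exists at a given rotation iff the hull's directional width along each
edge normal does not exceed the slab width `w h / sqrt(w^2 + h^2)`.  This
is exact, not a heuristic, and for an axis-aligned ellipse it reduces to
`(2 c1/w)^2 + (2 c2/h)^2 <= 1`.  The combined CS1+CS2 mode places both
outlines concentrically on the body axis with one shared rotation and
translation, which is equivalent to testing the convex hull of their
union.  Optimal rotation is found on a 0.25° grid over [0, 180°) with a
bounded scalar refinement of the exact clearance function; fits are
declared at a clearance tolerance of 1e-6 mm.  General convex polygons
are supported through a small linear program; diamonds use the fast slab
path.  Legs, setae and antennae are ignored (they fold against the body
during head-first penetration).

A geometric consequence worth noting: for an ellipse-like shape with
half-width a and half-height b, the mesh-size threshold is minimised at
`tan(oa/2) = sqrt(a/b)`.  With the krill aspect ratio (~1.4) the
selective optimum therefore lies near `oa ≈ 80°`, and L50 declines by a
couple of percent between 80° and 90°.  Design-guide checks treat the
increase of L50 with oa as strict below that optimum and as an endpoint
inequality across the full 10-90° range.

Fixed body rotations are parameterised by the angle θ between the
dorso-ventral axis and the mesh transverse axis: θ = 0 is the normal
swimming orientation (body height across the narrow axis of the
opening), θ = 90° aligns the body height with the mesh length axis and
maximises escapement.

## Selectivity estimation

Retention follows the logistic curve
`r(l) = 1/(1 + exp(-ln 9 (l - L50)/SR))`; the ln 9 slope ties SR to
L75 − L25, and quantile lengths obey
`Li = L50 + SR ln(i/(100-i))/ln 9`.

Simulated penetration data are treated as covered-codend observations
and fitted by binomial maximum likelihood in (L50, ln SR).  Complete
separation (knife-edge selection) is detected up front and reported with
SR at a 1e-3 mm floor.

Experimental paired-gear data (test vs control counts per 1-mm class,
hauls pooled) are fitted by minimising
`-Σ nt_l ln p_l + nc_l ln(1 - p_l)` with
`p_l = SP r(l)/(SP r(l) + 1 - SP)`, where the split parameter SP is the
relative fishing power of the test gear.  A Nelder-Mead simplex runs
from 8 starting points (two L50 quantiles × SR ∈ {1, 6} × SP ∈
{0.3, 0.7}) to a 1e-8 objective tolerance; goodness of fit is the
deviance against the saturated model on `(#non-empty classes) - 3`
degrees of freedom, with the model accepted at p > 0.05.

Uncertainty uses a double bootstrap: hauls are resampled with
replacement, then the haul's individuals — a (length class, gear)
record each — are resampled over the flattened class-by-gear cells, so
both the length structure and the test/control split vary between
replicates.  Percentile (Efron) 95% intervals are reported for the
parameters, for L05..L95 and as a pointwise curve band; the default is
1000 replicates.  With a single haul only the inner resampling runs.
Percentile intervals for the weakly identified SR are known to
undercover slightly at these sample sizes (~800 individuals); this is a
property of the method, not of the implementation.

## Opening-angle mixture and mesh-size predictions

A trawl presents a distribution of opening angles during fishing.  The
observed selection curve of the 15.4 mm commercial netting is expressed
as a convex combination of simulated single-oa curves (oa = 15-50° in 5°
steps) for the same mesh size: weights ≥ 0 summing to 1 minimise the
squared difference between the mixture retention and the target
retention at the 19 quantile lengths L05, L10, ..., L95.  The problem is
solved by nonnegative least squares with a sum-to-one augmentation and
refined under the exact simplex constraint (SLSQP with an analytic
gradient).  Single-oa cells in which the virtual population shows no
selection are carried as retention ≡ 0 or ≡ 1.

The calibrated weights are propagated to other mesh sizes by
re-simulating the single-oa curves per mesh size on the same wide
virtual population (10-70 mm; the span covers the component thresholds
of all predicted sizes, and cells beyond it are flagged), mixing them,
and refitting a single logistic to the mixture retention on a 0.1 mm
grid.

The weight distribution — unlike the predicted L50 values, which are
anchored by the calibration — is sensitive to the smoothness of the
component curves and to the exact cross-section parametrization.  With
the default residual variation the component curves have SR ≈ 3-4 mm and
the component nearest the experimental L50 (oa = 30°) absorbs most of
the weight (~70%); with steeper components the weight spreads further
across 25-35°.  Either way ≥ 80% of the mass falls on oa ∈ {25, 30, 35}°
with 30° among the leading components, matching the range observed on
underwater recordings.

## Synthetic study conditions

The generators reproduce the statistical structure the analysis assumes,
at the scale of the original study: morphometrics for 83 individuals
with lengths truncated-normal (mean 44.7, sd 7.7, range 19-55 mm);
paired catches of 809 encounters split over four hauls with true
parameters (L50, SR, SP) = (32.72, 4.85, 0.55), generated as the exact
inverse of the paired-gear likelihood (class totals multinomial from the
length distribution, each class split binomially at p_l) so that
recovery tests are true likelihood checks — gear-wise totals are
therefore random with the combined total fixed; and five digitised
meshes (15.4 mm, corner plus bar-midpoint points, optional Gaussian
noise).  Not emulated: preservation shrinkage, sex/maturity structure,
between-haul heterogeneity of the length distribution, and swarm
patchiness — so passing tests demonstrate correctness of the estimators
under the assumed model, not robustness to field-data violations of it.

## Problem sizes and determinism

Virtual populations of ~1000-2000 individuals (length grid 10-70 mm at
0.5 mm, 8-17 per length) are used for the selectivity simulations;
recovery experiments use 200 synthetic paired-gear datasets and 100-200
bootstrap replicates.  All randomness flows through numpy Generators
seeded from a single user seed; repeated runs with the same seed are
bit-identical.
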