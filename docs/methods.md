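# Methods

## Model and procedure

The package assumes samples in group j are draws from a p-variate normal
distribution with mean μⱼ and group-specific covariance Σⱼ. Discrimination is
by the quadratic rule: with estimates x̄ⱼ and Sⱼ (unbiased, divisor nⱼ − 1)
and priors πⱼ, a sample x is assigned to

argmaxⱼ { log πⱼ − ½ φⱼ²(x) },  φⱼ²(x) = (x − x̄ⱼ)′Sⱼ⁻¹(x − x̄ⱼ) + log|Sⱼ|.

φⱼ² is evaluated through the lower Cholesky factor of Sⱼ (one triangular
solve per group); no covariance matrix is ever inverted explicitly, and the
log-determinant is twice the log-trace of the factor's diagonal. A failed
factorization is the positive-definiteness error path and names the offending
group, since the usual cause is p exceeding nⱼ − 1.

The display is built in three steps:

1. **Score matrix.** φⱼ²(xᵢ) is computed for every sample × group and each
   column standardized to mean 0, SD 1 (divisor n − 1), giving Φ (n × J).
   Standardization stops one concentrated group (small |Sⱼ|, hence small
   scores) from collapsing against a dispersed one in the display.
2. **Projection.** PCA of Φ via SVD, no re-centring (the columns are already
   mean zero). Samples are plotted on the first two principal-component
   scores. For J = 2 the representation is exact; for J > 2 it is the best
   rank-2 approximation in the least-squares sense.
3. **Regions.** A display point z is mapped back to approximate raw scores
   φ̂ⱼ² = (Vᵣ z)ⱼ·sⱼ + φ̄ⱼ, where Vᵣ holds the retained right singular
   vectors and (φ̄ⱼ, sⱼ) the standardization constants — the standard PCA
   inverse map, the unique linear right-inverse on the retained subspace.
   The point is then classified by the quadratic rule above; labelling a
   regular lattice paints the classification regions.

With two groups the package also offers the direct scatter of φ₂² against
φ₁²: unscaled, the equal-prior boundary is exactly the line y = x (class 1
below-right, class 1 also winning ties); the scaled variant divides each
coordinate by its standard deviation while still deciding regions on the raw
scores.

The classical CVA biplot is retained for the equal-covariance case: M solves
BM = WMΛ subject to M′WM = I, solved as a symmetric problem (Cholesky-whiten
W, symmetric eigendecomposition, back-transform) rather than forming W⁻¹B.
Display scores are Z = XM₂ and the plane is classified by the nearest
canonical mean with log πⱼ added and the Mahalanobis scale factor n − J.

## Variable axes

Axes use the regression method: for variable k (centred column xₖ), the
direction is bₖ = (Z′Z)⁻¹Z′xₖ, so the orthogonal projection of a display
point z onto the axis reads off the fitted value z′bₖ + mean(k). Tick values
follow a 1-2-5 "nice numbers" ladder over the observed range (0 and 1 only
for binary variables); a tick for value v sits at ((v − mean(k))/‖bₖ‖²)·bₖ.
Orthogonal parallel translation ("hull-clear", the default) shifts each axis
along its unit normal just past the extreme score projection on the nearer
side, plus 5% of the score range; because the shift is orthogonal to the
axis, projections — and hence read-off values — are unchanged. Degenerate
directions (‖bₖ‖ < 1e-12) are omitted with a warning.

Rendered plots fix a 1:1 aspect ratio (distances in the display are
meaningful), draw regions as a shaded lattice behind the glyphs, and write
reproducible SVG (fixed hash salt, no timestamp).

## Synthetic data

`three_group_spec` defines the benchmark generator: J = 3 four-variate normal
groups of 50 samples each with μ₁ = (1,1,1,1), μ₂ = (−1,2,3,4),
μ₃ = (1,1,5,5); Σ₁ = I, Σ₂ = 2I, Σ₃ compound-symmetric with unit variance
and correlation 0.7. Group 2 is the most dispersed; groups order 1 < 2 < 3 on
variables 3 and 4. `dichotomize_at_median` converts to indicators at the
pooled per-variable median (pooled rather than per-group, since the
conversion precedes any group modelling; even-count medians use the
conventional midpoint, with values ≥ median mapped to 1). `pathogen_panel`
draws independent per-variable Bernoulli indicators with class-specific
presence probabilities, emulating a presence/absence pathogen panel; it does
not model co-occurrence between variables.

What the generators do *not* emulate about real data: measurement error
structure, correlated binary responses, unbalanced groups and label noise.
Passing tests on these fixtures show the geometry and algebra of the method
are implemented correctly, not that QDA is appropriate for any particular
data set.

## Numerical choices and conventions

- Covariance divisor nⱼ − 1 (unbiased); pooled covariance Σ(nⱼ−1)Sⱼ/(n−J).
- Eigen/PCA sign convention: the largest-magnitude entry of each
  eigenvector / loading column is made positive, so layouts are reproducible
  across platforms.
- Ties in every argmax go to the lowest class index, deterministically; in
  pattern collapsing the majority vote breaks ties the same way.
- No covariance regularization by default; `ridge` adds ε·I to every Sⱼ for
  near-singular (typically binary) data when explicitly requested.
- Priors: "proportional" (nⱼ/n) is the default for region classification,
  with "equal" and explicit vectors available.
- Region grid: 400 × 400 lattice with a 10% margin by default, both
  configurable; a degenerate (zero-range) display dimension falls back to a
  unit extent so rank-1 CVA displays still grid cleanly.
- RNG: numpy's default PCG64 generator with an explicit integer seed recorded
  in simulation sidecar metadata.

## Problem sizes

The test suite and the acceptance script run on the generators' native sizes:
the 150 × 4 benchmark (50 per group), 200-sample two-group fixtures (100 per
group, p = 4, both normal and binary), and 10,000-per-group draws for the
parameter-recovery check. Region-grid assertions use 50–200 points per side;
plots default to 400.

## Known limitations

- For J > 2 the rank-2 PCA of Φ discards a component of the score geometry,
  and the painted regions can misassign samples that the full quadratic rule
  classifies correctly; in unlucky draws of the benchmark an entire group's
  display region can capture few of its own samples even though direct QDA
  resubstitution exceeds 95%. The display is a visualization of the
  discrimination, not a substitute for the classifier.
- Median-dichotomized data can leave a variable constant within a group
  (e.g. a group whose values all exceed the pooled median), making that
  group's covariance singular; the fit then fails by design unless a small
  ridge is requested.
- Binary data violate the normality assumption underlying φⱼ²; the biplot
  remains usable as an exploratory display (the benchmark's indicator version
  preserves the main location/spread/separation features), but the
  probabilistic interpretation of the regions is heuristic there.
- Classification-region boundaries are rendered at lattice resolution; exact
  boundary curves are not computed.
- Only 2-D displays are produced; cross-validated error estimation and
  variable selection are out of scope.
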