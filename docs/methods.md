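# Methods

## Model

Two phenotypes are modelled as sums of additive genetic and environmental
components, x = a_x + e_x and y = a_y + e_y, and the target of inference is
the functional relationship E[a_y] = f(a_x) — not a single correlation but a
curve over the range of x. y may be binary, ordinal or continuous; x must be
(practically) continuous so that it can be binned. The direction of the
equation carries no causal commitment: f describes how the expectation of
y's genetic liability varies across x's distribution.

The observable raw material is a set of genetic correlations between
*bin-pair contrast GWASs* of x and a GWAS of y. Individuals are assigned to K
ordered bins of x; for each of the C(K,2) ordered pairs, the lower bin's
members are cases (coded 1) and the higher bin's members controls (coded 0),
and a per-variant association of membership on dosage characterises the
genetic difference between those two cross-sections of x.

## From correlation to distance

For a pair with representative values x_case < x_control, dx = x_control −
x_case, and estimated genetic correlation `cor` with y, the transform is
applied literally as a two-step trigonometric construction:

    angle = 90 − acos(cor/dx)·180/π      dy = tan(angle·π/180)·dx

equivalent to the closed form dy = dx·c/√(1−c²) with c = cor/dx (the basis of
the transform's oracle test). Properties: dy = 0 iff cor = 0, dy is odd and
strictly increasing in cor, and dy ≈ cor for |c| small.

Because the case is the *lower* bin, a positive correlation means the lower
bin's genetics align with y, so dy estimates f(x_case) − f(x_control); the
fitting stage consumes it with that orientation by default (`dy_sign`
switches it). This sign chain is not assumed but verified end to end in
simulation: a positive linear coupling produces a rising fitted curve.

Filtering before the transform, never clamping: missing rg →
`not_estimated`; |rg| > 1 → `out_of_bounds`; |cor/dx| > 1 (possible when
dx < 1 on the chosen scale) → `ratio_out_of_domain`; the measure-zero case
|cor/dx| = 1 → `divergent_distance` (the implied dy is infinite). Surviving
estimates are used regardless of significance. The division by dx inside the
acos makes the method deliberately scale-dependent; binning should be done
on a natural scale of x where one exists.

## Curve reconstruction

Only pairwise differences f(x_i) − f(x_j) are observed. Two estimators share
the objective

    min over coefficients  Σ_pairs ( dy_obs − [f(x_case) − f(x_control)] )²

* **C² cubic spline** — three local cubics f1, f2, f3 (coefficients b1..b12)
  on the segments delimited by two interior knots i < j, constrained to agree
  at each knot. The smoothness requirement is read as full C² continuity:
  matching first and second derivatives alone would leave the fitted function
  free to jump at the knots whenever the data are noisy, so the value-match
  constraints f1(i) = f2(i), f2(j) = f3(j) are imposed along with the four
  derivative matches — six linear constraints, six free parameters.
* **Degree-5 polynomial** — a single global polynomial, intercept excluded
  from the design (it cancels in every difference).

Both fits are linear in their coefficients with linear constraints, so they
are solved exactly by nullspace elimination (scipy null_space of the
constraint matrix) followed by ordinary least squares — deterministic, no
iterations, no seed. A dedicated test confirms the solution matches a
brute-force numerical minimiser of the same objective.

Numerical and identifiability choices:

* **Basis centering.** Cubic/quintic powers of raw trait values (e.g. BMI
  near 25, fifth powers ~10⁷) make the design badly conditioned; all
  polynomials are therefore expressed in powers of (x − x0) with x0 the
  domain midpoint. The `ShapeCurve` records x0; knots and the domain stay in
  trait units.
* **Anchor.** Differences identify f only up to a constant (the
  all-intercepts direction is in the constraint nullspace and invisible to
  the design). Default anchor: the mean of f over the distinct pair
  endpoints is zero, matching the relative liability scale on which results
  are read.
* **Knots.** The default places i and j at the 1/3 and 2/3 points of the
  representative-value range (symmetric segments); both are configurable.
* **Identifiability.** With p distinct representative values the spline's
  identified rank is min(p − 1, 5), so at least 7 distinct bins are needed;
  rank deficiency beyond the intercept direction raises a distinct error
  rather than returning an arbitrary minimum-norm curve. If a knot segment
  contains no pair endpoints, its cubic would be unidentified: the fit warns
  and falls back to the polynomial estimator.
* **Weighting.** Unweighted residuals by default; optional inverse-variance
  weighting by se(rg) behind a flag.
* Excluded distance estimates are dropped from the objective, never imputed.
* Evaluation refuses to extrapolate outside [min x_rep, max x_rep].

## Uncertainty

Each rg is redrawn from Normal(rg, se²) independently, B = 100 times, and the
*entire* pipeline — including the out-of-bounds filter — is rerun per
resample; out-of-bound draws are excluded exactly like out-of-bound point
estimates, not truncated, and failed refits are recorded and skipped, never
retried (retrying would bias the envelope). Curves are evaluated on a shared
grid fixed by the point-estimate fit and summarised by pointwise 2.5/50/97.5
percentile bands; all raw curves can be written out for spaghetti-style
display.

Resampling is independent across pairs, but rg estimates of overlapping bin
pairs share individuals and are correlated; the envelope therefore
*understates* the total sampling variability of the curve, visibly so for
null simulations, where the fitted curve's range can exceed several times
the pointwise band half-width without any real signal. Shape claims in the
test suite are therefore framed as contrasts against the null scenario
(tail elevation in units of band half-width) rather than as absolute
band-coverage statements.

## The simulator

The simulator generates n individuals × m independent biallelic variants
(frequencies uniform on (0.05, 0.95), dosages 0/1/2, linkage equilibrium),
builds standardized polygenic scores from unit-norm weight vectors, and
composes the two traits so that var(a_x)/var(x) = h2x exactly in
expectation. Couplings:

* **null** — a_y is an independent score.
* **linear** — a_y = ρ·ā_x + √(1−ρ²)·u, with ρ the coupling strength.
* **quadratic / two_tail** — two scores a_s, a_l enter x through *one-sided
  hinge* dose-responses (a_s pushes x down only when a_s > 0, a_l pushes x
  up only when a_l > 0) and a_y loads on a_s + a_l plus an independent
  score. `two_tail` places a_s and a_l on disjoint variant halves (two
  distinct tail aetiologies); `quadratic` lets them share the panel, giving
  a smooth, approximately quadratic E[a_y | a_x].

The hinge construction is deliberate. If all genetic effects on x are
additive and homogeneous, E[g_v | x] is linear in x for every variant, so
every bin-pair contrast tags the same effect vector and all pair
correlations with y coincide — the method is blind to any nonlinearity in
that regime (a property the test suite verifies: under a homogeneous
architecture the contrast effect vectors are near-perfectly correlated).
Likewise, a dependence of a_y on even functions of a scoring component has
zero additive projection and is invisible to an effect-vector correlation.
Detectable nonlinearity therefore requires genetic effects on x that are
heterogeneous across its range and carry a nonzero additive projection onto
y — exactly what the one-sided hinge provides: the low tail of x is strongly
enriched for a_s but only boundedly depleted of a_l, so low-vs-middle
contrasts correlate positively and middle-vs-high contrasts negatively with
y, and the recovered curve is a U.

rg per contrast is the Pearson correlation between the contrast's estimated
effect vector and the true per-variant additive effects on a_y (keeping rg
noise driven by the contrast GWAS at desk-scale n), with a delete-one-block
jackknife (20 contiguous variant blocks) for the standard error — a valid
genetic-correlation estimate under linkage equilibrium that exercises the
same (rg, se) interface as summary-statistic estimators.

x is emitted on a BMI-like natural scale (mean 25, sd 4 by default): on a
unit-sd scale adjacent decile bins sit closer than typical correlation
noise, pushing |cor/dx| past 1 and amplifying noise through the transform's
1/dx.

### Simulation sizes and summary statistics used by the tests

* Shape recovery runs n = 20,000, m = 2,000, K = 10 equal quantile bins,
  h2x = 0.5, coupling strength 0.5 (half of each trait's genetic variance in
  the coupled components — a strong but plausible shared-aetiology
  structure). Each end-to-end run takes a few seconds.
* Convexity of the quadratic scenario is summarised by the *aggregate*
  second derivative over the central 60% of the domain (the slope gain
  f'(hi) − f'(lo) = ∫ f''): the population curve has a flat bottom, so the
  pointwise sign of a noisy second-derivative estimate is uninformative
  wherever true curvature is ≈ 0. Both estimators must agree on the sign.
* The two-tail U is summarised by the tail elevation above the central
  minimum in units of the median envelope half-width (observed ≈ 5–6 at the
  sizes above); the null scenario must stay below 1 on the same statistic.
* The homogeneity check uses K = 3 equal bins, n = 40,000, m = 200,
  h2x = 0.8 — sized (per-variant GWAS noise sd ≈ 0.5/√n_pair against signal
  ≈ f(1−f)·√(h2x/m)·Δx) so that sampling attenuation of the vector
  correlations is a few percent at most; at m = 2,000 and K = 10 the same
  attenuation would dominate and the structural property would be
  unmeasurable.

### What the simulator does not emulate

Linkage disequilibrium, relatedness, mixed-model association, covariates,
ascertainment, and case-control imbalance of real biobank bins. Passing
tests show that the statistical core of the pipeline — binning, contrast
association, correlation-to-distance transform, constrained fitting,
resampling — behaves as designed under its own assumptions; they do not show
robustness to LD-induced correlation between variants, to stratification,
or to LDSC-specific estimation error in real summary statistics.

## Known limitations

* Scale dependence: the mapping from bins to numeric x (bin median vs
  midpoint vs index — all selectable) changes the recovered shape,
  especially in the tails where medians spread out.
* The envelope ignores correlation between overlapping pairs' rg estimates
  (see above) and so understates curve uncertainty.
* Under a linear coupling every contrast shares the same population rg
  regardless of bin distance, so the recovered curve is monotone but not
  exactly proportional to a linear f; the method's distances behave like
  derivative estimates scaled by 1/dx rather than pure differences.
* Tail bins are small by design in tail-emphasising schemes; their rg
  estimates are noisy and dominate local uncertainty at the curve ends.
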