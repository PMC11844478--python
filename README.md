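# genarc

Infer the **shape** of a (non)linear bivariate genetic relationship —
E[a_y] = f(a_x) — from genetic correlations between *bin-pair contrast GWASs*
of a continuous trait x and an outcome trait y.

A single genetic correlation r_g(x, y) summarises only the linear component of
the relationship between two traits' genetic liabilities. Famous
epidemiological shapes — U- and J-curves linking BMI or sleep duration to
psychiatric outcomes — are invisible to it. genarc implements a
summary-statistic method that recovers the curve itself:

1. **Bin** the continuous trait x into K ordered bins (quantile widths, e.g. a
   30-bin scheme emphasising the distribution tails, or natural-scale cuts
   such as hours slept). Each of the K·(K−1)/2 bin pairs defines a
   case/control contrast GWAS (lower bin = cases, higher bin = controls).
2. **Transform** each pair's genetic correlation `cor` with trait y into a
   distance on y's liability scale, using the distance dx between the bins'
   median x values:

       angle = 90 − acos(cor / dx) · 180/π          (degrees)
       dy    = tan(angle · π/180) · dx

   i.e. `cor/dx` is read as the cosine of the complement of the acute angle of
   a right triangle whose adjacent side is dx and whose opposite side is the
   unknown dy. Estimates with missing rg or |rg| > 1 are excluded; everything
   else is kept regardless of significance.
3. **Fit** the curve y = f(x) to the observed set of pairwise distances
   {dy_ij ≈ f(x_i) − f(x_j)} by equality-constrained linear least squares:
   either three local cubics f1, f2, f3 (coefficients b1..b12) joined at two
   interior knots with matching values, first and second derivatives (a C²
   cubic spline), or a single degree-5 polynomial. Pairwise differences leave
   f identified only up to an additive constant, which is anchored so the
   curve averages zero over the bin representatives (a relative liability
   scale).
4. **Resample** each rg from Normal(rg, se²) 100 times, rerun the whole
   filter → transform → fit pipeline, and report pointwise 2.5/50/97.5%
   envelope bands.

A polygenic simulator (two traits, each additive genetic + environmental,
with configurable linear / convex / two-tail / null coupling between the
genetic components) validates the full pipeline end to end without any
external data; genetic correlations are estimated there as effect-vector
correlations with block-jackknife standard errors, which is valid because
simulated variants are in linkage equilibrium.

## Worked example

Simulate a cohort in which both tails of x carry genetic risk for y (the
"short and long sleep both load on depression" structure: two independent
polygenic scores push x down / up through one-sided dose-responses and both
feed y), then recover the curve:

```bash
$ genarc simulate --coupling two_tail --seed 11 --out-dir demo
simulate two_tail: 45 contrasts, 100 envelope curves -> demo
```

`demo/rg_table.tsv` holds one genetic correlation per bin pair (case = lower
bin, so positive rg means the lower bin's genetics align with y):

```
case_bin  control_bin  x_case   x_control  rg       se
1         2            18.518   20.902     0.0930   0.0421
1         3            18.518   22.321     0.1368   0.0586
...
```

The low-tail contrasts correlate positively and the high-tail contrasts
negatively with y, so the fitted curve (`demo/curve.tsv`) is U-shaped: it
starts at +0.091 at the lowest bin median (x ≈ 18.5), dips to −0.039 in the
middle of the range, and rises again to +0.084 at the highest — a tail
elevation of ≈ 0.12 liability units against a median envelope half-width of
0.020, i.e. both tails sit well outside the uncertainty band
(`demo/envelope.tsv`). A null-coupling run of the same command produces a
curve whose structure stays inside the band.

The same stages are available on your own tables: `genarc bins` builds bin
tables and contrast manifests from a phenotype vector, and `genarc fit` /
`genarc envelope` consume any TSV with columns
`case_bin control_bin x_case x_control rg se` (for example, LD-score
regression estimates computed from real contrast GWASs).

Library use mirrors the CLI:

```python
import genarc as g

records = g.read_rg_table("demo/rg_table.tsv")
env = g.curve_envelope(records, B=100, seed=0)
curve = env.point_curve            # ShapeCurve: b1..b12, knots, domain
y = g.evaluate_curve(curve, env.grid)
```

## Caveats

The transform divides `cor` by dx before the acos, so the method is
deliberately scale-dependent: changing the scale of x changes the recovered
shape, and pairs with |cor/dx| > 1 (possible when dx < 1) are excluded rather
than clamped. Use a natural scale for x where one exists. Under a fully
homogeneous additive architecture on x, every bin contrast tags the same
effect vector and a nonlinear causal effect of x on y can go undetected; see
`docs/methods.md` for the full assumptions and design notes.
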