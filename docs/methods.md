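# Methods

`macrotol` re-implements, as a tested pipeline, the computational analysis
of genetic variation in macronutrient tolerance across an inbred fly
panel: strains of a genetic reference panel are reared on several defined
diets, vial-level survival to pupation and eclosion is scored, and the
package asks (i) whether strains differ genetically in their *response*
to diet (genotype-by-environment interaction), (ii) which biallelic
variants associate with the multivariate diet-response phenotype,
(iii) how developmental timing differs between groups, and (iv) how
respirometry measurements convert to standardized resting metabolic
rates.

## Survival model (GxE)

The response is the number of larvae in a replicate vial that pupated
out of those seeded, modelled as binomial with a logit link.  Two nested
mixed models are compared:

* **intercept-only** — diet as a categorical fixed effect, a scalar
  strain-level random intercept (no GxE);
* **intercept + slopes** — additionally a treatment-coded random slope
  for each non-reference diet at the strain level, with a full
  unstructured k x k covariance (k = number of diets).

The parameter counts are k + 1 and k + k(k+1)/2, so the likelihood-ratio
test has k(k+1)/2 − 1 degrees of freedom — 20 for six diets.  A
significant deviance reduction for the slopes model indicates non-zero
among-strain variance in the diet response, i.e. GxE.

The marginal likelihood is computed with a Laplace approximation:
per-strain random-effect modes are found by damped Newton iteration
(the penalized binomial log-likelihood is strictly concave, so this is
globally convergent), and the Gaussian curvature correction
−½ log det(ZᵀWZ + Σ⁻¹) is added.  The outer optimization is bounded
L-BFGS-B over the fixed effects and the log-Cholesky factor of Σ, from
fixed all-zero starting values, making fits deterministic.  Numerical
choices:

* log-scale diagonal bounds [−7, 3] on the Cholesky factor; an estimate
  at the lower bound is a numerically-zero SD and is reported as a
  *singular* fit (never silently dropped);
* inner Newton tolerance 1e−9 on the gradient; strains are processed as
  padded, batched arrays (zero-trial rows contribute nothing), so
  balanced and unbalanced panels share one code path;
* the χ² p-value of the comparison uses the naive reference
  distribution.  Under the null the extra variance components sit on the
  boundary of the parameter space, so this p-value is conservative; the
  caveat is emitted as a log warning.  Simulation confirms the
  conservatism (null rejection well below the nominal 5%).

Validation: the Laplace log-likelihood agrees with dense Gauss-Hermite
integration to ≤0.05 on 2–3-strain toys, and the deviance reduction and
fixed effects agree with `lme4::glmer` (the field-standard fitter) on a
30-strain panel.  Vial-level fitting is the default; a `pool_vials`
option collapses replicates to strain x diet totals, since published
descriptions of such screens are often ambiguous on this point.

## Variant screen

Line-level phenotypes are the unweighted mean of vial proportions per
line x diet (equal to pooled counts under equal seeding); eclosion is
denominated by seeded larvae by default (survival to adult), with a
pupae-denominated option.  Normalized phenotypes subtract each line's
reference-diet (high-protein) value and drop that column, so the raw
screen is 6-variate and the normalized screen 5-variate over six diets.

Per variant, among non-missing calls of phenotyped lines:

* **MANOVA** of the per-diet phenotype vector on genotype + Wolbachia
  infection status (additive binary covariate, never interacting).
  Pillai's trace with its standard F approximation is the default
  statistic — the conventional, most robust choice; Wilks' lambda is
  available behind a flag.  Both are computed by a small in-package
  linear-algebra routine (hypothesis/error SSCP of two nested fits) that
  reproduces `statsmodels` MANOVA p-values to 1e−10 but runs ~50x
  faster, which matters when screening hundreds of variants over many
  replicates.  Complete-case lines only; constant genotype vectors and
  rank-deficient designs raise explicit errors that the screen records
  per variant without aborting.
* **Wilcoxon rank-sum** per diet, two-sided.  For combined group sizes
  ≤ 20 the p-value is exact: the null distribution of the rank sum over
  all C(N, n1) group assignments is built by subset-sum dynamic
  programming over doubled midranks, which handles ties exactly.  Larger
  samples use the tie-corrected, continuity-corrected normal
  approximation.  The two paths agree to ≤0.01 when each group has ≥16
  observations; at a combined size of 16 the best possible agreement of
  the continuity-corrected approximation is 0.011 (an exhaustive
  computation over all rank-sum values), which is why the agreement
  property is stated per group rather than for the combined sample.
* **Effect size**: median(alternate) − median(reference) per diet.

A variant is selected when MANOVA p < 1e−5 AND some diet has Wilcoxon
p < 0.01 AND |median difference| ≥ 0.3 (raw) / 0.2 (normalized) on that
same diet.  P-values are deliberately unadjusted — the screen is a
relaxed pre-filter ahead of functional validation — but a
Benjamini-Hochberg column is emitted for information.  Selection is
monotone in the thresholds and invariant to variant order and line
relabeling (tested).

The variant filter keeps a variant only when ≥5 phenotyped lines carry
each allele among non-missing calls, mirroring standard inbred-panel
practice.

Calibration: the Pillai p-value's type-I error is within the binomial
confidence band of the nominal 5% over 200 null simulations.  Against an
*exactly enumerated* permutation distribution on a 12-line instance the
F-approximation agrees to ≤0.03; the residual gap is the systematic
difference between the conditional permutation distribution and the
unconditional normal-theory F at n = 12, not Monte-Carlo error.

## Pupation kinetics

Cumulative daily pupae counts are fitted by least squares to the
logistic curve I(t) = I_max / (1 + exp(−a₁(t − t_mid))).
Initialization is deterministic (I_max⁰ = max count, t_mid⁰ = first day
reaching half of it, a₁⁰ = 4 / the 10–90% rise interval) and I_max is
bounded at 1.1 x larvae seeded to prevent runaway asymptotes on
truncated curves.  The day a vial reaches a count k < I_max is the
closed form t = t_mid − ln(I_max/k − 1)/a₁, which inverts the curve
exactly (tested to machine precision).  Two threshold semantics exist
because both appear in practice: a fixed count (default 15, half of a
30-larva vial) and a relative half-of-maximum mode (returns t_mid).
They disagree whenever I_max ≠ seeded; the package exposes both rather
than resolving the ambiguity.

Half-pupation times are compared by Welch (unequal-variance) two-sample
t-tests, and line-level overall pupation between diet pairs by paired
t-tests, each Bonferroni-corrected over the tested pairs (15 for six
diets).

Note on precision: counts are integers, so a daily observation grid
quantizes the curve; slope recovery from rounded noiseless data is
limited to roughly 2–8% at a 0.5–1 day grid and reaches the 1% regime
only on sub-daily grids.  The asymptote and midpoint are far less
affected (≲0.3%).

## Metabolic rate

RQ is predicted from the dietary sugar-to-yeast mass ratio as
RQ = 0.872 + 0.125·log10(S:Y + 1); the energy equivalent of CO2
interpolates linearly between mixed protein catabolism in a uricotelic
species (25.4 J mL⁻¹ at RQ 0.74) and carbohydrate catabolism
(21.1 J mL⁻¹ at RQ 1.0), i.e. EE = 37.64 − 16.54·RQ.  The line is
asserted to pass through both anchors to ≤0.01 J mL⁻¹ at model
construction.  Power is V̇CO2 (μL h⁻¹) x EE (J mL⁻¹) = mJ h⁻¹.

Standardization fits ordinary least squares of metabolic rate on
experimental condition (by default the genotype x diet cell; the
grouping is configurable because "condition" is ambiguous in practice)
plus fresh mass and activity, pooled across RNAi libraries.  Each fly is
then adjusted to its library's reference mass (GD 0.83, kk 0.77,
Trip 0.81 mg) and zero activity:
mr_adj = mr − β_mass (mass − ref) − β_act · activity.  Rank-deficient
designs raise an error naming the aliased terms.

## Synthetic data

The generator produces the study conditions every test runs under:

* **Survival panels** — default design 196 strains x 6 diets x 4 vials
  of 30 larvae.  Fixed per-diet log-odds put mean pupation near 0.90 on
  the protein/starch/lard diets, 0.80 on the sucrose+lard diet, 0.76 on
  high sugar and 0.67 on coconut oil, matching the survival ordering
  such screens report.  Strain effects are multivariate normal on the
  logit scale (intercept + per-diet slopes) — exactly the GLMM2
  generative structure; default variances (0.6 intercept; 0.8 on the
  sugar and coconut-oil slopes, 0.2–0.4 elsewhere) concentrate genetic
  variation where inbred panels show it.  Eclosion is a binomial
  thinning of pupation with a per-strain Beta(27, 3) eclosion
  probability (mean 0.9), which guarantees eclosed ≤ pupated ≤ seeded.
* **Genotypes** — biallelic variant x line calls with a configurable
  minor-line-count distribution, independent missing calls (default 2%),
  and per-line Wolbachia status (default prevalence 0.5, the typical
  order for such panels).  Planted causal variants shift the pupation
  proportion of alternate-allele lines per diet, on the proportion scale
  clipped to [0.01, 0.99] — the scale of the screen's effect-size
  filter.  No linkage disequilibrium or realistic allele-frequency
  spectrum is attempted: variants are exchangeable, so power estimates
  here are per-variant and say nothing about LD-induced clumping of
  hits in real panels.
* **Pupation time courses** — each of I_max larvae pupates at a
  logistic(t_mid, 1/a₁) time, so expected cumulative counts follow the
  fitted curve exactly and realizations are integer and non-decreasing
  by construction.
* **Respirometry** — condition mean + mass and activity slopes +
  Gaussian noise, with masses ~N(0.8, 0.08) mg and Poisson(5) activity
  counts.

One global integer seed expands into per-component substreams via
`numpy.random.SeedSequence` spawn keys (survival 0, genotypes 1,
pupation 2, respirometry 3), so generators are pure functions of their
configuration and adding a generator never perturbs existing streams.

What passing tests do *not* show: real panels have LD, relatedness
structure, batch/cohort effects, overdispersion beyond the binomial and
diet-dependent eclosion — none of which are emulated.  Results on
synthetic data validate the machinery, not the biology.

## Problem sizes used in the test suite

Calibration and power checks run at sizes chosen to make their Monte
Carlo error small relative to the margins being tested while keeping
the suite quick to run routinely: GxE calibration/power uses 100 panels
per arm of 60 strains x 3 diets x 2 vials (planted slope SD 0.5);
MANOVA calibration uses 200 null datasets of 60 lines; the
planted-variant power check uses 20 replicates of a 100-line,
500-variant panel with a −0.4 proportion shift on the high-sugar diet
in 20 alternate lines.  The planted shift is negative (sugar-intolerant
alternate allele) because a +0.4 shift on a ~0.76 baseline saturates at
the 0.99 clip and cannot express its full median difference.  GLMM
variance-component recovery runs at 40 strains x 3 diets over 12
replicates.

## Known limitations

* The Laplace approximation is least accurate for small binomial
  denominators; with 30-larva vials its error is far below the 0.05
  log-likelihood tolerance, but single-larva data would warrant
  quadrature.
* The GxE p-value is boundary-conservative (see above); users who need
  calibrated boundary inference should bootstrap.
* The screen performs no kinship correction, LD pruning, or gene
  annotation, by design.
* Bomb-calorimetry energy-equivalent units are instrument-specific and
  carried through symbolically.
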