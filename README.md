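# macrotol

Genotype-by-diet survival analysis for inbred fly panels.

Inbred reference panels — ~200 fully sequenced *Drosophila melanogaster*
lines derived from one outbred population — make it possible to ask
whether tolerance to dietary macronutrients (sugar, fat, starch,
protein) is genetically variable, and which variants drive that
variation.  The experimental design is simple: rear every strain on a
set of defined diets in replicate vials of 30 larvae, count how many
pupate and eclose, and follow pupation daily.  `macrotol` implements the
full downstream analysis of such a screen, plus the indirect-calorimetry
arithmetic used to phenotype metabolic rate in follow-up experiments,
and a synthetic-data generator so the whole pipeline can be exercised
with known ground truth.

## What it computes

**Genotype-by-environment interaction** (`macrotol.survival`).
Vial-level pupation counts y ~ Binomial(n, p) are fitted with
logit p = β₀ + β_diet + b_strain, comparing a strain random intercept
model against one adding treatment-coded random diet slopes with a full
unstructured covariance Σ.  The likelihood-ratio χ² has
k(k+1)/2 − 1 df (20 for six diets); a significant deviance reduction
means the strains differ genetically in their *response* to diet.  The
marginal likelihood uses a deterministic Laplace approximation validated
against dense quadrature and against `lme4::glmer`.

**Multivariate variant screen** (`macrotol.screen`).  Per biallelic
variant, on line x diet survival proportions (raw, or normalized by
subtracting each line's high-protein-diet value): a Pillai-trace MANOVA
with Wolbachia infection as a covariate, two-sided Wilcoxon rank-sum
tests per diet (exact by enumeration for small groups, tie-corrected
normal otherwise), and median-difference effect sizes.  A variant is
selected when MANOVA p < 10⁻⁵, some diet has Wilcoxon p < 0.01 and
|Δmedian| ≥ 0.3 (raw) / 0.2 (normalized) on that same diet.  Variants
need ≥5 lines per allele to be tested.

**Pupation kinetics** (`macrotol.kinetics`).  Cumulative pupae counts
are fitted to I(t) = I_max / (1 + e^(−a₁(t − t_mid))); the day a vial
reaches k pupae follows in closed form as
t = t_mid − ln(I_max/k − 1)/a₁.  Welch t-tests compare half-pupation
times; paired t-tests compare overall pupation between diet pairs, both
Bonferroni-corrected.

**Indirect calorimetry** (`macrotol.metabolic`).  RQ = 0.872 +
0.125·log₁₀(S:Y + 1) from the dietary sugar-to-yeast ratio; energy
equivalent of CO₂ = 37.64 − 16.54·RQ (J mL⁻¹, through the protein and
carbohydrate anchors 25.4 @ 0.74 and 21.1 @ 1.0); power = V̇CO₂ × EE in
mJ h⁻¹; then OLS standardization to reference mass and zero activity.

**Bench assays** (`macrotol.assays`) — bomb-calorimetry gross heat
(Hg = Δt·E/w), trehalose/triglyceride background subtraction, dye-based
food intake, starvation time-of-death from activity traces.

See `docs/methods.md` for models, assumptions, and numerical choices.

## Worked example

```python
import macrotol as mt

cfg = mt.SimulationConfig(
    n_strains=60, diets=("HPD", "HSD", "WD"), n_vials_per_diet=4,
    n_larvae_per_vial=30, n_variants=200,
    minor_line_count_distribution=(3, 30),
    causal_variants=(mt.CausalVariant(10, {"HSD": -0.4}, n_alt_lines=15),),
    seed=42,
)
panel, genotypes, truth = mt.simulate_panel_with_genotypes(cfg)

fit_null = mt.fit_binomial_glmm(panel, random_slopes=False)
fit_gxe = mt.fit_binomial_glmm(panel, random_slopes=True)
comp = mt.compare_gxe(fit_null, fit_gxe)
# GxE: chi2=1517.0, df=5, p=0, dAIC=-1507.0

phen = mt.aggregate_line_phenotypes(panel)
res = mt.screen_variants(mt.filter_variants(genotypes, phen.lines), phen)
res[res.selected]
# the planted variant var_000011, and only it, is selected:
# manova_p=2.1e-08, wilcoxon_p[HSD]=7.4e-07, median_diff[HSD]=-0.39

rq = mt.predict_rq(2.0)                 # high-sugar diet, S:Y = 20/10
mt.energy_equivalent(rq)                # 22.23 J/mL at RQ 0.9316
mt.vco2_to_power(2.5, rq)               # 55.6 mJ/h for 2.5 uL CO2/h
```

The GxE test recovers the planted among-strain slope variance (χ² = 1517
on 5 df: strains genuinely differ in their diet response), the screen
flags exactly the planted sugar-intolerance variant with its −0.39
median shift on the high-sugar diet, and the calorimetry chain turns a
CO₂ trace into power units using the diet's predicted respiratory
quotient.

A command-line interface mirrors the library: `macrotol simulate`,
`macrotol gxe`, `macrotol screen`, `macrotol kinetics`,
`macrotol metabolic`, and `macrotol assays ...` — run any of them with
`--help`.

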