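# Methods

This note documents the models, numerical conventions and design choices
behind `nutrigeo`, and what the synthetic-data generator does and does not
emulate.

## Diet systems

**2-D P:C diets** are standardized for total macronutrient concentration
(default 100 g/L) and parameterized by ratio parts, e.g. a 1:6 diet at
100 g/L has 100/7 g/L protein and 600/7 g/L carbohydrate.  Protein and
carbohydrate carry roughly equal energy per gram, so 2-D analyses are done
in dry-mass units (mg).  Each diet induces a nutritional rail: the unit
vector (p, c)/‖(p, c)‖ in (protein, carbohydrate) intake space.

**3-D P:C:L diets** are standardized for total macronutrient energy
(default 675 J per cube) and parameterized by energy percentages summing to
100.  Lipid is taken to carry twice the energy per mg dry mass of protein
or carbohydrate; the absolute protein/carbohydrate energy density is a
package constant (17 J/mg, ≈4 kcal/g) — only the 2:1 ratio affects any
analysis, since the 3-D currency is energy fractions.  The printed label
"33:33:33" sums to 99 and is renormalized proportionally to exact thirds so
compositions close to 100%; other labels are taken at printed face value.

**Reference designs.** `reference_designs()` encodes the three standard
layouts: a choice experiment of two complementary pairings (1:6 with 3:1,
and 1:3 with 6:1 P:C; 12 colonies each, 200 workers, 12 days), a no-choice
experiment over five P:C rails (8 colonies each, 12 days), and a seven-diet
P:C:L no-choice experiment (33:33:33, 80:10:10, 10:80:10, 10:10:80,
45:45:10, 10:45:45, 45:10:45; 5 colonies each, 200 workers + 4 queens,
14 days).

## Intake accounting

Per day and cube, dry harvest is `initial_wet × r − leftover_dry`, where
`r = control_dry / control_wet` is that day's evaporation-control ratio.
Controls are per record (one per day per diet type); records with missing
controls fall back to the colony-wide mean ratio.  Negative computed
harvests — measurement noise around untouched cubes — clamp to zero with a
logged warning rather than propagating.  Hoarded and scattered masses are
end-of-experiment totals per diet color, attributed to cumulative
accounting; `consumed = harvested − hoarded − scattered` is an exact
identity, and a colony whose piles exceed its harvest raises a
mass-balance error naming the colony.  Hoarded/scattered percentages are
averaged as per-colony ratios (zero-harvest colonies flagged and excluded),
not pooled masses.

## 2-D geometry

The intake target is the across-colony mean of cumulative **consumed**
(not harvested) protein and carbohydrate, with per-axis standard errors.
Consumption is used because post-harvest processing is small and
consumption tracks harvest closely; both ratio conventions are reported
(C:P ratio of means as the headline, mean of per-colony ratios alongside).

Rule-of-compromise predictions per rail: *equal distance* is formalized as
constant total intake, the on-rail point with P + C = P_T + C_T (with
equal-concentration diets this is the natural mass formalization of a
straight-line array); *closest distance* is the orthogonal projection of
the target onto the rail, clamped to the nonnegative ray.  The two
coincide exactly when the target lies on the rail.

The classifier compares summed squared distances (SSE, mg²) of the
observed per-rail mean intakes to each rule's predictions and returns the
smaller-SSE rule, unless the SSE ratio falls within [1/1.5, 1.5], which is
declared *indeterminate*.  The original assessment of array shape is
visual; the SSE classifier is this package's quantification, and the 1.5
band was chosen so noise-free arrays are never indeterminate while heavily
overlapping fits decline to choose.  Under the generator's study
conditions (CV 0.15, 8 colonies per rail) the classifier recovers the true
rule in ≥95% of replicates (tested at 500).  A total-least-squares R²
("linearity") and the across-rail total-intake ANOVA accompany the
classification.  Rail-aligned ("pythagorean") error bars are
√(SE_P² + SE_C²) laid along the rail through the mean point.

## 3-D response surfaces

Surfaces are ordinary least squares on raw energy percentages (0–100), not
coded units, with terms {1, P, C, P², C², P·C}.  The intercept is
estimated freely.  Quadratic terms with p > α (default 0.05) are removed
simultaneously and the model refit once; linear and cross-product terms
are always retained.  Lack of fit decomposes residual SS into pure error
(within replicated design points, df = n − m) and lack of fit
(design-point means vs the surface, df = m − p); F is their mean-square
ratio.

Maximization over the closed simplex is exact: the interior stationary
point (when the Hessian is nonsingular and the point feasible), the three
edges as closed-form 1-D quadratics, and the vertices are enumerated and
the best value returned.  This was validated against brute-force
evaluation on a 0.1%-step simplex grid for 1,000 random coefficient draws.
A `domain` switch restricts P and C to the observed design range (10–80%)
instead of the full simplex; the full simplex is the default.

A note on printed coefficient tables: re-maximizing a surface from
3-decimal rounded coefficients can differ by a few percent from an
optimum computed from unrounded ones (for the percent-survival surface
above, the protein-free edge optimum is C* = 7.120/(2×0.058) ≈ 61.4).  The
package always reports the maximizer implied by the coefficients it is
given.

Thin-plate-spline landscapes use the standard r²·log r radial basis with
affine part and roughness penalty λ (default 0.001, matching common
practice for these landscapes); replicated design points are aggregated to
their means before fitting, so as λ → 0 the spline interpolates
design-point means.  `scipy.interpolate.RBFInterpolator` provides the
solver; an independently coded radial-basis linear solve serves as the
test oracle.  Landscapes are evaluated on a 1%-resolution grid masked to
the simplex, and are only rendered for responses whose overall model is
significant at α.  The FMN is the region at or above the q-quantile
(default 0.9) of in-mask consumption values, reported as % of simplex
area.

## Treatment statistics

One-way ANOVA uses classical sums of squares (df k−1, N−k); Tukey HSD
adjusted p-values come from the studentized-range distribution
(statsmodels), and compact letter displays use the insert-and-absorb
algorithm.  Paired t-tests on colored-diet hoard/scatter masses are
two-sided on differences; constant nonzero differences raise a
degenerate-variance error rather than reporting an infinite statistic.

Worker survival is modeled as binomial counts (alive vs cumulative dead)
with a logit link, fixed effects numeric day + diet + day×diet, and a
Gaussian random intercept per colony-source bin.  The marginal likelihood
is integrated exactly over the random effect with 21-node Gauss–Hermite
quadrature and maximized by BFGS (β, log σ); when the variance estimate
collapses, the σ = 0 boundary is refit and, if not worse, reported — in
that case the coefficients equal the ordinary fixed-effects GLM exactly,
which is the cross-check used in the tests.  Term tests are
likelihood-ratio chi-squares with df equal to the number of coefficients
dropped.  Census schedules follow collection practice: 4-day intervals for
the 2-D assay, daily for the 3-D assay.  Fully saturated data (no deaths
anywhere, or no survivors) return the saturated answer with a
degenerate-fit warning instead of a divergent fit.  α = 0.05 throughout;
no multiplicity correction beyond Tukey.

## The synthetic-data generator

The generator emulates colony-level harvest with known ground truth; its
defaults are the study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| `intake_target` | (40, 60) mg | cumulative consumed P, C per colony; C:P = 1.5 |
| `total_intake_cv` | 0.15 | lognormal CV of intake noise |
| `rule` | equal_distance | no-choice regulation strategy |
| `hoard_frac` / `hoard_sd` | 0.10 / 0.078 | Beta-distributed fraction of harvest hoarded |
| `scatter_frac` / `scatter_sd` | 0.052 / 0.025 | fraction scattered |
| `control_dry_wet_ratio` | 0.35 (±0.02 daily) | evaporation model |
| `surface_coeffs` | (10, 0.501, 1.323, 0, −0.011, 0.009) | consumed mg vs (P%, C%) |
| `surface_noise_sd` | 10 mg | Gaussian response noise |
| `death_hazard_fn` | logistic in P% | ~2%/day at low protein to ~8%/day at 80% |
| `egg_rate_fn` | quadratic in (P%, C%) | Poisson mean, peaks at balanced P:C |
| `bin_effect_sd` | 0.5 | logit-scale SD of bin random intercepts |

The target magnitude (~100 mg dry mass per colony over the experiment) and
the hazard scale (14-day survival spanning ~30–75% across compositions)
were chosen once as realistic for 200-worker colonies of a small ant and
are consistent with the consumption scale implied by the 3-D surface
defaults.  Choice colonies hit their lognormal target draw by solving the
2×2 diet-mixing system (draws outside the rail cone are projected onto the
nearest rail; an infeasible *mean* target raises an error).  No-choice
colonies sit at their rule's prediction times a mean-1 lognormal
multiplier.  Hoard/scatter fractions are drawn once per colony (Beta with
the configured mean/SD) so the pooled percentage of harvest is an unbiased
estimator of the configured fraction.  Per-day masses are back-computed
through the evaporation model with Dirichlet day weights, so the recorded
cube and control masses reproduce the colony's cumulative harvest exactly
— with all noise off, recovered intake equals truth to 1e-9 relative.
Deaths are daily binomial draws (dead workers not replaced after day 1);
an exactly zero hazard produces exactly zero deaths.  Random streams are
keyed by (seed, stream, colony index), so a colony's data are independent
of generation order and runs are byte-reproducible.

What the generator does **not** emulate: individual forager behavior and
recruitment dynamics, within-day feeding bouts, nutrient-selective
hoarding (a colony's hoard fraction is common to both diet colors except
through the optional misclassification rate, default 0), chemical
composition of hoarded material, day-varying hazards, and brood stages
beyond egg counts.  Passing recovery tests therefore demonstrates that the
estimators are consistent and the accounting exact under the stated noise
model — not that real colonies obey it.

## Problem sizes

The recovery studies use 200 replicates of the study-sized designs
(22-colony choice, 11-colony single pairing); classifier validation uses
500 replicates of the 40-colony no-choice design; the maximizer is checked
against 1,000 random surfaces on a 0.1% grid.  These sizes give
Monte-Carlo standard errors an order of magnitude below the effects being
checked while keeping the full suite under a minute.

## Known limitations

* The binomial mixed model supports a single random intercept (the
  colony-source bin); crossed or nested random effects are out of scope.
* Choice-experiment infeasibility handling (projection onto the nearest
  rail) slightly truncates the intake distribution at extreme CVs.
* The lack-of-fit test requires replicated design points; single-replicate
  designs report no lack-of-fit rather than an approximate one.
* Thin-plate-spline smoothing λ is fixed by configuration; no generalized
  cross-validation is performed.
* The compact-letter display is exact for the Tukey pattern given but can
  produce more letters than the minimal covering in adversarial patterns.
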