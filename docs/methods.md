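# Methods

## Model and estimands

`sacontrast` fits fixed-effects linear models by least squares with
sequential (Type I) sums of squares, in a fixed term order:

1. population (sum-to-zero contrasts; absorbs intrinsic quality
   differences among populations, and — because populations are nested in
   origin environments — all origin-level main structure),
2. test environment (quality differences among assay media),
3. **genetic SA contrast**: the sympatric indicator residualized against
   the preceding blocks, which confines it to the test × origin
   interaction space,
4. interaction remainder: an orthonormal basis of the remaining
   (J−1)(K−1) − 1 interaction directions,
5.–8. the field-phase (Δ) counterparts of 1–4, multiplied by the
   field-phase indicator; the Δ-population block includes the overall
   field-vs-common shift, and the field-phase SA contrast is the
   **plastic SA term**,
9. the rearing-unit adjustment: fixed arena contrasts centered within
   population × phase (so between-arena differences attributable to a
   population stay in the population block), or a centered log egg-density
   covariate for survival, or nothing for no-choice fecundity.

Each F statistic divides the SA mean square by the corresponding
interaction-remainder mean square, df (1, (J−1)(K−1)−1); p-values are
upper-tail F probabilities with no multiple-testing correction across
traits. The variance fraction φ = (MS_constrained − MS_free)/MS_constrained
compares an independently fitted constrained model (SA column omitted,
interaction block at full (J−1)(K−1) df) with the free fit. Because the
two mean squares use different df, φ ≤ 1 but may be negative. Note the
algebraic identity for J = K: φ = 1 − (df_full/df_rem)·SS_rem/(SS_SA+SS_rem),
which ties φ deterministically to F — a useful internal consistency check.

**Why the interaction remainder, not the residual, in the denominator.**
Real data contain genotype × environment structure that has nothing to do
with sympatry. Testing the SA contrast against the remaining interaction
directions means such structure inflates the denominator and the test gets
*conservative* rather than anticonservative — the appropriate failure mode
for an adaptation claim. The cost is very few denominator df (3 for three
environments).

**Estimates and standard errors.** The reported SA estimates are the
coefficients of the *raw* sympatric indicator (and field × indicator) in
the full joint fit; these equal the generative sympatric-minus-allopatric
contrasts exactly, even when both effects are nonzero, whereas the
sequential (orthogonalized) genetic coefficient would absorb part of a
nonzero plastic effect. Standard errors scale the coefficient variance
factor [(XᵀX)⁻¹]ss by the same denominator MS as the F test, keeping
t² = F whenever the two SA columns are orthogonal (balanced designs with
a single nonzero effect). A consequence of the Type I order worth knowing:
the *F test* for the genetic term is credited before the plastic term, so
a purely plastic signal contributes part of its magnitude to F_genetic;
the joint estimates separate the two cleanly, so a significant F_genetic
with a near-zero genetic estimate is the signature of that situation.

## Transforms and data rules

- Count traits (preference, fecundity): response = log(eggs + 1). The
  +1 offset keeps zero counts finite; it is recorded in output metadata
  and configurable (`TraitSpec.log_offset`).
- Survival (performance): p = adults/eggs capped at 1 (miscounted
  low-egg vials occur in practice); capped records are retained and
  flagged so a sensitivity re-run can drop them. Response = arcsin(√p),
  the angular transform. Vials with zero eggs have an undefined
  proportion and are excluded with a warning.
- Environment labels are matched case-insensitively after trimming; no
  fuzzy matching. Generation labels G0/G1 map to the field phase, G2/G3
  to the common phase.

## Numerical choices

- Sequential fitting uses block Gram–Schmidt with reorthogonalization;
  columns whose singular values fall below 1e-10 (relative) after
  residualization are dropped and logged (e.g. a constant egg-density
  covariate under fixed binomial trials). Block df = rank actually added.
- A denominator MS below 1e-12 of the total MS is treated as zero
  (noise-free data): the F statistic is reported as undefined with a
  `degenerate` flag rather than as infinity.
- If every record is sympatric the SA contrast has zero norm and the fit
  raises an explicit error; with J = K = 2 the interaction is fully
  consumed by the SA contrast and the test raises an error suggesting
  more environments.
- Unbalanced data use the identical construction; nothing downstream
  assumes orthogonality (sequential SS handles non-orthogonal blocks).
- Fixed unit blocks are absorbed exactly by within-unit demeaning
  (Frisch–Waugh) in the joint coefficient fit, and are never needed for
  the sequential SS of the SA and interaction terms because they enter
  last; the simulation loop exploits this by caching the orthonormal
  block basis per layout (the cached path is asserted equal to the full
  fit in the test suite).

## Descriptive layer

Effect means residualize the data against a nuisance-only model
(population, test environment, unit adjustment; no SA, no interaction).
The genetic mean of a (test, origin) cell is the mean common-phase
residual; the plastic mean is the field mean minus the common mean.
Genetic CIs use the common-phase residual spread. The plastic CI treats
the *excess* of the field-phase variance over the common-phase variance as
the variance attributable to plasticity — when the common-phase variance
is larger the interval cannot be formed and is reported absent. This
construction is a reconstruction from the observed behavior of such
intervals (they fail exactly when the common phase is noisier) and should
be read qualitatively.

Weighted Pearson correlations use weighted moments throughout and a
Fisher-z 95% CI with effective sample size n_eff = (Σw)²/Σw²; with equal
weights this is exactly the ordinary Pearson coefficient. Weights are
record counts (vials/arenas) per population.

## Synthetic data generator

The generator emulates the study conditions and doubles as the fixture
factory for the test suite. Defaults (all on the link scale):

| parameter | default | meaning |
|---|---|---|
| layout | 3 envs; 9/3/13 pops (unbalanced) or 9/9/9 (balanced) | study sampling |
| units_per_pop_phase | 8 | arenas/vial batches per population and phase |
| obs_per_unit_env | 1 | one observation per unit per test environment |
| mu | 3.0 (log scale ≈ 20 eggs); 0.0 for logit survival | baseline |
| sd_pop | 0.5 | population quality (dominant nuisance) |
| sd_test_env | 0.3 | test-environment quality |
| sd_interaction | 0.1 | non-sympatric genotype × environment structure |
| sd_unit | 0.3 | arena/batch effects |
| sd_res | 0.5 | residual link-scale noise |
| trials_binomial | 30 | eggs per survival vial |

The magnitudes follow the ordering visible in such experiments —
population quality spread largest, genuine interaction structure smallest
— and give ≈ 1200 records, matching the real experiment's size. Families:
normal (identity; the response is already on the analysis scale), Poisson
egg counts (log link, analysed as log(eggs+1)), binomial adults-of-eggs
(logit link, analysed as arcsine-root survival). The Poisson and binomial
routes deliberately reproduce the mismatch between the generative link and
the analysis transform that real data impose.

Field-phase deviations (Δ population, Δ environment, Δ interaction) are
drawn independently with the same SDs as their shared counterparts, so
both F-test denominators face genuine interaction variance under the null.

**The null is an exact null.** Interaction draws (shared and field-phase)
are double-centered and then stripped of their sympatric component *in the
record-count-weighted cell metric* — the same metric in which the model
residualizes its SA contrast. Without this, every "null" replicate would
carry a random, genuinely realized sympatric contrast of order
sd_interaction and a false-positive-rate study would not be measuring
false positives. With it, `sa_genetic_true`/`sa_plastic_true` are the only
sympatric signals, injected into sympatric cells of both phases (genetic)
or of the field phase only (plastic).

Seeding: a master seed spawns per-replicate substreams through
`numpy.random.SeedSequence([master, index])`; every dataset is a pure
function of its config.

## What the simulations show — and what they cannot

Under these conditions both F tests are conservative: across the six
family × layout conditions the empirical false-positive rate at α = 0.05
stays in the 0.1–4% range, well below nominal for the normal and Poisson
families (≤ ~2.5%) and closest to the bound for the binomial family
(~3–4%), where logit-scale population variance makes the arcsine-scale
cell variances heteroscedastic. Power for the plastic term rises with
effect size and with the design multiplier (X1 → X10), but saturates for
large designs when non-sympatric interaction variance is present, because
that variance scales into the denominator along with the signal.

The generator does not emulate: temporal batch structure (populations
assayed on different dates), overdispersion beyond the link-scale normal
components, missing cells, correlated preference/performance errors
within vials, or microbiome-type vertically transmitted effects.
Passing calibration here therefore demonstrates the statistical behavior
of the method under its own assumptions, not robustness to every field
complication.

## Problem sizes used in the shipped studies

The calibration study runs 1000 replicates per condition (six conditions)
and completes in a few seconds thanks to the per-layout compiled design;
the power study in the test suite uses 300 replicates per condition at
X1 and X10. Larger designs (X100) are supported by `scale_design` but not
exercised by default.

## Known limitations

- The plastic-effect CI construction in the descriptive layer is a
  qualitative reconstruction (see above).
- SEs are tied to the F-denominator MS by design; analyses that computed
  SEs from the global residual MS will report somewhat different SEs for
  the same estimates.
- With only three environments the denominator has 3 df; the tests are
  honest but blunt, and single-generation tests with two environments are
  impossible (the dual test or more environments are required).
- No mixed-model (random-effects) variant is provided.
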