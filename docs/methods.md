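# Methods

## The analysis pipeline

### Per-pot aggregation

Above-ground and biomass traits are measured per plant; root traits
(projected area, length) only per pot, because root systems overlap in the
images. Before any model, per-plant traits are summed over the plants of a
genotype within a pot (six in pure stands, three in mixtures); leaf N is
averaged. All downstream quantities live on this pot scale, which keeps
pure and mixed stands directly comparable (both pot types hold six
plants).

### Adjusted references

Harvests are staggered across four dates within each block × treatment, so
raw pure/mixed comparisons would confound date with composition. Instead,
references are built from linear mixed models (REML, via statsmodels
MixedLM):

* fixed effects: block and harvest/measurement date (sum-coded, so the
  intercept sits at an *average* block and date) and treatment (R+ as the
  baseline level);
* random effects: variety identity for pure stands, *oriented* pair
  identity (focal|neighbour) for mixtures — the orientation gives each
  variety its own value within each mixture — with a random intercept and,
  by default, a random slope on the treatment contrast.

The adjusted value under treatment *k* is μ̂ + τ̂_k + BLUP_intercept
(+ BLUP_slope when *k* is the non-baseline level). Root traits are modelled
without a date term (all root images are captured on one day).

Choices worth making explicit:

* The grand intercept is included — references must live on the biomass
  scale — and block/date are evaluated at their average via sum coding.
* Random-slope fits whose slope variance collapses to the boundary are
  refit with an intercept-only random effect and flagged singular.
* Effectively noiseless inputs (zero residual variance) make REML
  degenerate; the fitter detects this and uses the exact λ→1 shrinkage
  limit, estimating group deviations as fixed effects by OLS. This keeps
  the contract "noiseless simulation is recovered exactly" testable.

### Diversity effects

RY, RYT and the CE/SE partition follow the standard additive partitioning
of the net biodiversity effect with N = 2, expected RY = 0.5, ΔRY = RY −
0.5 and M the adjusted pure-stand biomass. SE uses the **population**
(divisor-N) covariance: with the sample (divisor N−1) convention the
identity CE + SE = Σ ΔRY_i·M_i would fail for N = 2. Y_O is the sum of the
two oriented adjusted pair values, keeping every partition input on the
same adjusted scale.

Known property: because the pure references and the pair values come from
two models with different shrinkage (36 vs 108 groups, different replicate
counts), the ratio RY carries a small upward bias — about +0.8% on mean
RYT at the default noise levels, measured under the no-interaction
scenario. This is inherent to BLUP-ratio estimators, affects both
treatments equally, and is far below the effects of interest (−13% under
resource limitation); the null-scenario test budgets for it explicitly.

### Treatment comparisons and ANOVA

Fixed-term tests are Type-III-style Wald F tests. Denominator degrees of
freedom use the Satterthwaite approximation: the REML log-likelihood of
the single-grouping-factor model is re-expressed as a function of the
variance parameters, its Hessian is obtained by central finite
differences, and each (eigen)contrast's df is 2g²/(∇g'A∇g); multi-df terms
combine eigencontrast dfs as in lmerTest. Kenward–Roger df were
deliberately not implemented: they require the bias-adjusted
small-sample covariance machinery, and in the balanced designs this
package targets the two approximations coincide (the test suite
cross-checks F, df and p against lmerTest on a balanced fixture). Boundary
or deterministic fits fall back to residual df, flagged.

### Trait composition

Features are the mean and absolute difference of the two varieties'
adjusted pure-stand traits — five traits, ten predictors. Response and
predictors are z-scored within treatment (divisor n−1). All 2^10 subsets
are fit by OLS; exhaustive enumeration replaces stepwise search because it
is exact, cheap at this scale, and can only improve on a backward pass
(property-tested). Ranking uses AICc = AIC + 2k(k+1)/(n−k−1) with k
counting intercept, slopes and the residual variance. The top 10 models
get Akaike weights w ∝ exp(−Δ/2); averaging is *full* by default (a model
without a term contributes 0; conditional averaging is available as an
option), with unconditional variance Σ w[SE² + (β − β̄)²], ±1.96·SD
confidence intervals, importances as summed weights, and the mean adjusted
R² over the top set. Interactions and polynomial terms are out of scope.

### Hierarchy and plasticity

HD = (A_focal − A_neighbour)/A_focal is normalized by the focal area
(deliberately asymmetric). The plasticity index compares the adjusted
observed mixture pot root area with the mean of the two components'
pure-stand references, all on the pot scale — pure and mixed pots hold the
same number of plants, so the pot-level ratio equals the per-plant one.
Positive values mean root area increased in the mixture; a
`literal_order` flag flips the sign for the opposite word-order
convention. The index is reported as a fraction (a value of −0.10 is a 10%
reduction).

## The synthetic experiment generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream stage is validated without any external data.

### Design

36 genotypes; every genotype appears in exactly three binary mixtures; 54
mixtures total; pure stands and mixtures replicated once per block in 3
blocks × 2 treatments (540 non-control pots); six control pots of a check
variety per block per treatment (36); pots split evenly across four
harvest dates within each block × treatment. Mixture drawing uses a seeded
configuration-model construction (each genotype's quota of stubs shuffled
and paired, redrawing on self-pairs or duplicates); duplicate pairs across
the panel are forbidden.

### Competition model

Each genotype carries an intrinsic per-plant projected root area A_g — the
area expressed in pure stands, where the below-ground arms race against
its own genotype is fully engaged. In mixture, the focal plant
re-equilibrates via the geometric plastic response

    a_f = A_f^(1−θ_f) · (κ·A_n)^θ_f

* κ = 0.60 is the *non-self discount*: a different genotype is perceived
  as a weaker competitor than self, so both partners disengage; pure
  stands (neighbour = self, no discount) realize exactly A_f.
* θ_f = θ_k · (w·A_f + (1−w)·Ā_pair)/Ā_panel, capped at 0.95, with
  w = 0.4: plasticity grows with how competitive the pot is, and
  large-rooted genotypes — whose pure-stand area is most inflated by
  escalation — are also the most plastic. θ_k is 0.3 under R− and 0 under
  R+ (no water/nutrient competition, no arms race).

Per-plant biomass is

    b = m_k · a^γ / (1 + δ_k·ā_pot) · block · date · lognormal(−σ²/2, σ)

with γ = 1, a shared-resource penalty on the pot-mean realized area
(δ = 2.5·10⁻⁵ mm⁻² under R−, 0 under R+), multiplicative mean-one block
(0.97–1.03) and harvest-date (0.94–1.06) effects, and σ = 0.10 residual.
The biomass scale m_k is calibrated per treatment so the expected
pure-stand pot total matches 2364.71 mg (R+) and 1947.35 mg (R−). The
root:shoot split uses ρ = 0.48 (R+) and 0.82 (R−) with small per-plant
noise; totals equal shoot + root exactly.

A purely symmetric response (no κ discount) provably cannot produce
underyielding: with biomass linear in area, RYT = [½(u+v) + δā]/(1+δā)
with uv = 1, hence RYT ≥ 1 by AM–GM. Mutual disengagement toward a
discounted non-self target is the minimal extension that yields the
resource-limited pattern — mean RYT < 1 driven by the *mean* root area of
the pair, losses of high-hierarchy genotypes exceeding the gains of their
partners, and reduced mixture root area correlating with reduced RYT.

### Panel and trait structure

Intrinsic areas are lognormal around 4000 mm² (σ_log = 0.30, clipped at
±2 SD — a varietal panel spans a limited range, and one extreme genotype
would otherwise dominate every mixture it enters). The mean follows from
the biomass-per-area slope of the pot totals (≈0.08 mg/mm² at 1947 mg per
pot). Leaf and tiller counts and leaf N are monotone noisy functions of
shoot biomass with treatment shifts (resource limitation lowers the counts
and raises leaf N from 2.95% to 3.32%) plus genotype-level deviations
drawn independently of area, so above-ground traits are only loosely
coupled to below-ground competitiveness. Pot root area is the sum of
realized plant areas with 5% lognormal measurement noise; root length is
proportional to area (0.25 cm/mm², i.e. an effective root diameter of
0.4 mm) with a genotype-level length:area deviation.

### What the generator does *not* emulate

Within-season growth dynamics, spatial structure inside a pot, genotype ×
block interactions, kin recognition beyond the self/non-self dichotomy,
root-image segmentation errors that correlate across pots, and any
above-ground (light) competition. Passing tests therefore demonstrate that
the *pipeline* recovers the structure this model encodes at realistic
noise levels — not that real wheat obeys the model.

## Problem sizes and numerics

Simulation-based tests run one full full-scale experiment (576 pots,
3240 plants) per scenario and share it across tests; calibration tests use
30–400 seeded replicates of deliberately small models. Mixed-model fits
try several optimizers (default, Powell, CG) and keep the first converged
one; variance ratios below 10⁻⁸ of the total variance count as boundary.
Finite-difference steps for the Satterthwaite machinery are relative
(10⁻⁴). All randomness flows from a single seed; pipeline outputs are
byte-identical across reruns of the same configuration.

## Known limitations

* Satterthwaite (not Kenward–Roger) df; indistinguishable in balanced
  designs, slightly liberal in strongly unbalanced ones.
* One grouping factor per model; no crossed random effects, no spatial
  correlation.
* The BLUP-ratio bias described above (~+0.008 on RYT at default noise).
* AICc model averaging assumes Gaussian OLS candidates; responses are
  standardized, not transformed.
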