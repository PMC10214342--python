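# Methods

## Model

Let `y` be the natural log of SG-corrected urinary cortisol (ng/ml SG).
The observation model is Gaussian and homoscedastic:

    y = X beta + sum_k Z_k u_k + eps,        eps ~ N(0, sigma2 I)

Fixed effects `X` contain an intercept, linear and quadratic z-scored
time of day (t, t2), and every covariate — demographic class (adult
male [reference], cycling female, lactating female, immature male,
immature female), z-scored age, season (sine and cosine of
2*pi*doy/365.25), z-scored adult sex ratio, z-scored community size,
and assay method (new/old internal standard) — interacted with each of
{1, t, t2}. Categorical covariates are treatment-coded; this affects
the interpretation of individual beta's but not any variance partition.

Random terms group reaction-norm deviations (intercept and, where the
variant includes slopes, t and t2) by: community ("group"),
community-year, research project (a technical term), individual,
individual-year, mother, and — in the animal models — an additive
genetic effect with covariance `A (x) Sigma_genetic`, where `A` is the
pedigree additive relationship matrix. Model variants:

| variant               | random structure                                      |
|-----------------------|-------------------------------------------------------|
| null                  | intercepts for group, group-year, project              |
| intercepts            | + intercepts for individual, ID-year                   |
| reaction_norms        | + (t, t2) slopes on individual and ID-year             |
| full_heritability     | (1, t, t2) on all seven terms incl. mother and genetic |
| trait_heritability    | all seven terms, intercepts only (residual usable)     |
| tai_heritability      | full model restricted to one site's communities        |
| dominance_heritability| full model + dominance covariate                       |
| demographic:*         | reaction_norms on one demographic subset               |

Individuals with no sampled mother receive unique singleton maternal
levels, so the maternal factor is defined for every row; singleton
levels contribute to `Sigma_mother` estimation only weakly.

## Pedigree and A matrix

Unknown parents are founders: unrelated and non-inbred. `A` is built
parents-first by the tabular recursion `A_ii = 1 + 0.5 A_{dam,sire}`,
`A_ij = 0.5 (A_{j,dam} + A_{j,sire})`; sampled individuals absent from
the pedigree are added as founders with a warning. A direct recursive
kinship function (exponential-time, small pedigrees only) serves as an
independent oracle in the tests. In the model the genetic term is
non-centered — iid per-individual deviates premultiplied by a Cholesky
factor of the sampled-individual submatrix of `A`; if `A` is
numerically singular (duplicate founders) the diagonal is jittered by
1e-8 before factorization.

## Priors and sampling

Fixed effects: N(0, 1) (covariates are z-scored; the response is a log
concentration of order unity in spread). Random-effect covariances use
the Huang–Wand hierarchical inverse-Wishart: for a d-dimensional term,
`Sigma | a ~ IW(nu + d - 1, 2 nu diag(1/a_j))`,
`a_j ~ IG(1/2, 1/10^2)`. With nu = 2 (used for the 3x3 reaction-norm
terms) the implied marginals are half-t(2, 0, 10) standard deviations
and exactly uniform correlations; for 1-D terms and the residual SD,
nu = 3 gives half-t(3, 0, 10). Scale 10 is extremely diffuse relative
to the unit-scale data, so the choice of 2 vs 3 degrees of freedom is
immaterial in practice; nu = 2 was preferred for the multivariate terms
to keep the correlation prior exactly uniform.

Sampling is a conjugate block Gibbs sweep:

1. all coefficients (beta and every u_k) jointly from their Gaussian
   full conditional — one Cholesky solve of the mixed-model normal
   equations per sweep; the joint update is what keeps heavily
   confounded terms (individual vs maternal vs genetic) mixing;
2. sigma2 and each Sigma_k from conjugate inverse-gamma /
   inverse-Wishart conditionals with their auxiliary a's;
3. one generalized-Gibbs scale move (Liu–Sabatti group move, sampled
   by slice sampling on log gamma) per term and reaction-norm
   dimension, jointly rescaling u and Sigma. This is the package's
   remedy for the near-zero-variance funnel of centered Gibbs
   samplers; it was validated by comparing full posterior quantiles
   against a long run of the plain sampler on the same data.

Defaults are 4 chains x 4000 iterations with half warmup; all test and
permutation fits use reduced chains via `SamplerSettings`. Convergence
is summarized with split-Rhat and ESS (arviz); any Rhat >= 1.1 raises a
warning state, never a silent success. Identical seeds and settings
reproduce draws exactly.

Pointwise log-likelihoods are stored for every fit; model comparison
uses PSIS-LOO (`arviz.loo` / `arviz.compare`) with the conventional
Pareto-k 0.7 diagnostic threshold.

## Variance partitioning

All quantities are per-draw ratios summarized afterwards (median,
equal-tailed 95% interval) — this ordering is what produces credible
intervals on proportions. Draws with zero denominators are undefined
and dropped with a logged count rather than coerced to 0. With
`V_total = V_individual + V_ID-year + V_group + V_group-year`
(intercept components):

* long-term trait repeatability `= V_individual / V_total`;
  short-term `= (V_individual + V_ID-year) / V_total`
* reaction-norm repeatability per component
  `= V_individual / (V_individual + V_ID-year)`
* between- vs within-community split per component:
  `V_group / (V_group + V_within)` with
  `V_within = V_genetic + V_mother + V_group-year + V_individual +
  V_ID-year`
* within-group heritability `h2 = V_genetic / V_within` and maternal
  effects `m2 = V_mother / V_within` (the five within shares sum to 1)
* trait heritability (no-slope model only)
  `= V_genetic / (V_within + V_residual)`

The project term is technical and excluded from all denominators by
default; `include_technical=True` adds it to `V_within`, which
mechanically lowers the biological shares (the convention used when
reporting permutation histograms). The within-year/between-year
repeatability pair is reported exactly as computed; reference analyses
of this design have reported slightly inconsistent rounded values for
the within-year figure, and no attempt is made to match one of them.

## Permutation null

Because variance shares are bounded below, credible intervals alone
cannot establish that h2 or m2 exceeds chance. The null permutes
sampled individuals' identities within communities in `A`
(`A_perm = P A P'` — spectrum and within-group entry multisets
preserved) and maps mothers through the same permutation
(`mother_perm(i) = mother(pi(i))`), so permuted maternal sibs are
always genetic sibs: concordance holds by construction. Unsampled
pedigree ancestors keep their labels (permuting them cannot change the
likelihood). Each permutation refits the animal model — by default
with shorter single chains, since only posterior medians feed the null
— and one-sided exceedance probabilities count permutations with
statistic >= observed, ties counting toward the null (conservative);
the lower-tail count is also recorded. Failed refits are logged and
excluded from counts, never silently dropped.

## Synthetic data

The generator mirrors the study system: communities with founder
"immigrants" and two offspring generations (maternal sibs, paternal
half-sibs, full sibs; ~60% of sires known), one reproductive event
history per adult female so states are always assignable, sampling
clock times uniform on [06:00, 18:00] with each individual-year forced
to satisfy the 3-sample / 6-h / both-halves rule, specific gravity
uniform on [1.008, 1.035], and an assay-method changeover date at the
window midpoint. Covariates are encoded through the same code path the
pipeline uses, so generative variances are defined on exactly the
scale the model fits. The default ("study") preset uses 5 communities
x 34 individuals and a variance structure that qualitatively mirrors
the study system (community-dominant intercept variance, maternal
share larger than genetic); the "recovery" preset (3 x 15, ~20 samples
per individual, within-group intercept shares genetic 0.1 / maternal
0.2 / group-year 0.4 / individual 0.2 / ID-year 0.1) defines the
parameter-recovery conditions, and "tiny" (3 x 8) the smoke/permutation
scale. What the generator does *not* emulate: behavioral covariance
(rank dynamics, association networks), measurement-batch drift beyond
the single changeover, missing-data mechanisms, or pedigree errors —
so passing recovery tests demonstrates correctness of the estimator
under the declared model, not robustness to those field realities.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale as a deliberate
design point: parameter recovery uses 20 replicates of the recovery
preset with 2 chains x 800 iterations; permutation calibration uses 20
permutations per replicate with 400-iteration single chains (observed
and permuted fits share settings inside calibration tests so the null
rank is exchangeable). Permutation *power* against a maternal share of
0.3 requires more maternal structure than the smoke scale offers — the
statistic and its null are driven by how many dams with multiple
sampled offspring exist — so the power check runs at the recovery
scale with a low founder fraction (0.25), a converged two-chain
observed fit, and short single-chain permutation refits. The
acceptance script uses 4 communities x 20 individuals with 12
permutations. Degenerate inputs:
single-level grouping factors, non-finite responses, and pregnant-state
ambiguity (pregnancy takes precedence over lactation, maximizing
exclusion safety) are all hard errors or logged exclusions. Calendar
year defines "year" in the composite group-year and ID-year factors;
the morning/afternoon boundary is 12:00 (configurable); the quadratic
time term is the square of the z-scored linear term; cortisol is
logged with the natural log (base affects scale, never variance
ratios).

## Known limitations

* The genetic/maternal/individual split rests entirely on pedigree
  structure; with shallow pedigrees the h2 and m2 posteriors are wide
  and strongly prior-influenced near zero.
* The between-community share is estimated from few community levels
  and is correspondingly uncertain under its heavy-tailed SD prior.
* Covariance shares between intercept and slope components are not
  reported (no agreed formula); only the diagonal variance shares are.
* REML/point-estimate backends are not provided; inference is fully
  Bayesian.
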