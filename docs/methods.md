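# Methods

`epiclonal` implements the statistical analysis of a clonal common-garden
epigenetics study: a plant cultivar propagated only by cuttings is sampled
across contrasting climates, the cuttings are raised in one glasshouse, and
the package asks (i) whether DNA-methylation variation exists and is
structured by origin despite the absence of genetic variation, and
(ii) whether autumn phenology (bud set) of the cuttings carries a
transgenerational signal of the home-site climate.

## Clone identification (SSR)

Samples are grouped into multilocus genotypes (MLGs) by exact per-locus
allele-multiset identity; heterozygote phase is ignored.  The modal MLG is
the reference clone (ties broken by lexicographic MLG id, with a warning).
A sample is a clone member if it differs from the reference by at most
`max_mismatch` allele slots (default 1) and every differing allele is off by
exactly one repeat unit — the signature of a somatic stepwise mutation.
Repeat-unit lengths come from an optional per-locus table (default 2 bp,
dinucleotide).  The genotyping error rate is

    100 * n_discordant_scores / (n_loci * n_replicated_individuals)

over replicated samples, where a discordant score is a (sample, locus)
whose allele multiset differs between the two independent analyses.

## MS-AFLP epigenotype scoring

Each locus is scored twice, with the isoschizomers HpaII and MspI, which cut
the same CCGG motif but differ in methylation sensitivity.  The presence
pattern maps to a methylation state:

| HpaII | MspI | state |
|-------|------|-------|
| 1 | 1 | U — unmethylated |
| 0 | 1 | I — internal-cytosine CG methylation |
| 1 | 0 | H — hemimethylation |
| 0 | 0 | A — ambiguous: full methylation *or* loss of the site by mutation |

Processing order: (1) per-primer-combination replicate mismatch rate, pooled
over both enzymes (the mean over combinations is the study-wide scoring
error); (2) size filtering (default 150–600 bp; short fragments suffer size
homoplasy) and singleton removal (a locus present in, or absent from,
exactly one sample — both directions, configurable); (3) pattern
classification; (4) methylation-susceptibility: a locus is
methylation-susceptible iff its fraction of discordant samples (I, H or A)
strictly exceeds the per-combination threshold

    tau = 2 e (1 - e),

the probability that two independent Bernoulli(e)-flipped scorings of one
band disagree, with e the combination's replicate error rate.  The cited
scoring convention describes the threshold only verbally ("the expected
per-individual probability of obtaining a mismatch ... owing to technical
and/or scoring errors"); 2e(1−e) is that probability under independent
flips, and it is exposed as a config override.  A one-sided binomial test of
the discordance count against tau is available as an alternative
(`test="binomial"`); strict exceedance is the default.  (5) binarization:
U→0, I/H→1; the ambiguous pattern A counts toward susceptibility evidence
but becomes **missing** under `missing_on_double_absence` (diversity
analyses, which must not mistake somatic mutation for methylation) and **0**
under `absence_as_unmethylated` (association tests, which need complete
data).  A locus is polymorphic iff both states occur among its non-missing
entries; loci with any missing value are dropped before the diversity
statistics.

## Diversity and structure

* **Shannon index** per epilocus: I = −[p ln p + (1−p) ln(1−p)] with p the
  frequency of the methylated state among non-missing entries; summarised
  as mean ± SD over loci.
* **Shared epigenotypes**: two samples match iff at every locus they are
  equal or at least one is missing.  The relation is not transitive, so
  groups are grown greedily in sample order (a sample joins the first group
  all of whose members it matches); the order dependence is documented
  behaviour.
* **Distances**: squared Euclidean distance over pair-complete loci,
  rescaled by L / L_complete(pair) so pairs with different missingness are
  comparable (for binary data the squared Euclidean distance is the
  mismatch count).  Geographic distances are haversine great-circle
  distances with Earth radius 6371.0088 km.
* **PCoA**: Gower double-centering of −D²/2, eigendecomposition, axes
  scaled by the square root of the positive eigenvalues; each axis's sign
  is fixed by making its largest-magnitude loading positive, so output is
  deterministic across linear-algebra backends.
* **AMOVA**: one-level (among/within countries).  SS_total is the sum of
  all pairwise squared distances over N; SS_within sums within-group pair
  terms over n_g; σ²_within = SS_within/df_within, and σ²_among uses the
  standard unequal-size coefficient n₀ = (N − Σn_g²/N)/(G−1).
  Φ_ST = σ²_among/(σ²_among+σ²_within).  Groups smaller than 2 are dropped.
  Significance permutes individuals among groups.
* **Mantel test**: Pearson correlation of lower-triangle entries;
  one-tailed permutation of rows+columns of the second matrix.  Both r and
  r² are reported; the permutation test is on r.
* All permutation p-values use (count + 1)/(n_perm + 1) — the
  "p(rand ≥ data)" convention, never zero and never below 1/(n_perm+1).
  Default 999 permutations.

## Bud-set phenology model

Bud set is scored on the 7-level ordinal scale 3 (growing apical meristem)
→ 0 (fully developed bud) in 0.5 steps, weekly, on every cutting ("ramet").
The model is a cumulative link (proportional-odds, logit) mixed model with
the categories ordered 3 → 0, so "the first j categories" means the least
advanced phenophases:

    logit P(score among first j) = alpha_j − beta_D·day − beta_S(site)
                                   − beta_CN·CN − u_tree − u_ramet

with day of year raw (not centred) in the model definition, home site as a
fixed categorical effect (reference = alphabetically first site), the
carbon:nitrogen ratio CN as a physiological covariate (cutting weight is
deliberately excluded: it correlates with CN at r ≈ −0.5, and only CN
enters), and independent Gaussian random intercepts for donor tree
(σ_T) and for ramet nested in donor (σ_R), the latter absorbing the
repeated measures.  A warning is issued when a site has a single donor
(site effect then confounded with the donor intercept).

**Estimation.**  The marginal likelihood integrates both random-effect
levels by a Laplace approximation that exploits the nested structure: per
donor the penalized-likelihood Hessian over (u_tree, u_ramets) is an
arrowhead matrix, so the joint mode (damped Newton; the ordinal-logit
log-likelihood is concave in the linear predictor, making the inner problem
globally concave) and the log-determinant (Schur complement) cost O(data).
The outer optimizer is L-BFGS-B on (alpha_1, log threshold increments,
betas, log sigmas) with central-difference gradients (step 1e-4 — at
log-likelihood magnitudes of 1e3–1e4 a smaller step leaves the optimizer at
its noise floor); convergence at gradient max-norm 1e-4; starting values
from a fixed-effects proportional-odds fit.  Internally the fixed-effect
columns are centred for conditioning and the thresholds shifted back to the
raw scale on reporting; this is invisible in the results.  Score levels
unobserved in the data are collapsed with a warning.

`fit(method="agq")` additionally polishes the optimum under an adaptive
Gauss–Hermite likelihood (nodes centred on the Laplace modes and scaled by
the arrowhead curvature; the ramet-level centres track the donor node
through the cross-derivative; default 7 nodes per level).  Laplace leaves a
small (~2%) downward bias on σ_ramet when each ramet contributes only a
few observations; the quadrature polish removes it at roughly 3–4× the cost
of the Laplace fit.  `loglike_quadrature` (dense nested Gauss–Hermite) is a
slow reference used in validation only.

Standard errors (optional, `se=True`) come from the numerical Hessian of
the approximate marginal log-likelihood; sigma SEs by the delta method on
the log scale.  No inference is offered on variance components beyond this.

**D50%.**  Per donor, the day of year at which the probability of having at
most reached score 1.5 (i.e. being in {3, 2.5, 2, 1.5}) is 50%,

    D50 = (alpha_(1.5) − beta_CN·CN_ref − beta_S(site) − u_tree) / beta_D,

with CN_ref = 12 and alpha_(1.5) the threshold below score level 1.5 (the
threshold index is resolved from the observed levels; it is an
interpretation that the cumulative set for "maximally 1.5" ends at that
boundary).  D50 values are correlated (Pearson, two-sided t test) with
home-site January and July temperature and potential evapotranspiration.

## Association tests and FDR

Per polymorphic epilocus (absence-as-unmethylated coding), simple
binomial-logit regressions of the state on one climate covariate at a time
(January/March/July temperature, precipitation, frost days, PET, topsoil
C:N).  Complete separation (|slope| > 15 on a standardized covariate, or
non-convergence) flags the test non-estimable and removes it from the FDR
family.  Welch's unequal-variance t test compares per-donor D50% between
methylation states, after discarding loci methylated in only one donor or
in all but one; the test is applied at donor level because D50% is a
per-donor statistic.  Benjamini–Hochberg step-up control at q = 0.05 is
applied to all estimable tests of an analysis pooled (the conservative
reading; a per-covariate family is available).

## Synthetic-study generator

The generator emulates the study design so that every stage is testable
without external data: ~20 home sites × 3 donor trees, seven primer
combinations × 31 loci, 14 replicated samples, 12 ramets per donor scored
on 6 weekly late-summer dates (day of year 222–257).

* **Climate**: one latent "winter harshness" factor per site with loading
  0.97 on January temperature, March temperature, frost days (negative) and
  PET, plus independent noise — the simplest structure giving the strong
  pairwise correlations (r² > 0.8) seen among these variables; July
  temperature, precipitation and topsoil C:N are independent.  Values are
  clipped to the observed geographic/climatic ranges.  Latitude decreases
  with winter mildness; neighbouring sites by latitude share a "country"
  (~2 sites each), the AMOVA grouping.
* **Methylation**: per-locus baseline frequency Beta(0.15, 0.25) scaled to
  `meth_freq_range` — U-shaped, so roughly half the panel exceeds the
  technical threshold and about a quarter of the susceptible loci is
  monomorphically methylated, matching real MS-AFLP panel proportions.
  Latent states (with `double_absence_rate` = 0.003 somatic double absence,
  chosen so ~1/6 of susceptible loci carry missing values) map
  deterministically to dual-enzyme bands; every band is flipped
  independently with the combination's rate e.  The default e values derive
  from observed per-combination scoring error rates m via e = (1−√(1−2m))/2,
  so the measured replicate mismatch rate 2e(1−e) reproduces m in
  expectation.  `climate_effect` (default 0.3 logit/°C of January
  temperature) induces modest among-country differentiation (Φ_ST ≈ 0.05)
  while single-locus climate associations rarely survive FDR — the pattern
  reported for the real collection; a uniform per-locus effect cannot make
  the aggregate structure larger without flooding the per-locus tests.
* **Double absence** arises both as a latent state (mutation) and as the
  (0,0) image of band-level noise, since both causes produce it in real
  profiles.
* **SSR**: one clone MLG over 11 loci, a configurable number of one-repeat
  somatic variants and of distinct genotypes sharing one allele per locus,
  and replicated samples whose per-locus call is discordant with
  probability `ssr_error_rate` (so the recovered study-wide error rate
  equals it in expectation).
* **Bud set**: drawn exactly from the cumulative-logit model above, with
  default thresholds placed so phenophase transitions sweep the observation
  window, beta_day = 0.15/day, beta_CN = 0.1, σ_T = 0.8, σ_R = 0.5; the
  site effect is linear in centred January temperature
  (−0.15 logit/°C, making warm-origin ramets set bud later with a
  D50–January-temperature correlation around 0.3–0.5); donor C:N and ramet
  weight are jointly Gaussian at correlation −0.504.

All randomness flows from one integer seed; per-table substreams are
spawned with `numpy.random.SeedSequence`, so adding draws to one generator
does not perturb the others, and equal seeds give bit-identical tables.

**What the generator does not emulate**: electropherogram traces, peak
intensities, fragment-size binning and homoplasy (scoring starts from
binary presence/absence), spatial autocorrelation beyond the single latent
climate factor, locus-specific climate responsiveness, and missing
observations in the phenology series.  Passing tests therefore validate the
statistical machinery under the stated generative assumptions, not the
wet-lab scoring chain.

## Numerical and design choices

* Thresholds are kept increasing via a log-increment parameterization;
  sigmas via log with bounds [e⁻¹⁰, e³] — at the lower bound the model is
  numerically indistinguishable from one without that random effect, which
  is how a zero variance component is represented.
* Probability floor 1e-300 inside logs; if no damped-Newton step improves
  the inner objective (floating-point limit), the current iterate is
  accepted.
* Degenerate inputs raise: non-increasing thresholds, probabilities outside
  [0,1], distance pairs with no complete loci, fewer than two eligible
  AMOVA groups, zero-variance correlation inputs, β_D = 0 in D50.
* Problem sizes in the validation suite: 50 CLMM recovery replicates at
  60 donors × 12 ramets × 6 days; 400 null datasets for the AMOVA and
  Mantel calibrations (99 permutations each); 200 replicates for the
  BH-FDR and logistic-slope recovery checks; dense-quadrature comparisons
  on a 3-donor instance.

## Known limitations

* The Laplace approximation's error grows with the random-effect SDs and
  shrinks with the information per group; on very small instances it can
  reach ~0.1 log-likelihood units — use `method="agq"` when variance
  components matter.
* The greedy epigenotype matching depends on sample order (inherent to the
  non-transitive missing-tolerant relation).
* Maximum-likelihood variance estimates carry the usual small-sample
  downward bias (no REML analogue is implemented for this model class).
* The per-epilocus regressions are simple (one covariate); the strong
  collinearity among winter variables means their single-covariate results
  are not independent.
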