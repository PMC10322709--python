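# Methods

## The problem

Case-control sequencing studies (16S amplicon or shotgun metagenomic
profiling of matched cohorts, for example) yield per-sample counts that
are compositional: sequencing depth is an instrument artifact, so only
relative abundances carry information, and any shift in total microbial
load appears as an unidentifiable constant added to every feature's log
fold change. Cross-study comparisons are further confounded by age, sex,
household and protocol ("batch") effects. `matchrank` implements a
matched-pair Bayesian differential ranking workflow that addresses these
problems jointly: cases are paired to demographically similar controls
within each cohort, per-pair baselines absorb pair-level structure, and
all downstream statistics are invariant to the unidentifiable
compositional offset.

## The model

For feature (taxon) j and sample i with raw sequencing depth
N_i, pair index k(i), cohort b(i) and disease group p(i):

    y_ij ~ NegativeBinomial(lambda_ij, alpha_ij)         Var = lambda + alpha * lambda^2
    log lambda_ij = log N_i + C_{k(i),j} + D_j * I[i = case]
    alpha_ij = a0_{b(i),j} / lambda_ij + a1_{b(i),j} + beta_{p(i),j}

The depth offset log N_i makes the model self-normalizing (no
rarefaction needed); C_{k(i),j} is a free per-pair baseline log
proportion, so each case is compared only with its own matched control;
D_j is the natural-log fold change of interest. The dispersion is a
DESeq2-style trend — variance lambda + a0*lambda + a1*lambda^2 — with a
per-disease-group shift beta_p. Priors:

    a0 ~ LogNormal(0, 1)          a1 ~ LogNormal(log 10, 0.1)
    beta_p ~ Normal(beta_mu, beta_sigma)
    beta_mu ~ Normal(0, 3)        beta_sigma ~ LogNormal(log 0.1, 0.1)
    C_kj ~ Normal(C_mu_j, C_sigma_j)
    C_mu_j ~ Normal(1/d, 3)       C_sigma_j ~ Normal(1/d, 1), truncated > 0
    D_j ~ Normal(0, 3)

Notes on the priors as implemented:

* `C_mu_j ~ Normal(1/d, 3)` centers a log proportion at 1/d where
  log(1/d) would be the natural choice; we keep the stated form (at
  scale 3 the center is immaterial) and flag it here.
* `C_sigma_j` has a normal prior yet is a scale; we truncate it at zero
  from below.
* `alpha` can go nonpositive through beta_p; we floor it at
  `alpha = max(alpha, 1e-6)` (the `alpha_floor` estimator parameter).
* The dispersion subscripts are read as cohort/batch indices (one a0/a1
  per cohort per feature) and beta carries one value per disease group —
  dispersion is estimated per feature, per batch, and per group. beta_mu
  and beta_sigma are per-feature hyperparameters inside each independent
  per-feature fit, which preserves the property that features can be
  fitted independently.

Because features are conditionally independent, the full fit is a batch
of per-feature posteriors sampled jointly. The group-averaged comparator
(`GroupAveragedDifferentialModel`) replaces the per-pair baselines with
a single shared baseline per feature — the standard unmatched
differential-ranking analysis — and is used as the contrast in the
confounding benchmarks.

## Posterior computation

No external MCMC framework is used; the package ships a batched sampler
(`matchrank._hmc`) tailored to this posterior family:

* **Adaptive HMC with a dense metric.** All features x chains advance in
  one vectorized process with analytic gradients. Warmup estimates a
  diagonal then a dense (full-covariance) mass matrix per chain; dual
  averaging tunes step sizes toward 0.9 acceptance.
* **Delayed rejection.** A rejected trajectory is retried at one fifth
  of the step size with the Green-Mira correction, so locally stiff
  curvature does not throttle the bulk step size.
* **Slice-within-Gibbs for the dispersion block.** The dispersion-level
  coordinates (a0, a1, the group dispersion levels phi_p = mean(a1) +
  beta_p, beta_mu, log beta_sigma) are excluded from the Hamiltonian and
  updated by univariate stepping-out slice sampling. Two reasons: the
  `max(alpha, eps)` floor kinks their conditionals exactly where
  posterior mass can sit, and the tight `a1` prior with the free
  `beta_mu` forms a stiff curved valley; both defeat gradient-based
  steps but are trivial for slice updates. phi_p is the
  likelihood-identified reparameterization of the group dispersion
  level (unit Jacobian), which decouples the data-informed coordinate
  from the prior-only ridge. In addition to the univariate updates, a
  composite slice move shifts (phi_control, phi_case, beta_mu) by a
  common offset: the tight beta prior tethers the three together, so
  for sparse features (weak dispersion likelihood) this diagonal is the
  soft direction that coordinate-wise updates would otherwise
  random-walk along.
* **Non-centered pair baselines.** C_kj = C_mu_j + C_sigma_j * eta_kj
  with eta ~ N(0,1), which removes the hierarchical funnel that
  otherwise traps chains when between-pair variation is small.
* **Pseudo-mode restarts.** Hierarchical overdispersed models admit a
  metastable "collapsed baseline + inflated dispersion" basin. During
  warmup, a chain whose running mean log density trails its feature's
  best chain by more than 15 nats (relative mass < e^-15) restarts from
  the best chain's position.
* **Robustness guards.** Per-coordinate variances of the dense metric
  are capped against the diagonal-phase estimate (a warmup window
  polluted by a basin jump would otherwise corrupt the metric); final
  step sizes are capped at 0.8 in whitened units; 15% of iterations run
  at one tenth of the step (a state-independent mixture, hence valid
  MCMC) so no chain can stay wedged against stiff curvature.

Split-chain rank-normalized Rhat and bulk ESS are computed with ArviZ
and reported per feature; fits with Rhat > 1.1 are flagged, not fatal.
Defaults are 4 chains x 1000 warmup x 1000 draws. Given a seed, fits are
bit-reproducible.

## Downstream statistics

* **Ranking** orders features by posterior mean D (descending, ties by
  feature id). Because the compositional offset K shifts all D_j
  equally, the ranking is invariant to it.
* **Classification** labels a feature case-associated when >= 70% of its
  posterior draws are positive, control-associated when >= 70% are
  negative, neutral otherwise (boundary inclusive; exact zeros count to
  neither side). Cross-study **consensus** requires the same label in at
  least two studies; a feature qualifying for both sides is set neutral
  and flagged.
* **Balances**: per sample, ln geometric mean of the case-associated set
  minus ln geometric mean of the control-associated set, on zero-adjusted
  relative abundances (default: pseudocount 0.5 on zero cells only;
  mean-imputation mode available). Case-minus-control differences per
  pair and the fraction of pairs above zero summarize separation.
* **Significance calls**: increased if the 5% posterior quantile is
  above 0, decreased if the 95% quantile is below 0, stable if the
  central 90% interval covers 0 and the posterior sd is below 3
  (natural-log scale), otherwise uncertain.
* **Effect size**: E = ||mu_D||_2 / r_D where r_D is the largest
  distance of any posterior draw from the posterior mean. E > 1 means
  the origin lies outside the sphere enclosing all m draws, reported
  with the Bayesian bound P <= 1/m (P = 1 when the origin is inside; E
  is flagged infinite when all draws coincide).
* **Robust CLR heat-map values**: per sample, zeros are imputed to the
  feature's mean relative abundance across all samples, the centered
  log-ratio transform is applied, and case-minus-control differences are
  taken per pair (rows sum to zero exactly).
* **Longitudinal recentering**: timepoint pairs of one subject replace
  case-control pairs (the later timepoint plays the case role). A
  reference set R — features with negative cross-sectional posterior
  mean — anchors all intervals: D* = D - mean_R(D), applied draw-wise so
  recentered credible intervals stay coherent. Responses are classified
  as above after an sd < 3 low-uncertainty filter.

## The synthetic-cohort generator

`SyntheticConfig` / `generate_matched_cohort` emulate a matched 16S
cohort: feature baseline log-compositions ~ Normal(0, 2.0) (heavy-tailed
rank-abundance), per-pair subject variation ~ Normal(0, 1.0), lognormal
depths (mean 20,000, log-sd 0.5), gamma-Poisson counts with the same
DESeq2-style trend the model assumes (defaults a0 = 1.0, a1 = 1.0,
beta = 0, i.e. variance = lambda + lambda + lambda^2 at scale — within
the range 16S practitioners report and consistent in order of magnitude
with the model's own dispersion prior), and true log fold changes
~ Normal(0, 1) added to case compositions before per-sample
renormalization. That renormalization reproduces compositionality: the
fitted differentials recover the truth only up to a shared additive
offset, which `evaluate_recovery` removes before scoring (raw-scale MSE
is also reported, and interval coverage is assessed against the
offset-aligned truth).

Confounders are explicit dials:

* `age_effect_sd`: per-feature age slopes (per year, log scale) applied
  to mean-centered ages;
* `age_gap_mode="sibling-like"`: within-pair age gaps drawn as in
  sibling-control designs — 60% of gaps are 2-5 years, with the
  unaffected sibling older 80% of the time (families typically enroll an
  available older sibling), the rest within +-1 year; sibling pairs
  share a household id, matched pairs do not;
* `household_sd`: shared per-(household, feature) offsets;
* `apply_depth_confounder`: binomial thinning / multinomial top-up of
  case samples to shift their expected depth;
* `apply_protocol_bias`: per-feature multiplicative bias applied
  compositionally by multinomial re-draw at the original depth.

What the generator does **not** emulate: real taxon-taxon correlation
structure, phylogenetic signal, time-varying effects within a
cross-sectional draw, or zero-inflation beyond what the NB + composition
produces. Passing benchmarks therefore demonstrate correctness of the
machinery and the value of matching under the stated confounders — not
performance guarantees on any particular real cohort.

## Benchmark configurations and what they showed

Problem sizes were chosen so each benchmark runs in minutes on one CPU:

* **Convergence / recovery**: 30 pairs x 50 features, default MCMC; max
  Rhat over D stays near 1.01, min bulk ESS in the several hundreds, and
  posterior means track the truth at r ≈ 0.91.
* **Interval calibration**: 30 pairs x 200 features; central 90%
  intervals cover the offset-aligned truth for ~92% of features.
* **Invariances**: depth x10 rescaling and strong per-feature protocol
  bias (log-normal sd 1) shift each feature's posterior mean by well
  under 2 combined posterior sd, and depth rescaling preserves the
  ranking (Spearman rho > 0.99).
* **Matching benchmark**: a sibling-like cohort (50 pairs, age slopes
  sd 1.0/yr, household sd 0.5). Re-matching by age (gap <= 0.5 y) and
  fitting the matched model yields an order-of-magnitude lower MSE than
  the group-averaged fit on the same data — the qualitative pattern of
  matched designs dominating under age confounding.
* **Longitudinal**: 18 subjects x 40 features, 12 of 20 focal features
  declining by ln 2 between two timepoints, within-subject dispersion
  a1 = 0.25 (repeated measures of one subject are less variable than
  cross-subject contrasts); the recentered analysis recovers the decline
  direction for >= 90% of declining features and the significant-decrease
  fraction lands within 10 points of the simulated 60%.

### A known honest failure: null classification rates

With D_true = 0 everywhere, the 70%-posterior-mass rule labels roughly
half of the features non-neutral, not <= 10%. This is a property of the
rule, not a bug: for an approximately calibrated posterior the fraction
of posterior mass above zero is uniformly distributed under the null, so
the rule flags ~60% of null features by construction (a threshold of
~0.95 would flag ~10%). The corresponding acceptance test is left
failing deliberately rather than weakening the generator or the rule;
the rule is useful for *ranking and grouping*, not as a type-I-error
controlled test — consistent with the framework's premise that
per-feature significance testing is not the goal.

## Numerical choices and degenerate inputs

* alpha floor 1e-6; log lambda clipped to +-30 inside the likelihood.
* All-zero features are skipped with a warning (mean-imputation and
  model fitting are undefined for them); all-zero samples are an error.
* Rarefaction drops samples below the requested depth (reported), keeps
  exact totals via multivariate hypergeometric draws.
* Matching breaks cost ties by lexicographic sample id; infeasible edges
  receive a prohibitive cost so cardinality dominates total age gap.
* ESS is capped at the number of stored draws; Rhat is validated against
  its finite-sample floor sqrt((n-1)/n).
* Effect size with r_D = 0: reported as +inf with a degenerate flag
  rather than an error.
* Randomness: every public entry point takes a single integer seed;
  internal seeds derive from `numpy.random.default_rng(seed)`.

## Limitations

* The per-feature independence assumption ignores taxon covariation;
  joint shrinkage across features is out of scope.
* The unidentifiable offset K means absolute fold changes are never
  recovered — only rankings, balances and within-frame contrasts.
* No zero-inflation component; heavy structural zeros in real data may
  inflate dispersion estimates instead.
* The sampler is tuned for this posterior family; it is not a
  general-purpose replacement for Stan-style NUTS.
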