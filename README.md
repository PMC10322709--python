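# matchrank

Matched-pair Bayesian differential ranking for case-control omics count
data.

Sequencing-based profiling (16S amplicon, shotgun metagenomics and
similar) yields compositional counts: depth is an artifact, total load
is unobserved, and cohort effects (age, sex, household, protocol)
confound naive case/control contrasts. `matchrank` is a toolkit for
analysts running matched case-control or longitudinal intervention
studies on such data. It provides:

* **Optimal matching** — within-cohort bipartite pairing of cases to
  controls on age and sex (maximum pairs first, minimum total age gap
  second), and timepoint pairing for longitudinal designs.
* **A matched negative-binomial model** — per feature j and sample i,

  ```
  y_ij ~ NB(lambda_ij, alpha_ij)            Var = lambda + alpha lambda^2
  log lambda_ij = log N_i + C_{k(i),j} + D_j I[i = case]
  alpha_ij = a0_b/lambda_ij + a1_b + beta_p
  ```

  with a free baseline C per pair k(i), so each case is contrasted only
  against its own matched control; D_j is the natural-log fold change,
  identified up to a shared compositional offset. Fitted by a built-in
  batched MCMC sampler (adaptive dense-metric HMC with delayed rejection
  and slice-sampled dispersion coordinates), with split-chain Rhat and
  bulk ESS reported per feature. Exposed as scikit-learn-style
  estimators (`MatchedDifferentialModel`, `GroupAveragedDifferentialModel`).
* **Posterior ranking statistics** — three-group taxon classification
  (>= 70% of posterior draws on one side of zero), cross-study consensus,
  per-sample log-ratio balances and per-pair balance differences,
  significance/stability calls, robust-CLR per-pair heat-map values, and
  the posterior-sphere effect size E = ||mu_D||/r_D with its Bayesian
  P bound.
* **Longitudinal (FMT-style) analysis** — timepoint differentials
  recentered draw-wise to a stable reference set (D* = D - mean_R D).
* **A synthetic-cohort generator** — matched or sibling-like cohorts
  with known log fold changes, overdispersed counts, depth variation,
  and switchable age/household/depth/protocol confounders, plus recovery
  scoring (offset-corrected MSE, correlation, interval coverage).

The scientific model and its evaluation are described in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from matchrank import (SyntheticConfig, generate_matched_cohort,
                       match_case_control, build_model_input,
                       fit_matched_model, classify_features,
                       effect_size_and_p, evaluate_recovery)

cfg = SyntheticConfig(n_pairs=30, d=50, seed=42)
table, metadata, truth = generate_matched_cohort(cfg)

pairs = match_case_control(metadata, max_age_gap=0.5)
print(f"pairs: {len(pairs)}  unmatched: {len(pairs.unmatched)}")

post = fit_matched_model(build_model_input(table, pairs, metadata),
                         {"chains": 4, "warmup": 1000, "draws": 1000, "seed": 7})
print(f"max Rhat {post.summary['rhat'].max():.3f}  "
      f"min ESS {post.summary['ess'].min():.0f}")

labels = classify_features(post, threshold=0.70)
print(labels.value_counts().to_dict())

effect = effect_size_and_p(post.draws)
print(f"effect size E = {effect.effect_size:.2f}  P <= {effect.p_bound:.2e}")

print({k: round(v, 3) for k, v in evaluate_recovery(post, truth).items()})
```

prints

```
pairs: 30  unmatched: 0
max Rhat 1.005  min ESS 1108
{'control-associated': 26, 'case-associated': 14, 'neutral': 10}
effect size E = 1.48  P <= 2.50e-04
{'mse': 0.1, 'mse_raw': 0.247, 'pearson_r': 0.91, 'coverage90': 0.96, 'offset': -0.383, 'n_features': 50}
```

Reading it: all 30 simulated cases found a same-sex control within six
months of age; the MCMC diagnostics clear the usual Rhat < 1.1 /
ESS > 300 bar; 40 of 50 features earn a non-neutral label under the 70%
posterior rule (the cohort was simulated with real effects, sd 1);
the joint posterior sphere excludes the origin (E > 1), so the global
case-control difference is credible at P <= 1/m; and the posterior mean
log fold changes track the simulated truth at r = 0.91 after removing
the unidentifiable compositional offset (the `offset` entry; `mse_raw`
keeps it).

The same pipeline is scriptable from the shell:

```bash
matchrank simulate --seed 3 --out-prefix sim
matchrank match --metadata sim_metadata.tsv --out pairs.tsv
matchrank fit --table sim_table.tsv --pairs pairs.tsv \
              --metadata sim_metadata.tsv --seed 7 --out differentials.tsv
matchrank run --config pipeline.yaml --out-dir results/   # all stages + manifest
```

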