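# temporal-beta

Temporal β diversity of ecological communities: observed among-year
dissimilarity, a marginal-preserving null model with a standardized
departure statistic, and AICc multimodel inference that contrasts the
drivers of observed versus null-corrected community variability.

## The problem

Long-term monitoring of a site yields a years × taxa abundance matrix.  How
much does community composition change from year to year, and is that
change driven by deterministic environmental filters (which act on species
identities) or by stochastic processes — random recruitment, chance
colonization, sampling effects — that produce patterns indistinguishable
from chance?  The two are confounded in raw dissimilarities: a site can
look variable simply because its yearly richness fluctuates.

This package implements the standard analysis for that question, developed
for multi-year stream macroinvertebrate surveys but applicable to any
site × year × taxon count data:

1. **Observed temporal β diversity.**  For each site, Bray–Curtis
   dissimilarity `BC(x, y) = Σ|xᵢ − yᵢ| / Σ(xᵢ + yᵢ)` on log(x + 1)-
   transformed counts over all consecutive year pairs; the mean is β_obs.
2. **Null expectation.**  A quantitative null model randomizes each site's
   matrix while preserving per-year richness (α), per-taxon occurrence
   frequencies, site taxon total (γ) and per-year abundance totals.  The
   binary structure is shuffled with the curveball trade algorithm (uniform
   over the fixed-marginals ensemble at stationarity); abundances are then
   reallocated over the shuffled presences (each present taxon gets ≥ 1
   individual, the surplus multinomially).  Repeating this 1000 times gives
   the chance expectation β_exp and its SD.
3. **Departure.**  `β_dep = (β_obs − β_exp) / SD β_exp` is a standardized
   effect size; β_dep < −2 reads as "more stable than expected by chance".
4. **Driver contrast.**  All 2⁶ = 64 subsets of six site covariates (bed
   movement intensity, bryophyte cover, substrate Simpson 1/D, water
   temperature, riffle connectivity, γ) are fit by OLS on z-scored data and
   ranked by AICc; Akaike weights are summed per variable into importance
   values (threshold 0.80).  Running the selection twice — response β_obs,
   then β_dep — separates stochastic drivers (importance collapses under
   the null-corrected response) from deterministic ones (importance
   persists).

A synthetic-data generator produces study-shaped datasets (23 sites ×
14 years, 129-taxon pool, skewed abundances) in which one covariate acts
through an identity-dependent stabilizing channel and another through an
identity-free recruitment channel, so the whole contrast is testable end to
end without field data.  Environmental index builders (stone-movement
disturbance, substrate diversity, cover, temperature, riffle area,
rank-consistency diagnostics) cover the raw-field-table path.

## Worked example

```python
import temporal_beta as tb

cfg = tb.SyntheticConfig(seed=42, n_sites=23)
dataset = tb.generate_dataset(cfg)
result = tb.run_study(dataset, n_iter=1000, seed=42)

bt = result.beta_table
print(bt[["site", "beta_obs", "beta_exp_mean", "beta_exp_sd", "beta_dep", "stability"]]
      .head(5).to_string(index=False))
print("sites more stable than chance:", (bt["beta_dep"] < -2).sum(), "of", len(bt))
print(result.selection_obs.importance.round(2).to_string())
print(result.selection_dep.importance.round(2).to_string())
```

prints

```
site  beta_obs  beta_exp_mean  beta_exp_sd  beta_dep               stability
 S01  0.684884       0.728238     0.018149 -2.388760 more_stable_than_chance
 S02  0.560381       0.607345     0.016207 -2.897743 more_stable_than_chance
 S03  0.493018       0.536434     0.014141 -3.070243 more_stable_than_chance
 S04  0.424784       0.503494     0.013405 -5.871892 more_stable_than_chance
 S05  0.544369       0.596661     0.015475 -3.379117 more_stable_than_chance

sites more stable than chance: 17 of 23

importance (response = beta_obs):        importance (response = beta_dep):
bmi             0.19                     bmi             0.24
bryophytes      1.00                     bryophytes      1.00
simpson         0.15                     simpson         0.17
temperature     0.18                     temperature     0.53
connectivity    0.97                     connectivity    0.24
gamma           0.29                     gamma           0.17
```

Most sites are more stable than chance (negative β_dep).  Connectivity is
an important driver of the observed dissimilarity (importance 0.97) but is
demoted once stochastic variation is controlled for (0.24 under β_dep): it
acted through an identity-free channel.  Bryophyte cover stays at 1.00 for
both responses — a deterministic stabilizer.

The same pipeline runs from the shell:

```bash
temporal-beta simulate --config sim.yaml --out-dir synth/
temporal-beta run --community synth/community_long.tsv \
    --env synth/environment.tsv --iters 1000 --seed 42 --out-dir results/
```

writing `beta_by_site.tsv`, `model_selection_obs.tsv`,
`model_selection_dep.tsv`, `importance.tsv` and a JSON run manifest.

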