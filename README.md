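# leafagree

Observer-variability analysis for integer count phenotypes, built around the
canonical example of counting rosette leaves in top-view images of
*Arabidopsis thaliana*.

Image-based phenotyping treats human annotations as gold standard, yet
experienced (ExP) and non-experienced (NExP) observers — and crowdsourcing
volunteers — disagree, especially on young, barely emerged leaves and at low
image resolution. This package provides, for anyone designing or auditing a
counting-annotation campaign:

- a **synthetic cohort generator** emulating a two-cultivar longitudinal
  study (wild type vs a slower-growing starch mutant; 5 replicates; 13 time
  points at 48 h; two optical resolutions; transformed duplicate sets
  labelled A–D) with ground-truth leaf counts and per-leaf emergence times;
- an **observer model**: resolution-dependent young-leaf misses, spurious
  counts, tool vs spreadsheet counting modes, per-leaf dot timestamps, and a
  citizen pool with heavy-tailed user activity and self-reported confidence
  (Yes = 3 / Not sure = 2 / Missed leaves = 1);
- the **agreement suite** between a reference observer X_R and another
  source X_o, with d = X_R − X_o: DiC = (mean d, sd d), |DiC|,
  MSE = mean d², R² (squared Pearson correlation), and Krippendorff's
  alpha on a ratio scale, where δ²(c, k) = ((c − k)/(c + k))²;
- a **count-aware Bland–Altman** representation that merges coincident
  (pair mean, difference) points into multiplicity-weighted cells, with
  bias and 1.96·SD limits of agreement;
- the **longitudinal mixed-effects repeated-measures ANOVA**
  count ~ time × cultivar with plant-level random intercept and time slope
  (time continuous), whose time:cultivar interaction tests whether genotype
  growth trends differ;
- the **Monte-Carlo observer-subsampling study**: binary sampling matrices
  with K annotations per plant-time row, per-row consensus averaging, and
  the distribution (min/max/mean/SD/kurtosis) of interaction p-values over
  500 trials per (pool, K);
- **citizen-consensus aggregation** (average / max / single random) and the
  confidence-vs-count-spread analysis.

## Worked example

```python
import pandas as pd
import leafagree as la

design = la.build_design()                                   # 130-image study grid
truth = la.simulate_growth(design, la.GrowthParams(), seed=42)

pool = la.default_observer_pool()                            # 5 ExP + 4 NExP
ann = pd.concat(
    [la.simulate_observer_counts(truth, design, p, seed=100 + 7*i)
     for i, p in enumerate(pool)],
    ignore_index=True,
)

paired = la.pair_counts(ann, ann,
                        selector_a={"observer_id": "ExP1"},
                        selector_b={"observer_id": "NExP1"})
rep = la.agreement_report(paired)
print(f"DiC {rep.dic_mean:.2f} ({rep.dic_sd:.2f})  |DiC| {rep.adic_mean:.2f}  "
      f"MSE {rep.mse:.3f}  R2 {rep.r2:.3f}  alpha {rep.alpha:.3f}")
print(f"within +/-1 leaf: {la.within_one_fraction(paired):.1%}")

table = la.build_count_table(ann, design, "mean_over_observers")
res = la.fit_interaction_anova(table)
print(res.terms.round(4).to_string(index=False))

summary = la.run_subsampling_study(ann, design,
                                   [p.observer_id for p in pool],
                                   K=1, n_trials=500, seed=7)
print(f"K=1 subsampling: min {summary.minimum:.2e}  max {summary.maximum:.2e}  "
      f"mean {summary.mean:.2e}  kurtosis {summary.kurtosis:.1f}")
```

prints

```
DiC 0.16 (0.71)  |DiC| 0.45  MSE 0.531  R2 0.954  alpha 0.907
within +/-1 leaf: 96.2%
         term  df_num  df_den    sum_sq  f_value  p_value
         time       1     8.0 1194.4980 586.3909   0.0000
     cultivar       1     8.0   73.5423  22.5129   0.0015
time:cultivar       1     8.0   31.1231  15.2786   0.0045
K=1 subsampling: min 3.18e-04  max 4.52e-02  mean 7.87e-03  kurtosis 8.2
```

Reading this: the expert and non-expert disagree by well under one leaf on
average (the positive DiC means the non-expert undercounts, consistent with
missed young leaves), agreement is chance-corrected excellent (alpha 0.91),
and the two observers land within ±1 leaf on 96% of images. Despite that
noise, the time:cultivar interaction is clearly significant (p ≈ 0.005) —
the two genotypes separate longitudinally — and it stays significant in
every one of 500 subsampling trials that keep only one randomly chosen
observer annotation per plant and time point (max p 0.045 < 0.05): a single
annotation per image, spread over a pool of mixed-experience observers,
preserves the phenotyping conclusion.

## Command-line pipeline

`leafagree --seed 123 --outdir out report` runs the full chain
(simulate → agreement → Bland–Altman → ANOVA → subsampling → citizen
consensus) and writes CSV/JSON tables plus a `manifest.json` with the
config hash, seed and library versions needed to reproduce the run
bit-for-bit. Individual stages are available as subcommands
(`simulate`, `agree`, `baplot`, `anova`, `subsample`, `consensus`); a TOML
file (`--config`) overrides any default.

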