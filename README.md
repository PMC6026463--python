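# isodiet

Triple stable-isotope (δ¹³C, δ¹⁵N, δ³⁴S) diet reconstruction for trophic
ecology: lipid normalization, trophic-enrichment-factor (TEF)
construction, Monte Carlo mixing-polygon validation of consumers, and
Bayesian Dirichlet mixing models with gut-content-derived priors — plus a
synthetic-data generator so the whole pipeline is testable end to end
without any external download.

## The problem

Benthivorous sea ducks are hard to observe feeding. Two complementary
windows exist on their diet: gut contents of bycaught birds (taxonomically
precise, but biased toward indigestible prey) and stable isotope ratios of
blood from live birds (integrates assimilated food, but needs a model to
invert). `isodiet` implements that inversion for three tracers and K prey
end-members. A consumer's tracer value is modelled as

    X_ij ~ Normal( Σ_k p_k (μ_jk + λ_jk),  Σ_k p_k² (ω_jk² + τ_jk²) + σ_j² )

where p is the diet-proportion simplex (Dirichlet prior, optionally
informed by gut-content proportions), μ_jk ± ω_jk the lipid-corrected
source statistics, λ_jk ± τ_jk the TEFs and σ_j a per-tracer residual SD.
Before fitting, each consumer must pass a mixing-polygon gate: the convex
hull of TEF-corrected sources is iterated under their uncertainties, and
consumers inside fewer than 5% of hulls in any pairwise tracer projection
(outside the "95% mixing region") are excluded.

The built-in `study_data` module carries the published summary statistics
of a Baltic Sea winter-diet study of the Velvet Scoter: five soft-bottom
macrozoobenthos end-members, gut contents of 66 bycaught birds, and blood
statistics of 8 live-caught scoters.

## Worked example

```python
from isodiet import (build_tef_set, gut_priors, MixingModelSpec, McmcConfig,
                     compare_prior_modes, validate_consumers, study_data)

groups = study_data.study_source_groups()          # 5 end-members, C corrected
tefs   = build_tef_set("model0", groups)           # diet-dependent carbon TEFs
birds  = study_data.emulate_consumers(7, seed=1)   # pseudo-individuals

gate = validate_consumers(birds, groups, tefs, seed=1)
print(gate.excluded_ids())   # outside the 95% mixing region

comp = study_data.study_diet_composition()
ww   = gut_priors(comp, study_data.DEFAULT_TAXON_MAPPING,
                  [g.group_id for g in groups], mode="ww")
spec = MixingModelSpec(groups=tuple(groups), tefs=tefs)
print(compare_prior_modes(birds, spec, {"none": None, "ww": ww},
                          McmcConfig(seed=1)).round(1).to_string(index=False))
```

prints

```
['scoter_07']
prior_mode        source_id  mean_pct  sd_pct  ci2_5_pct  ci97_5_pct   ess
      none          saduria      14.6    10.2        0.5        36.2 174.4
      none          crangon      14.3     9.8        0.8        35.7 238.8
      none mya_cerastoderma      54.3     8.4       38.0        71.4 285.8
      none           macoma       3.1     3.2        0.1        11.8 238.4
      none      polychaetes      13.7    10.7        1.0        39.3  76.5
        ww          saduria      33.4     9.9       10.4        46.3  76.8
        ww          crangon       2.4     5.8        0.0        22.5   3.3
        ww mya_cerastoderma      58.2     6.8       47.9        74.3 628.6
        ww           macoma       3.8     3.2        0.1        11.5 221.4
        ww      polychaetes       2.1     5.2        0.0        19.0  14.2
```

Read: under a flat prior, the pooled *Mya* + *Cerastoderma* bivalve group
contributes ~54% of the diet (95% CI 38–71%). Adding the wet-weight
gut-content prior pulls the isopod *Saduria* up (15 → 33%) and collapses
the shrimp and the polychaetes — which the guts barely or never contain —
to a few percent, exactly the qualitative behaviour reported for the
original analysis (published flat-prior bivalve mean: 52 ± 9%).

A command-line interface mirrors the library:

```sh
isodiet synth --seed 7 --out-dir data/          # synthetic dataset + manifest
isodiet validate --sources data/sources.csv --consumers data/consumers.csv \
        --model model0 --iters 1500 --threshold 0.05 --seed 42 --out gate.csv
isodiet run --config pipeline.yaml --seed 42 --out results/
```

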