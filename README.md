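# socsel — multilevel selection on social network phenotypes

`socsel` estimates how natural selection acts simultaneously on **individual
social behaviour** and on **group social structure** in wild populations
where both are measured from social networks.  It was built for
marmot-style field systems — annual cohorts of individually marked animals,
observed interactions and co-locations, binomial/Poisson fitness outcomes —
but every stage is generic.

The pipeline, from raw field records to selection gradients:

1. **Filtering** — keep affiliative interactions between known, resident
   (≥ 5 annual observations) adults and yearlings inside the spring season
   window, with a per-rule removal report.
2. **Social groups** — simple-ratio association indices from daily
   co-location records (`x / (x + y_a + y_b + y_ab)`), partitioned by
   minimizing the two-level map equation (the description length of a random
   walk on the association network).  Adult males additionally join every
   group holding an interaction partner; their own traits and fitness stay
   with their primary group.
3. **Network traits** — per group-year, a directed weighted interaction
   network and four analogous individual/group trait pairs: degree/density
   (connectivity), closeness/average path length (closeness),
   embeddedness/cut points (breakability), local clustering/transitivity
   (clustering).  Embeddedness is the exact structural-cohesion level: the
   largest k for which the individual sits in a k-vertex-connected subgroup.
4. **Standardization** — individual traits are mean–variance standardized
   within each group-year (ΔP_i); group traits and group size across all
   group-years (ΔP_g); the signs of average path length and cut points are
   flipped so every predictor reads "larger = more social".
5. **Contextual analysis** — generalized linear mixed models per age–sex
   cohort and fitness channel,

   ```
   w_jkl = β0 + β_{w,ΔPi} ΔP_ijkl + β_{w,ΔPg} ΔP_gjkl + (covariates) + e_jkl
   ```

   with random intercepts for individual and year, a VIF > 5 screen that
   removes collinear trait pairs as a unit, Benjamini–Hochberg FDR across
   models, and a mean gradient-magnitude summary per phenotypic level.
   β_{w,ΔPi} and β_{w,ΔPg} are the among-individual and among-group
   selection gradients, reported on the link scale.

A first-class synthetic-data generator produces populations with *known*
true gradients (including antagonistic selection between levels) so the
whole pipeline is testable without field data.

## Worked example

Simulate a population with antagonistic multilevel selection on the
closeness trait — individuals socially closer to their groupmates are
penalized (β_i = −0.5 on the logit scale of hibernation survival) while
groups with shorter internal social distances are favoured (β_g = +0.8) —
then recover both gradients from the raw records:

```python
from socsel import PipelineConfig, scenario, simulate_and_analyze

cfg = scenario("antagonistic_between", seed=1, n_years=19, groups_per_year=9)
pop, result = simulate_and_analyze(cfg, PipelineConfig(seed=1))

model = next(r for r in result.results
             if r.spec.name == "hibernation_survival:adult_F")
print(model.table.loc[["dPi_closeness", "dPg_avg_path_length"],
                      ["beta", "se", "p", "p_fdr"]])
```

```
                         beta        se             p         p_fdr
dPi_closeness       -0.696006  0.121422  9.916956e-09  5.950174e-08
dPg_avg_path_length  0.701185  0.172439  4.777012e-05  1.433104e-04
```

The adult-female hibernation model recovers the negative individual
gradient and the positive group gradient with the correct signs and
magnitudes near the simulated truth (−0.5 / +0.8; single-run estimates
carry sampling error of roughly ±0.2).  Pooling the four hibernation cohort
models by inverse variance gives −0.545 / +0.887 for this seed.  The same
machinery is available from the shell:

```bash
socsel simulate --scenario antagonistic_between --seed 42 --out data/
socsel analyze  --inputs data/ --seed 42 --out results/
socsel recover  --scenario antagonistic_between --replicates 200 --seed 1 --out rec/
```

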