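# scalesia-csm

Carbon sequestration modelling for restored *Scalesia pedunculata* stands in
Galapagos agroforestry.

*S. pedunculata*, the dominant endemic tree of the Santa Cruz and Floreana
highlands, has lost most of its range to farmland.  Restoration programmes
replant it into coffee farms with water-saving technologies (Groasis
Waterboxx, Cocoon, hydrogel and combinations) and monitor survival and
height quarterly.  This package turns that monitoring design into a tested
modelling pipeline for restoration scientists and carbon-accounting
practitioners:

1. **synthetic_cohort** — generates monitoring tables with the study's
   structure (426 plants, 10 sites, 2 islands, 6 treatment arms, quarterly
   censuses 2013–2023) so every downstream stage is testable without field
   data;
2. **survival_model** — fits the repeated-measures logistic mixed model
   `logit P(alive) = β₀ + β_treatment + β_age·age + b_plant + u_site`
   (Laplace or adaptive Gauss–Hermite maximum likelihood, Wald chi-square
   tests, survival curves with 1- and 4-year cut-offs);
3. **growth_allometry** — multi-stem DBH aggregation
   (`2·√Σrᵢ²`), the `DBH ~ age + height` estimator, and per-tree dry mass
   `0.01540·(DBH²)^1.609 + 0.01769·(DBH²)^0.779` (kg) at 48% carbon;
4. **stand_projection** — the carbon sequestration model proper:
   `density × survival(t) × tree_carbon(t) × noise(t)` for a 530 trees/ha
   stand over 10 years, with mean-one geometric Brownian noise (20% horizon
   SD) and replicate-based uncertainty bands;
5. **carbon_accounting** — scales per-hectare carbon to the 723 ha of
   Galapagos coffee and expresses it against the archipelago's 523×10³
   Mg CO2/year footprint.

## Worked example

```bash
scalesia-csm run-all --seed 1 --out demo
```

generates a cohort, fits both models, projects the stand and writes all
tables, figures and a manifest under `demo/`.  The printed summary includes
(seed 1):

```
"n_records": 6372,
"per_tree_carbon_kg_c": 47.0,
"stand_carbon_mg_c_per_ha": 21.846,
"stand_carbon_se": 0.1952,
"total_storage_mg_c": 15794.9,
"footprint_reduction_pct": -1.1074
```

— a 530 trees/ha stand accumulates ≈ 21.8 Mg C/ha in ten years (mean of 500
noise replicates, SE of the mean ≈ 0.20); replicated over every coffee farm
in Galapagos that is ≈ 15.8×10³ Mg of stored carbon, or a 1.1% dent in the
archipelago's decade-long CO2 footprint.  The fitted survival summary
(`demo/survival_summary.txt`) mirrors the field study's reporting: Wald
tests for treatment (5 df) and age (1 df), random-effect variances, then the
coefficient table.  The same stages are available individually
(`simulate`, `fit-survival`, `fit-dbh`, `project`, `compare`, `offset`) and
as library functions:

```python
from scalesia_csm import (CohortConfig, ProjectionConfig, SurvivalFixedEffects,
                          extract_dbh_subsample, fit_dbh_model, fit_survival_glmm,
                          per_tree_trajectory, project_stand, GrowthParams)
from scalesia_csm.synthetic_cohort import generate_cohort_frame

frame = generate_cohort_frame(CohortConfig(seed=1))
fit = fit_survival_glmm(frame)                      # logistic GLMM, Laplace ML
dbh = fit_dbh_model(extract_dbh_subsample(frame), records=frame)
tree = per_tree_trajectory(GrowthParams(), dbh)     # kg C per surviving tree
result = project_stand(ProjectionConfig(seed=2), fit.fixed, tree)
print(result.mean_carbon[-1])                       # Mg C/ha at year 10
```

See `docs/methods.md` for the model assumptions, the generator calibration,
and known limitations (aboveground biomass only, no density dependence or
climate covariates).

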