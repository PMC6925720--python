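# anaemia-gamm

Geoadditive logistic mixed models for childhood anaemia surveys, with
BLUP-based district performance ranking.

## The problem

Anaemia in children aged 6–59 months (altitude-adjusted haemoglobin below
11 g/dl) is strongly patterned in space: cluster-sampled household surveys
such as the DHS and MIS record child outcomes nested in households, survey
clusters with GPS coordinates, and administrative districts, across several
countries. Estimating covariate effects without accounting for that spatial
heterogeneity misattributes risk; and health planning happens at district
level, so the question "which districts are doing unusually well or badly,
after adjusting for what we can measure?" needs a model-based answer.

This package implements the full pipeline for that analysis:

* a **synthetic survey generator** producing child-level records with the
  complete hierarchical geography (country → district → cluster →
  household → child), realistic covariates, and outcomes simulated forward
  from a fully known model — so every estimation stage can be validated by
  recovery;
* **cohort tools**: altitude adjustment of haemoglobin (CDC correction),
  outcome classification, design encoding with fixed reference levels,
  univariate screening at the 10% level and likelihood-ratio exploration of
  two-way interactions;
* the **model**: for child *k* in household *j*, cluster *i*, district *h*,

  ```
  logit π_hijk = x'_hijk β + U_h + f_age(age_hijk) + f_spat(lon_i, lat_i)
  ```

  with linear fixed effects β, an i.i.d. district random intercept
  U_h ~ N(0, σ²_U), a P-spline smooth of age (cubic B-splines on 20 equal
  segments, second-order difference penalty), and a tensor-product P-spline
  surface over cluster coordinates penalized by squared differences to the
  four nearest neighbours on the coefficient grid. Smooths are
  reparameterized into mixed-model form (τ² = 1/λ) and the whole model is
  fitted by penalized iteratively weighted least squares (inner loop) with
  REML estimation of the variance components (outer loop, Schall's
  fixed-point updates on the working linear mixed model);
* **appraisal**: the fitted district effects are BLUPs — shrinkage
  predictors of each district's deviation on the log-odds scale.
  Standardized (BLUP / prediction SE by default) and ranked within country,
  they yield top-k "best" (lowest) and "worst" (highest) district league
  tables.

## Worked example

```python
from anaemia_gamm import synthetic_data as sd, gamm, appraisal
from anaemia_gamm.cohort import ModelSpec

ds = sd.generate_dataset(n_children=8000, seed=42)   # 40 districts, 160 clusters
fit = gamm.fit(ds, ModelSpec(spatial_segments=5))
print(fit.aor_table()[["term", "aor", "ci_low", "ci_high"]].head(4))
print("variance components:", {k: round(v, 4) for k, v in fit.theta.items()})

dmeta = ds.records.drop_duplicates("district_id")[["district_id", "country"]]
league = appraisal.appraise(fit, dmeta, k=3)
print(league[league["flag"] == "best"].head(3))
```

Output (adjusted odds ratios with 95% Wald intervals):

```
                 term      aor   ci_low  ci_high
       gender[female] 0.905324 0.823076 0.995791
 rdt_result[positive] 4.425993 3.931495 4.982688
       household_size 1.006654 0.980962 1.033019
     residence[rural] 0.715869 0.555327 0.922822
variance components: {'age_months': 0.0015, 'spatial': 0.4963, 'district': 0.0887}
country district_id      blup  standardized_blup  rank_within_country
  Kenya    KEN-D004 -0.450651          -2.583296                    1
  Kenya    KEN-D006 -0.282303          -1.659269                    2
  Kenya    KEN-D003 -0.239436          -1.408275                    3
```

Reading it: girls have about 10% lower adjusted odds of anaemia than boys; a
positive malaria test multiplies the odds by ~4.4; the estimated district
variance (0.089 here) quantifies residual between-district heterogeneity;
and KEN-D004 is this simulation's best-performing Kenyan district — its BLUP
of −0.45 means the district lowers a child's log-odds of anaemia by 0.45
relative to an average Kenyan district with the same covariates. The
generating truth used here sets the fixed effects to published
survey-scale odds ratios (e.g. malaria AOR 4.315) and σ²_U = 0.1516, so the
estimates can be compared with what was simulated.

A command-line interface mirrors the library:

```sh
anaemia-gamm simulate --out run/ --seed 1 --n-children 8000
anaemia-gamm fit --data run/dataset.csv --out run/
anaemia-gamm appraise --fit-json run/fit.json --data run/dataset.csv --k 3 --out run/league.csv
anaemia-gamm run-all --config config.yaml
```

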