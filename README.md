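# gcfpool

Analysis toolkit for **randomized factor-pool experiments** on multiple
global-change factors (GCFs) — soil stressors such as salinity, drought,
microplastic, pesticides, nitrogen deposition — acting simultaneously.

When k factors are drawn from a pool of 12, a full factorial is hopeless
(C(12,5) = 792 combinations at the 5-factor level alone). The randomized
factor-pool design instead samples a fixed number of distinct combinations per
number-of-factors level, and the analysis asks three questions about the joint
responses:

1. **What would no interaction look like?** Three null models predict the
   joint effect of a combination from its members' single-factor effect sizes
   ES_i, with CT the control-group response:

   * additive: `P = Σ ES_i`
   * multiplicative: `P = CT · Π(1 + ES_i/CT) − CT`
   * dominative: `P = ES_j` with `|ES_j| = max_i |ES_i|`

   Prediction *distributions* come from a K-draw bootstrap: resample control
   and single-factor groups, form per-iteration effect sizes `Z_i = t_i − c_i`,
   combine under the null rule, add back the control mean.

2. **Which treatments deviate, and which way?** A treatment whose observed
   mean falls outside the 95% CI of the prediction distribution carries a net
   interaction; its rescaled deviation `DN = (observed − mean)/sd` plus the
   response's direction (does it rise or fall under stress?) classifies the
   interaction as synergistic or antagonistic. Per response, the null model
   with the smallest sum of squared deviations (SSD) is the best-fitting one.

3. **Is it the number of factors, or their dissimilarity?** Each factor has an
   effect profile across the measured responses; the dissimilarity index DI of
   a combination is the sum of pairwise Euclidean distances between its
   members' standardized profiles, range-normalized within each level. A
   hierarchy of seven models separates the *factor identity* contribution
   (Model 1: the three null predictions as predictors) from number-of-factors
   and dissimilarity contributions (Models 4–6) and full composition
   (Model 7), with GLM (R², AIC, nested F-tests) and random-forest
   (out-of-bag R², Altmann permutation importance) backends.

A synthetic-data generator with known ground truth (single-factor effect
matrix, per-response null world, optional distance-proportional interaction
terms, Gaussian unit noise) makes every stage testable end to end.

## Worked example

Simulate a reference-shaped experiment (12 factors; 20 controls, 10 water
controls, 12×8 single-factor units, 50 combinations at each of the 2/5/8
levels — 276 units) in an additive world with injected distance-proportional
interactions, then fit everything:

```python
from gcfpool import MultiFactorExperiment

config = {
    "truth": {"control_sd": 1.0, "world": "additive",
              "interaction": {"kind": "distance_proportional", "gamma": 0.15, "sign": +1}},
    "B": 2000, "K": 1000,
}
exp = MultiFactorExperiment.from_config(config, seed=7)
results = exp.fit(seed=7)
print(results.summary())
```

```
Multi-factor experiment — fit summary
==============================================
design: 164 treatments, 276 units ({'control': 20, 'water_control': 10, 'single': 96, 'multi': 150})
effect sizes: 1134 estimates over 7 responses (1041 with BH-adjusted p < 0.05)
factor ordination: PCoA axes explain 29.4%, 23.2%

best-fitting null model and net-interaction calls per response:
  beta_glucosidase       multiplicative syn=  8  ant=  8  none=134
  cellulase              additive       syn=121  ant=  2  none= 27
  decomposition_rate     dominative     syn= 10  ant=112  none= 28
  nag                    additive       syn=116  ant=  4  none= 30
  ph                     multiplicative syn=106  ant=  4  none= 40
  phosphatase            additive       syn=122  ant=  1  none= 27
  wsa                    dominative     syn= 11  ant=121  none= 18

Spearman DN vs normalized DI (best null model):
  beta_glucosidase       rho=+0.199  p=0.0146  n=150
  cellulase              rho=+0.347  p=1.4e-05  n=150
  ...

hierarchy (R² by model, delta vs baseline):
  cellulase              M1=0.452  dR²(+n)=+0.491  dR²(+DI)=+0.128  M7=0.958
  nag                    M1=0.246  dR²(+n)=+0.683  dR²(+DI)=+0.201  M7=0.945
  ...
```

Reading it: the injected interaction term is *positive* for every response
(`sign=+1`), so for responses that rise under stress (the enzymes, pH) the
treatments exceeding their null CI read as synergistic, while for the
negative-direction responses (decomposition rate, water-stable aggregates) the
same upward push opposes the stress direction and reads as antagonistic —
exactly the direction-dependent classification rule. Because the injected term
is proportional to pair distances, DN correlates positively with the
normalized dissimilarity index for every response, and the hierarchy's
Models 4/5 pick up sizable R² increments beyond the identity baseline.

The same pipeline runs from the shell, stage by stage or end to end:

```bash
gcfpool design --levels 2,5,8 --n-per-level 50 --seed 1 --out design.csv
gcfpool simulate --design design.csv --seed 1 --out responses.csv
gcfpool run --seed 1 --out artifacts/        # full pipeline + manifest
```

Measured data enter through the same CSV contracts
(`design.csv`: `treatment_id,kind,level,factors,n_replicates`;
`responses.csv`: `unit_id,treatment_id,response,value`).

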