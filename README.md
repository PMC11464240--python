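# vitalfit

Predicting discard survival of trawl-caught fish from vitality indicators.

When undersized fish are discarded from commercial trawls, managers need to
know what fraction survives. Holding fish in captivity to observe mortality
is expensive; scoring their *vitality* on deck — six reflex responses and
four injury types per fish — is cheap. `vitalfit` is a tested pipeline for
asking how well such scores predict survival, for fisheries scientists who
collect reflex-and-injury data (reflex action mortality predictor, RAMP,
style protocols) and want to go beyond the usual equal-weight index.

## What it computes

Each candidate model is a binomial logistic GLM of mortality at asymptote
(`1 = dead`) on a vitality indicator plus optional covariates:

    logit P(dead_i) = α + β₁X₁ᵢ + … + βₙXₙᵢ

Seven indicator families are compared, including the reflex-and-injury
index `RI = (1/10) Σₐ attrₐ` and its optimized version

    RI_w = Σₐ wₐ · attrₐ ,   wₐ ≥ 0, Σ wₐ = 1,

whose weights are found by nested optimization — the outer search moves
`w` on the simplex, the inner step refits the GLM — minimizing either the
fish-level AIC or the trip-level mean absolute error between predicted and
observed mean survival per trip. Twelve optimization methods run from the
same uniform start; the weighting is trusted only when the converged
methods agree. Candidates are then scored with AIC, Brier score (×100),
the Index of Prediction Accuracy `IPA = 100·(1 − Brier/Brier_null)`,
confusion matrices, and observed-vs-predicted survival ratios per trip and
gear with a high/low call at the 0.50 management line.

A synthetic-data module generates trip → deployment → fish datasets with
the same hierarchical structure and a known ground-truth survival model,
so every stage is testable without access to any field dataset. See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
import vitalfit as vf
from vitalfit.pipeline import RunConfig, run_model_comparison
from vitalfit.records_io import complete_cases

rs, truth = vf.generate(vf.default_config(), seed=1)
sub = complete_cases(rs, ["gear", "sea_temp"])
res = vf.optimize_weights(sub, "Gear*SeaTemp", "fish",
                          methods=["ucminf", "bobyqa", "L-BFGS-B"])
rep = vf.check_consistency(res)
print("consensus:", rep.status, " best:", rep.best.method,
      " AIC:", round(rep.best.objective, 1))
comp = run_model_comparison(sub, rep.best.weights, rep.best.weights,
                            RunConfig(seed=1))
print(comp.table[["model", "aic", "brier", "ipa", "accuracy"]]
      .round(2).to_string(index=False))
```

prints

```
consensus: trusted  best: bobyqa  AIC: 1067.7
      model     aic  brier   ipa  accuracy
RI_opt_fish 1067.72  16.86 28.75      0.75
RI_opt_trip 1067.72  16.86 28.75      0.75
partitioned 1084.65  16.83 28.90      0.75
         RI 1124.16  18.00 23.95      0.73
     n_both 1124.16  18.00 23.95      0.73
   n_injury 1171.36  18.82 20.47      0.71
   n_reflex 1188.11  19.21 18.85      0.71
categorical 1197.37  19.29 18.51      0.71
       null 1387.86  23.67  0.00      0.62
```

Reading this: the three optimization methods agreed on the weights
(`trusted`), and the optimized index concentrates weight on body bruising
(w = 0.27 here — the attribute the generator's truth makes most lethal).
Every indicator model beats the intercept-only null (IPA > 0), equal-weight
RI and the count of all impairments are identical models in different
clothing (AIC 1124.16 for both), and the optimized index lowers the AIC by
~56 points over equal weights. Brier 23.67 for the null is exactly
100·r(1−r) at this dataset's mortality rate r = 0.385.

The same pipeline runs from the shell:

```
vitalfit simulate --seed 1 --out data.csv
vitalfit run-all --input data.csv --out reports/
```

writing `weight_table.csv` (best weighting per level × covariate set, with
relevance classes), `model_comparison.csv`, `per_trip_sr.csv` and a
manifest with the seed and config hash.

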