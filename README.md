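# accelerage

Biological age prediction from time-to-event data, for biostatisticians
and epidemiologists building or evaluating mortality-trained "aging
clocks" on prospective cohort data.

## The idea

Biological age is operationalized through residual life. Individual *i*
with chronological age *c* and marker vector *x* has biological age *b*
when

    mrl(c | x) = mrl(b),

i.e. their model-predicted (mean or median) residual life equals the
residual life of a *b*-year-old in a reference population. Prediction is
a two-step procedure:

1. **Regression.** Fit an accelerated failure time (AFT) model with
   chronological age as the timescale on left-truncated, right-censored
   cohort data. With a Gompertz baseline hazard `h0(t) = a·exp(b·t)` —
   the canonical law of adult mortality — the conditional survival is
   `S(t|x) = S0(t·θ)` with aging rate `θ = exp(βᵀx)`, and the
   conditional law is again Gompertz(aθ, bθ). Estimate
   `m̂rl(c_i|x_i)` for every subject.
2. **Life-table inversion.** Look up the age `b̂_i` in a reference life
   table whose residual life equals `m̂rl(c_i|x_i)`.

The acceleration factor θ is directly interpretable as a faster (θ > 1)
or slower (θ < 1) ticking clock. Two comparators are included: a
semiparametric Cox model on the age axis with a Breslow baseline
(`CoxAge`), and a GrimAge-style clock (`GrimAgeModel`) that fits a Cox
model on time-on-study with age as a covariate and affinely rescales the
linear predictor to the training set's age mean and SD.

Evaluation goes beyond the usual age-acceleration hazard ratio:
predictions are scored by RMSE against known truth (in simulation),
Uno's IPCW concordance, and life-table calibration of predicted X-year
mortality probabilities.

## Worked example

```python
import numpy as np
from accelerage import (SimConfig, draw_cohort, true_bioage, GompertzAFT,
                        predict_bioage, rmse, uno_concordance)
from accelerage.simulate import population_table

cfg = SimConfig(mechanism="gompertz_aft", n_obs=5000, seed=1)   # beta = (0.05, 0.05)
train, test = draw_cohort(cfg), draw_cohort(cfg.with_seed(2))
table = population_table(cfg, mode="marginal")                  # true reference table

fit = GompertzAFT(train.data).fit()
print(fit.summary().round(4))
preds = predict_bioage(fit, table, test.data)
truth = true_bioage(test, table=table)
print("RMSE:", rmse(preds.bioage_hat, truth))
print("Uno's C:", uno_concordance(test.data, preds.bioage_hat).c_index)
```

Output:

```
         coef      se         z    p  ci_low  ci_high
log_a -8.9673  0.1306  -68.6765  0.0 -9.2232  -8.7113
log_b -2.4687  0.0219 -112.5160  0.0 -2.5117  -2.4257
x1     0.0511  0.0035   14.7039  0.0  0.0443   0.0579
x2     0.0527  0.0035   15.1017  0.0  0.0458   0.0595
RMSE: 0.2791004101626732
Uno's C: 0.8138395588510869
```

The fitted aging-rate coefficients (0.051, 0.053) recover the generating
values (0.05, 0.05) within one standard error, and the baseline
estimates (log a ≈ −8.97, log b ≈ −2.47, i.e. b ≈ 0.085) match the
generating mortality law. Biological age on the independent test cohort
is accurate to about a quarter of a year, and predicted biological age
ranks observed survival better than chronological age alone.

The same pipeline is available from the shell:

```bash
accelerage simulate --mechanism gompertz_aft --n-obs 5000 --seed 1 --out run/sim
accelerage lifetable --from-parametric gompertz --mode marginal \
    --assumption AFT --beta 0.05 --beta 0.05 --out run/table.csv
accelerage fit --model gompertz-aft --cohort run/sim/cohort.csv --out run/fit
accelerage predict --model-file run/fit/model.yaml --cohort run/sim/cohort.csv \
    --lifetable run/table.csv --out run/pred
accelerage evaluate --predictions run/pred/predictions.csv \
    --cohort run/sim/cohort.csv --truth run/sim/truth.csv --out run/eval
```

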