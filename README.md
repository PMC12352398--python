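# patchforage

Simulation and analysis of a timed patch-foraging decision task, built
for studying how people decide when to disengage from a depleting option
— and whether that differs in groups with elevated eating-disorder
symptoms. The package is aimed at computational-psychiatry researchers
who want a fully testable, download-free replica of the task, the choice
model, and the behavioural analyses.

It provides:

* **Task simulator** — four 720-s blocks crossing within-patch reward
  decay (0.81 / 0.91 per dig, SD 0.07, censored at 1) with travel delay
  (2.5 s / 9 s); first-dig rewards ~ N(100, 10); forced first dig; every
  event (RT, 1.5-s feedback, travel) consumes the block clock.
* **Choice model** — a logistic marginal-value-theorem rule,

  `P(exploit)ₜ = 1 / (1 + exp(−[c + β(r_{t−1} − T_t)]))`,

  whose leaving threshold `T_t` is a delta-rule reward-rate estimate
  (`r̂_t = r̂_{t−1} + α(r_t − r̂_{t−1})`, leaves update toward 0 with
  `α_l`, initialised at 50 per block), fitted per participant by
  multi-start bounded maximum likelihood — statsmodels-style
  (`MVTForagingModel.fit()` → `MVTForagingResults.summary()`).
* **Behavioural metrics** — patch residence times, leaving thresholds
  (prospective reward at the moment of leaving), response-vigour slopes
  from Gamma log-link regressions of RT on remaining block time, with
  Welch/permutation group tests and Spearman symptom correlations.
* **Optimal-policy sweep** — total block reward for leave-after-*n*
  policies, giving the optimal residence per condition.
* **Synthetic cohort generator** — a 44 + 56 two-group cohort with
  group-specific choice parameters, RT acceleration under time pressure,
  and symptom scores correlated with that acceleration, so the entire
  pipeline runs end to end without any external data.

## Worked example

```python
import numpy as np
from patchforage import ModelParams, MVTForagingModel, simulate_agent

true = ModelParams(alpha=0.15, alpha_l=0.02, beta=0.20, c=4.6)
trials = simulate_agent(true, rng=1)          # one 4-block session
res = MVTForagingModel(trials).fit(n_starts=10, seed=0)
print(res.summary())
```

```
MVT foraging choice model (participant-level ML fit)
========================================================
participant: sim   trials: 997 (free choices: 897)
NLL: 214.0736   AIC: 436.1472   starts: 10 (converged 10)
--------------------------------------------------------
   param     estimate      std err  bounds
   alpha       0.1356       0.0180  (0.0, 1.0)
 alpha_l       0.0439       0.0486  (0.0, 1.0)
    beta       0.1923       0.0268  (0.0, 2.0)
       c       4.5262       0.5002  (-50.0, 50.0)
```

The agent produced 997 decisions; the refit recovers the generating
sensitivity (β 0.19 vs 0.20) and exploitation bias (c 4.53 vs 4.6); the
rewarded learning rate is close (α 0.14 vs 0.15) while the leave rate
α_l is weakly identified, as its standard error shows.

The same flow works from the shell:

```sh
patchforage cohort  --seed 1 --out run/cohort      # synthetic 100-person study
patchforage fit     --trials run/cohort/trials.csv --out run/fits
patchforage analyze --trials run/cohort/trials.csv \
                    --participants run/cohort/participants.csv --out run/analysis
patchforage sweep   --out run/sweep                # optimal residence per condition
```

Every output directory contains a manifest (seed + settings) that
reproduces it bit-exactly.

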