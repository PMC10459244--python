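# fiprisk

Probabilistic dietary risk assessment of fipronil residues in food, built as
a reusable, tested Python pipeline. Fipronil is a phenylpyrazole insecticide
whose residues are monitored in fruits, vegetables and chicken eggs; in
routine surveillance more than 95% of samples are non-detects, and the
classic fixes (substituting DL/2 for every non-detect, deterministic safety
factors) hide most of the uncertainty that matters for risk characterization.

`fiprisk` is aimed at exposure and risk assessors who want the full
probabilistic treatment:

1. **Censored-residue reconstruction** (`fiprisk.residues`) — Bayesian MCMC
   fit of a lognormal concentration distribution per food category, where
   detects enter through the density and the n censored samples through the
   lognormal CDF at an inferred reporting limit RL:
   `ln y ~ Normal(ln GM, ln GSD)`, censored term `n_cen · ln Φ((ln RL − ln GM)/ln GSD)`,
   with priors `GM ~ N(Y_max/2, Y_max/4)`, `ln GSD ~ N(ln 4, ln 2)`,
   `RL ~ N(Y_min, Y_min/5)` and the Gelman–Rubin R̂ < 1.1 convergence rule.
2. **Monte Carlo exposure simulation** (`fiprisk.exposure`) — 200,000
   simulated individuals across age(0–100) × sex strata (≥ 10 per stratum),
   truncated-normal body weights and food intakes, lognormal residue draws
   via the exact moment map `meanlog = ln(m²/√(s²+m²))`, `sdlog = √(ln(1+s²/m²))`,
   and the aggregate chronic dose
   `exposure_j = Σ_i intake_ij · residue_ij / (BW_j · 1000)` [mg/kg/day],
   under general-population (LB) and consumer-only (UB) intake scenarios.
3. **Bayesian benchmark dose** (`fiprisk.doseresponse`) — the eight standard
   dichotomous models (Logistic, LogLogistic, Probit, LogProbit, Quantal
   Linear, Multistage-2, Weibull, Dichotomous Hill) fitted by MCMC to
   convulsion incidence in male SD rats, inverted for the BMD at 10% extra
   risk, and combined into a model-averaged BMD posterior with posterior
   model weights.
4. **Probabilistic reference dose** (`fiprisk.prfd`) — WHO/IPCS-style
   conversion `HD50 = BMD·(BW_a/BW_h)^(1−b)/A` with `b ~ N(0.7, 0.0243)` and
   `A ~ LN(GM 1, GSD 1.95)`, then `HDMI = HD50/10^F` with
   `F ~ LN(GM 0.746, GSD 1.5935)` (human variability at incidence I = 1%);
   the pRfD is the lower 5th percentile of HDMI.
5. **Risk characterization** (`fiprisk.risk`) — hazard quotients
   `HQ = exposure / (ADI or pRfD)` with exceedance summaries by age group
   and sex; the deterministic ADI is NOAEL 0.019 / SF 100 = 0.0002 mg/kg/day.

A synthetic-data module (`fiprisk.synthetic`) replaces the external
Taiwanese surveillance/consumption/demographic databases: it calibrates a
lognormal to each category's published summary row (total samples, detect
count, detect-only mean/SD, DL = 0.002 ppm) and emits per-sample residue
tables, demographics and intake tables with the same statistical structure.

## Worked example

```python
from fiprisk.doseresponse import (FIPRONIL_CONVULSION, fit_all_models,
                                  compute_model_weights, model_average_bmd)
from fiprisk.prfd import derive_hdmi

fits = fit_all_models(FIPRONIL_CONVULSION)          # 3 chains x 50,000, seed 76316
weights = compute_model_weights(fits)               # BIC-approximated marginal likelihoods
avg = model_average_bmd(fits, weights, n_draws=100_000, seed=2)
res = derive_hdmi(avg.averaged_draws, seed=3)
print({k: round(v, 3) for k, v in weights.items()})
print("BMD median", round(res.percentile_table["BMD"]["median"], 2))
print("HD50 median", round(res.percentile_table["HD50"]["median"], 2))
print("HDMI median", round(res.percentile_table["HDMI"]["median"], 3))
print("pRfD", round(res.prfd, 4))
```

prints (seed-dependent in the last digits):

```
{'Logistic': 0.308, 'LogLogistic': 0.019, 'Probit': 0.307, 'LogProbit': 0.019,
 'QuantalLinear': 0.3, 'Multistage2': 0.019, 'Weibull': 0.019, 'DichotomousHill': 0.007}
BMD median 14.36
HD50 median 3.14
HDMI median 0.523
pRfD 0.0538
```

i.e. the three two-parameter models carry ~90% of the weight, the averaged
benchmark dose is ~14 mg/kg/day, the median human dose at 50% population
incidence is ~3 mg/kg/day, and the probabilistic reference dose — the dose
protecting 99% of the population from ≥10% extra risk of neurotoxicity with
95% confidence — is ~0.05 mg/kg/day, roughly 250× the deterministic ADI.

An end-to-end run on synthetic inputs:

```bash
fiprisk synth --out inputs --seed 1
fiprisk run-all --config config.yaml        # reconstruct -> expose -> bmd -> rfd -> risk
fiprisk report --run-dir out/
```

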