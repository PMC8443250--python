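# extinctrl

Simulation and analysis toolkit for three-day fear-conditioning /
extinction experiments: trial-schedule generation, a Rescorla-Wagner /
Pearce-Hall hybrid learning model with maximum-likelihood fitting of binary
US-expectancy ratings, model-derived parametric regressors for first-level
fMRI GLMs, skin-conductance / fear-rating contrasts, and causal mediation
analysis — all exercisable end-to-end on synthetic cohorts with known
ground truth.

## Modules

| module | purpose |
| --- | --- |
| `extinctrl.paradigm` | Day 1–3 trial schedules (habituation + acquisition, extinction, retrieval + reinstatement) and BIDS-style events TSV I/O |
| `extinctrl.hybrid_model` | value / associability / prediction-error recursion, logistic observation model, Bernoulli likelihood |
| `extinctrl.fitting` | Nelder-Mead MLE per subject (reparameterised, multi-start with coarse-grid pre-scan), cohort tables |
| `extinctrl.regressors` | stick-function designs at TR = 1.493 s, canonical double-gamma HRF, parametric modulators (group-mean PE, orthogonalised associability), OLS first level |
| `extinctrl.psychophys` | ln(1+x) + range correction of SCRs, VAS rating correction, block averages, differential and reinstatement contrasts, group tests, Pearson correlation |
| `extinctrl.mediation` | two-path OLS mediation, quasi-Bayesian ACME (1000 draws) and bootstrap CIs |
| `extinctrl.synthetic_data` | seeded ground-truth cohorts (two groups, mediated group effect), agents, synthetic BOLD |

## CLI

```bash
extinctrl simulate-schedule --day 2 --seed 7 --out events.tsv
extinctrl make-cohort --out data/ --seed 11           # events + ratings + SCR + truth.json
extinctrl fit --ratings data/ratings.csv --events data/sub-001/events_day2.tsv --out fits.csv
extinctrl psychophys --scr data/scr.csv --out contrasts.csv --k 3
extinctrl mediate --in data/mediation.csv --method qb --draws 1000 --seed 1
```

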