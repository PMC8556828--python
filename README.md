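# emonet — temporal emotion networks and burnout

`emonet` implements a complete analysis pipeline for studying the *dynamics*
of momentary emotions in relation to burnout. In ecological momentary
assessment (EMA) studies, participants rate emotions (e.g. frustrated,
stressed, worried, exhausted) on a 0–100 visual-analogue scale several times
a day for weeks. How strongly those emotions carry over and spill into each
other from one prompt to the next — their inertia and cross-lagged
interplay — can be summarised as a *temporal network*: a directed graph
whose edge from emotion *k* to emotion *j* is the lag-1 regression
coefficient Φ[j,k]. The mean absolute coefficient, the network **density**,
indexes how rigid a person's emotion system is; the scientific question is
whether denser negative-emotion networks go with more severe burnout.

It is written for researchers running (or re-analysing) EMA protocols of
this design: ~5 prompts/day over 2–3 weeks, four to eight emotion items, and
a Maslach Burnout Inventory – General Survey (MBI-GS) assessment at the end
of the sampling period.

## The model

For person *i* with within-person-centered ratings x, each emotion *j* at
prompt *t* is modeled by a multilevel lag-1 vector autoregression (mlVAR),
fitted equation by equation as a linear mixed model:

    y_ij(t) = (β0_j + b0_ij) + Σ_k (B[j,k] + b_ij[k]) · x_ik(t−1) + ε_ijt

* **B** — fixed effects: the population-average temporal network.
* **b_i** — random effects: subject deviations, predicted by empirical
  Bayes (BLUPs); person-specific networks are Φ_i = B + b_i.
* Transitions crossing midnight are removed (the overnight lag is not
  comparable to the within-day lag), predictors are person-mean centered,
  and transitions with any missing rating are dropped listwise.
* Density_i = Σ|Φ_i| / divisor, with divisor p² by default (the mean
  absolute effect) or an explicit compatibility divisor.
* The density–burnout association is tested one-sided (positive) with
  Pearson's r and Spearman's ρ at α = .05, after screening both variables
  for values diverging more than 3 sample SDs from their mean.

A synthetic-data generator (`emonet.synthetic_data`) produces cohorts with
known person-specific VAR(1) matrices, realistic pseudorandom prompt
schedules, missing-at-random nonresponse, burnout outcomes with a chosen
true correlation to density, and one-factor MBI-GS items calibrated to a
target Cronbach's α — so every stage of the pipeline is testable against
ground truth without any external data.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort (the original study's shared data files are not redistributed here;
see below). `python analysis/01_study_design.py` prints the sampling plan
and power analysis:

```
scheduled prompts: 85
usable same-day transitions (complete subject): 68
planned assessments at 20% missing: 54
required sample size for rho=0.3, one-tailed, alpha=.05, power=.80:
  gpower_t                 n = 64
  exact_bivariate_normal   n = 67
  fisher_z                 n = 68
```

85 prompts lose 20% to the overnight-lag rule and another 20% to assumed
nonresponse, leaving ~54 analyzable assessments per person. The three
sample sizes are three conventions for powering the correlation test: the
noncentral-t approximation (the G*Power correlation module), the exact
sampling distribution of r under bivariate normality, and the Fisher-z
approximation.

`02_simulate_cohort.py`, `03_fit_networks.py` and `04_density_burnout.py`
then generate a 47-subject cohort (seed 1), estimate the networks and test
the association:

```
enrolled 47: 0 missing burnout, 0 over the EMA-missingness limit -> N = 47
lagged design: 2254 same-day transitions (median 48 per subject)
group network: 10 significant edges at alpha=.05
median density: 0.1226 (p^2 divisor), 0.0981 (divisor 20)
burnout severity: mean 2.55, quartiles [1.88, 3.25]
Cronbach's alpha (16 items, efficacy reversed): 0.901
Pearson  r(45) = 0.12, 95% CI [-0.13, 1.0], one-sided p = 0.213
Spearman s(45) = 0.16, one-sided p = 0.146
```

All significant group-level edges are positive, autoregressive effects
(~0.3) dominate the cross-lags (~0.05), and the per-subject densities sit
around 0.10 under the 20-divisor convention. The true density–burnout
correlation in this cohort is 0.40, but estimating each subject's network
adds noise: at n = 47 the observed r of 0.12 is not significant — a
concrete illustration of the attenuation any single study of this size
faces (at n = 200 the pipeline detects the association reliably; see the
acceptance tests).

The same pipeline is exposed programmatically,

```python
from emonet import RunConfig, SimConfig, run_study
report = run_study(RunConfig(sim=SimConfig(n_subjects=47, seed=1), re_structure="diagonal"))
print(report.correlations["pearson"])
```

and as a CLI (`emonet simulate|prepare|power|score-mbi|correlate|run`).

## Re-analysing the original study data

`analysis/05_replicate_published.py` reruns the published analysis (divisor
20, one-sided tests, both emotion sets) if the study's supplementary data
files are placed at `data/additional_file_2.csv` (EMA panel) and
`data/additional_file_1.csv` (subject table), both ';'-separated. The
corresponding acceptance test checks the published values (final N = 47,
median 77 observations, negative-set median density 0.093, r = .32,
ρ = .36, positive-set 0.096 with r = .14, burnout mean 2.19, α = .91) and
fails with an explanatory message when the files are absent.

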