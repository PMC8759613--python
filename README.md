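# cloudprobit

Bayesian multilevel ordinal-probit analysis of weather–pain associations
from daily smartphone symptom diaries.

## The scientific problem

Many people with chronic pain report that weather affects their symptoms,
yet population-level studies find only modest average associations. One
explanation is heterogeneity: a minority of *weather-sensitive* individuals
— some reacting to high values of a weather variable, some to low — whose
opposing effects largely cancel in the population mean. Detecting such
subgroups requires long within-person symptom series and a model that
estimates an individual effect for every participant while sharing
statistical strength across the cohort.

`cloudprobit` implements that analysis for ecological-momentary-assessment
cohorts: participants report daily ordinal pain severity (1 = no pain … 5 =
very severe) on a smartphone, hourly GPS locations are linked to the
nearest weather station, and daily mean exposures (temperature, pressure,
relative humidity, wind speed) are regressed on pain in a hierarchical
cumulative probit model. Because such diary datasets are usually not
redistributable, the package ships a first-class synthetic-cohort generator
with known ground truth, calibrated to published cohort descriptors
(~82% female, mean age ≈ 48.7, median follow-up ≈ 106 days, ~65% reporting
compliance, ~70% of reports in the mild/moderate categories).

## The model

For participant *i* on day *j*, a latent variable

  z_ij = x_ij′β + w_ij′(γ + u_i) + u_i0 + f(t_ij) + ε_ij,  ε_ij ~ N(0, 1)

crossed with ordered cutpoints τ₁ < τ₂ < τ₃ < τ₄ generates the observed
category: y_ij = c iff τ_{c−1} < z_ij ≤ τ_c. Here w_ij holds the four
scaled daily exposures (per 1 °C, per 10 mbar, per 10 % humidity, per
1 m s⁻¹), γ the population weather effects, and
u_i = (u_i0, u_i1, …, u_i4)′ ~ MVN(0, Σ) a participant's correlated random
intercept and weather slopes. x_ij carries age, sex, belief in a
weather–pain link, daily mood and exercise; f(t) is a natural cubic spline
in days since study entry. Estimation is by data-augmentation Gibbs
sampling (Albert–Chib latent utilities, conjugate coefficient and
covariance updates, collapsed Metropolis cutpoint moves, and exact
translation moves along the likelihood-invariant ridges), with
rank-normalized split R-hat, effective sample sizes and posterior
predictive checks as diagnostics.

Outputs mirror the standard reporting of such studies:

* **Population summary** — posterior mean, equal-tailed 95% credible
  interval, and the *marginal effect at the mean* (MEM): the change in
  P(pain ≥ moderate) per scaled unit of a weather variable for the
  population-typical participant.
* **Sensitivity classification** — each participant × parameter labelled
  *high-value sensitive* (95% CrI of γ_k + u_ik entirely positive),
  *low-value sensitive* (entirely negative) or *undetermined*, plus
  forest-plot data, multi-parameter sensitivity counts, and prevalence
  breakdowns by single-diagnosis groups (osteoarthritis, fibromyalgia/CWP,
  inflammatory arthritic pain, other chronic pain).

## Worked example

```python
from cloudprobit import (GeneratorConfig, generate_dataset, filter_cohort,
                         link_exposures, assemble_analysis_table,
                         HierarchicalOrdinalProbit)
from cloudprobit.effects import classify_participants, sensitivity_profile

data = generate_dataset(GeneratorConfig(n_participants=100, seed=7))
included = filter_cohort(data["baselines"], data["reports"])
baselines = data["baselines"][data["baselines"].participant_id.isin(included)]
reports = data["reports"][data["reports"].participant_id.isin(included)]
pings = data["pings"][data["pings"].participant_id.isin(included)]
exposures = link_exposures(pings, data["stations"], data["observations"])
table, scaling = assemble_analysis_table(baselines, reports, exposures)

model = HierarchicalOrdinalProbit(n_chains=2, n_warmup=1000, n_keep=1000,
                                  seed=1).fit(table)
print(model.summary_.round(3))
```

prints (6892 participant-days from 95 participants; max R-hat 1.009):

```
                  parameter  estimate  cri_lower  cri_upper    mem
      Temperature (per 1°C)    -0.164     -0.206     -0.123 -0.055
     Pressure (per 10 mbar)    -0.119     -0.185     -0.047 -0.039
Relative humidity (per 10%)     0.256      0.168      0.346  0.073
   Wind speed (per 1 m·s⁻¹)     0.106      0.063      0.150  0.032
```

The generating values were γ = (−0.15, −0.15, 0.30, 0.15): every 95%
credible interval covers its truth. The estimate column is on the latent
(probit) scale per scaled unit; `mem` says, e.g., that +10 percentage
points of relative humidity raises the probability of at least moderate
pain by 7.3 points for the population-typical participant under these
(deliberately decisive) synthetic effect sizes. Classification then
recovers the built-in heterogeneity:

```python
labels = classify_participants(model.draws_)
print(sensitivity_profile(labels)["proportions"].round(3))
# x_temp: 67% low-value sensitive; x_hum: 42% high-value sensitive; ...
```

The same pipeline runs from the shell:

```bash
cloudprobit run-all --preset smoke --seed 4 --out out/   # < 2 minutes
cloudprobit simulate|fit|report ...                      # stage by stage
```

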