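# thermomort

Probabilistic early warning of temperature-driven mortality. Given daily
regional records of air temperature, dew point, death counts and population,
`thermomort` estimates each region's temperature–mortality exposure-response
curve, finds its *comfort temperature* (the temperature of minimum
mortality), fits an independent Bayesian cubic model to the warm and cold
tails of the curve, simulates probabilistic mortality for heat-wave and
cold-spell temperature scenarios, and verifies the resulting
emergency-threshold exceedance forecasts. It is aimed at climate-service and
environmental-epidemiology practitioners who need calibrated, regional
"will mortality exceed the emergency threshold?" probabilities.

## The model

Exposure is daily mean **apparent temperature**,
`Tapp = −2.653 + 0.994·Tair + 0.0153·Tdewpt²` (°C), a humidity-adjusted
index. For each region *i* the observed `Tapp` range is divided into equally
spaced intervals (default 0.1 °C); days in each interval *k* are averaged,
giving interval-mean temperature `x_ik` and the log interval-mean mortality
rate `y_ik` (deaths per million per day). A centred 31-term moving-average
filter (≈ 3 °C) smooths the curve; its minimum defines the comfort
temperature `x_im`, splitting the range into cold (`x < x_im`) and warm
(`x ≥ x_im`) tails. Each tail *j* is modelled as

    y_ik ~ Normal(α_j + β1_j·x_ik + β2_j·x_ik² + β3_j·x_ik³, σ_j²)

with predictors centred at `x_im`. The prior is conjugate
Normal–Inverse-Gamma, so the joint posterior of `(α, β1, β2, β3, σ)` is
sampled exactly (1000 draws per tail by default, no MCMC).

For a scenario — daily apparent temperatures `x_it` over an episode such as
a 15-day heat wave — each day is routed to the tail its temperature falls
in and a daily log rate `y_it` is drawn per posterior sample, including
residual noise σ. Daily rates `exp(y_it)` are averaged over the episode;
the forecast probability is the fraction of posterior draws whose
event-mean rate exceeds the region's **emergency threshold**, the 75th
percentile of observed daily rates conditional on the tail. Warnings issued
at a decision threshold (30% cautious / 70% strict) are scored across
regions by hit rate, false-alarm rate, proportion correct and the ROC
score (area under the hit-rate/false-alarm-rate curve; 50% = no skill).

Because the multi-country daily mortality dataset such analyses use is not
publicly redistributable, the package ships a first-class synthetic
generator (`thermomort.synthetic`) producing multi-region panels with known
ground-truth curves, against which the whole pipeline is validated.

## Worked example

```python
import thermomort as tm
from thermomort.synthetic import simulate_event_observations
from thermomort.verification import verification_table

panel = tm.generate_panel(n_regions=54, n_years=6, seed=1)      # synthetic study
results = tm.MortalityEarlyWarning(panel.series).fit()
print(results.summary())

truths = list(panel.truths.values())
scen = tm.generate_scenario(truths, kind="heatwave", seed=1, severity=8.0)
scen = simulate_event_observations(truths, scen, seed=1)        # "observed" outcome
forecasts, _ = results.predict_scenario(scen, tail="warm")
print(verification_table(forecasts, scenario="heatwave").round(3).to_string(index=False))
```

prints

```
Temperature-mortality early-warning model
regions fitted: 54
posterior draws per tail: 1000
comfort temperature: median 19.5 degC, range 14.2-25.1 degC
emergency threshold: 75% quantile of tail-conditional daily rates
config hash: 282493852ea55db4  seed: 0
scenario  threshold_level  roc_score  decision_threshold  hit_rate  false_alarm_rate  proportion_correct
heatwave             0.75      0.993                 0.3     0.958             0.167               0.944
heatwave             0.75      0.993                 0.7     0.958             0.000               0.963
```

i.e. for this simulated 8 °C heat wave the model discriminates
exceeding/non-exceeding regions almost perfectly (ROC score 99.3%); at the
strict 70% trigger it catches 95.8% of true events with no false alarms.

The same pipeline runs from the shell:

```sh
thermomort simulate --n-regions 10 --years 6 --seed 3 --out-dir data/
thermomort run-all --panel data/panel.csv --scenario data/scenario_heatwave.csv \
    --tail warm --seed 3 --out-dir out/
```

writing curves, comfort temperatures, posterior draws, forecasts and
verification tables as CSV/JSON, all reproducible byte-for-byte from the
seed.

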