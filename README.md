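# yldhale

Measuring health-adjusted life expectancy (HALE) normally requires the
full prevalence of every non-fatal condition, converted into an all-cause
years-lived-with-disability (YLD) rate — data that provincial and
municipal health authorities rarely have. `yldhale` implements a
practical alternative calibrated for China: the 21 age-specific YLD rates
are predicted from just three routinely monitored indicators, and HALE
follows from an ordinary abridged life table via the Sullivan method.

The package is for epidemiologists and health planners who need HALE
estimates (national, provincial or municipal) from routine surveillance
data, and for methodologists who want to re-estimate or stress-test the
transfer model on their own reference panels.

## The model

For each of the 21 age groups (0, 1–4, 5–9, …, 90–94, 95+) and each sex,
the all-cause YLD rate Y_i is linked to three predictors by a linear
model on a half-logit scale:

```
Γ(Y_i) = β_i + a_i·X₁ + b_i·X₂ + c_i·X₃        Γ(Y) = ½·ln((1−Y)/Y)
```

* **X₁ (IID)** — incidence of class A/B notifiable infectious diseases,
* **X₂ (PCDPF)** — prevalence/incidence of chronic disease among persons
  aged 15+ (the only sex-specific predictor),
* **X₃ (U5MR)** — under-five mortality rate,

all expressed as proportions in [0, 1]. Note the transform is
*decreasing* in Y (and carries a ½ factor); the published coefficient
tables are only valid under exactly this transform. The bundled
`gbd2019_china_3param` asset ships the published male/female/combined
coefficients with their 95% uncertainty bounds.

HALE at the start of age group x is the Sullivan sum over remaining
groups,

```
HALE_x = Σ_{j≥x} L_j·(1 − Y_j) / l_x ,
```

with survivors l and person-years L from an abridged life table (held
fixed). Uncertainty intervals are Monte-Carlo: the reference panel's
half-logit YLD values are resampled from per-year normals whose spread is
recovered from the published 95% bounds, all 21 models are refit per
draw, and the 2.5th/97.5th percentiles across draws are reported for
every coefficient, YLD rate and HALE value.

## Worked example

```python
import yldhale as yh

table = yh.load_coefficient_table("gbd2019_china_3param")
x = yh.PredictorSet(iid=0.0023, pcdpf=0.2656, u5mr=0.0289, sex="both")

yld = yh.predict_yld_rates(table, x)
config = yh.SyntheticConfig(seed=1)          # synthetic stand-in inputs
lt = yh.generate_life_table(config)
hale = yh.sullivan_hale(lt, yld)
```

With the observed mean indicator values above this prints:

```
YLD rate, age 0:     0.02659
YLD rate, age 60-64: 0.17067
YLD rate, age 95+:   0.40829
e0:     73.89 years
HALE0:  65.72 years
```

Reading: an infant spends about 2.7% of each year in less-than-full
health, rising to 41% past age 95; against a life table with 73.89 years
of life expectancy at birth, 65.72 of those years are lived in full
health. (The life table here is synthetic; supply your own
`age_group,l,L` CSV for real populations.)

Re-fitting on a (here synthetic) reference panel and propagating its
uncertainty:

```python
panel = yh.generate_reference_panel(config)
res = yh.propagate_uncertainty(panel, lt, x, n_draws=1000, seed=1)
```

gives `HALE0 = 65.56 (63.94, 66.48)` — point estimate from the
unperturbed fit, bounds from 1000 refit draws.

The same workflow is available from a shell via `yldhale predict`,
`hale`, `fit`, `uncertainty`, `simulate` and `evaluate`; every command
writes plain CSV with a deterministic metadata header. Try:

```sh
yldhale simulate --years 30 --seed 1 --out-dir sim
yldhale fit --panel sim/panel.csv --predictors sim/predictors.csv --out-dir fit
```

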