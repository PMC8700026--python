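# t2dscreen

A cost-utility model of population screening for type 2 diabetes at two
primary-care tiers (commune health stations and district health centers),
rebuilt as a tested, configurable Python package.

The model is a hybrid of:

* **screening cascades** (`t2dscreen.screening`) — risk questionnaire →
  capillary glucose → referral → plasma glucose confirmation at the commune
  tier; risk questionnaire → plasma glucose → repeat plasma glucose at the
  district tier, with per-round detection probabilities and expected cascade
  costs by true state and perspective;
* a **five-state lifetime Markov cohort model** (`t2dscreen.markov`) —
  disease-free, undiagnosed, diagnosed, complication, dead — with
  HbA1c-scaled mortality and complication risks applied on the rate scale,
  background mortality from a life table, a 1-year cycle, Simpson 1/3
  within-cycle correction, and 3% annual discounting;
* **economic evaluation** (`t2dscreen.econ_eval`) — ICERs with dominance
  flags, net monetary benefit ranking at a threshold of one GDP per capita
  (US$ 2,715.3/QALY), and the extended-dominance efficient frontier;
* **uncertainty analysis** (`t2dscreen.uncertainty`) — one-way DSA with
  tornado ordering on incremental NMB, seeded Monte Carlo PSA with common
  random parameter draws, cost-effectiveness planes and acceptability
  curves;
* **parameter machinery** (`t2dscreen.params`) — the published input table
  shipped as CSV, beta/gamma/lognormal distributions fitted by the method of
  moments, and ±20% / 95%-CI one-way ranges;
* **synthetic data** (`t2dscreen.synthetic_data`) — a Gompertz–Makeham life
  table calibrated to a life-expectancy target (the national table is not
  publicly deposited), gamma cost microdata, and additive-decrement
  EQ-5D-style questionnaire data with their (mean, SE) estimators.

## CLI

```bash
# full scenario grid (ages x intervals x tiers x perspectives)
t2dscreen run --config cfg.yaml --out results/

# probabilistic sensitivity analysis (draw table, CE plane, CEAC CSVs)
t2dscreen psa --n 1000 --seed 12345 --out psa_out/

# one-way sensitivity analysis (tornado CSV)
t2dscreen dsa --setting CHS --interval annual --out tornado.csv

# synthetic inputs
t2dscreen synth-lifetable --e0 73.6 --out life_table.csv
t2dscreen synth-microdata --kind cost --n 1631 --mean 66 --out costs.csv
```

Config files are YAML; every key is optional. The defaults reproduce the
base case (start age 40, all three intervals, both tiers, both
perspectives); `src/t2dscreen/data/paper_base.yaml` spans the full
published grid. Example:

```yaml
ages: [30, 35, 40, 45]
intervals: ["one-off", "annual", "3-yearly"]
settings: ["CHS", "DHC"]
perspectives: ["societal", "provider"]
life_table_e0: 73.6   # or life_table_path: my_table.csv
wtp: 2715.3
seed: 12345
```

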