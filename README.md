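# adofp

Bayesian hierarchical estimation and projection (1990–2030) of family-planning
indicators — contraceptive use (any/modern), unmet need, total need, and the
share of need satisfied by modern methods — among adolescent women aged 15–19,
separately for married and unmarried women, with draw-level aggregation to
all-women, regional and global estimates.

The package is self-contained: a synthetic-data generator produces complete
input bundles (survey observations with bias/misclassification flags,
demography, country groupings) with the statistical structure the model
assumes, so the whole pipeline runs and validates without any external data.

## What is inside

| Module | Role |
| --- | --- |
| `adofp.core_io` | Domain types, CSV readers/writers, dataset validation |
| `adofp.synthetic_data` | Truth + survey + demography + metadata generator |
| `adofp.process_model` | Logistic transition curves, unmet-need link, AR(1) deviations, composition assembly |
| `adofp.observation_model` | Survey likelihood with non-baseline-sample shifts and modern/traditional misclassification |
| `adofp.hierarchy` | Geographic (married) and sexual-activity-group (unmarried) shrinkage trees |
| `adofp.inference` | Adaptive Metropolis-within-Gibbs sampler, diagnostics (split R-hat, ESS), projection to 2030 |
| `adofp.indicators` | Marital-weighted combination, counts, draw-level aggregation, SDG 3.7.1, summaries with median-identity adjustment, suppression rules, adolescent share |
| `adofp.validation` | Holdout splits and posterior-predictive coverage reports |
| `adofp.visualization` | Ternary coordinates, ternary-balance colour blending, trajectory fan plots |

## CLI

```bash
# generate a synthetic input bundle (observations/demography/meta + truth)
adofp simulate --seed 1 --out bundle/            # optionally --config cfg.yaml

# fit both marital groups and write estimate tables
adofp fit --observations bundle/observations.csv \
          --demography bundle/demography.csv \
          --meta bundle/meta.csv \
          --chains 4 --iterations 10000 --warmup 5000 --thin 5 \
          --seed 1 --out results/
```

`fit` writes `estimates_married.csv`, `estimates_unmarried.csv`,
`estimates_all.csv` (medians with 95% uncertainty intervals) and a
`validation.json` dataset report.

## Library example

```python
from adofp.synthetic_data import SimulationConfig, make_fixture, simulate_truth, simulate_surveys
from adofp.inference import ModelConfig, McmcConfig, fit, diagnostics
from adofp import indicators

cfg = SimulationConfig(n_regions=2, n_subregions_per_region=2, n_countries_per_subregion=3)
truth = simulate_truth(cfg, seed=1)
obs = simulate_surveys(truth, cfg, seed=2)

samples = {
    g: fit(obs, truth.demography, truth.meta, ModelConfig(),
           McmcConfig(n_chains=4, n_iterations=10_000, n_warmup=5_000, seed=3),
           marital_group=g)
    for g in ("married", "unmarried")
}
print(diagnostics(samples["married"])["flagged"])

all_women = indicators.combine_marital(samples["married"], samples["unmarried"], truth.demography)
records = indicators.summarize(all_women, years=[1990, 2019, 2030])
```
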