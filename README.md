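# mucosim

Deterministic compartmental PK/PD modelling of a topically applied
antiretroviral gel on vaginal mucosa, plus a machine-learning bridge from
blood pharmacokinetics to mucosal pharmacokinetics/pharmacodynamics.

The package has four parts:

1. **Transport model** (`mucosim.transport`) — coupled 1-D unsteady
   diffusion–reaction of drug across gel, epithelium and stroma with
   partition-coefficient jumps at the layer interfaces, a first-order
   dilution sink in the gel, a stroma-to-blood uptake term feeding a
   well-mixed blood compartment with first-order clearance, and local
   intracellular conversion to the active diphosphate metabolite.
   Solved by a conservative cell-centred finite volume (solubility-
   transformed potential, harmonic-mean face conductances) with
   Crank–Nicolson stepping; the discrete mass ledger closes to round-off.
2. **Metrics** (`mucosim.metrics`) — compartmental PK summaries
   (Cmax, tmax, AUC, C24) and the percent-protected (PP) pharmacodynamic
   time course: the instantaneous fraction of stromal volume whose
   metabolite concentration meets a prophylactic EC50, summarized by the
   time to maximum protection (t_lag) and the maximum protection (PPmax).
3. **Cohort** (`mucosim.cohort`) — the canonical host-variability design:
   a full-factorial 5×5×5 grid over epithelial thickness, gel dilution
   rate and stroma-to-blood transport rate (125 distinct cases), plus
   independently sampled test cohorts and train/test splitting.
4. **Neural nets** (`mucosim.neuralnet`, `mucosim.workflow`) — a
   single-hidden-layer perceptron (10 sigmoid units, linear output)
   trained by Levenberg–Marquardt with analytic Jacobians and
   multi-restart selection on an independent test cohort; one net per
   stromal metric maps the four blood PK metrics to stromal
   Cmax/tmax/AUC/C24 and to t_lag/PPmax.

## Command-line pipeline

All commands accept `--config` (YAML, defaults shipped in
`mucosim/data/default_config.yaml`), `--seed` and `--log-level`; every
output embeds the config hash and seed, and identical (config, seed)
yields byte-identical outputs.

```sh
# 1. one simulation: concentration fields + PK/PD summary
mucosim simulate --out runs/standard

# 2. the 125-case cohort dataset
mucosim cohort --out runs/cohort

# 3. train the six blood-to-stroma metric maps
#    (an independent test cohort is simulated automatically; pass
#    --test-dataset to supply one instead)
mucosim train --dataset runs/cohort/cohort.csv --out runs/nets

# 4. predict mucosal metrics from per-subject blood PK metrics
mucosim predict --nets runs/nets --input blood_metrics.csv \
                --out predictions.csv
```

`blood_metrics.csv` needs the columns `blood_Cmax`, `blood_tmax`,
`blood_AUC`, `blood_C24` (units ng/mL, hr, ng·hr/mL, ng/mL).

## Python API sketch

```python
from mucosim import (default_params, default_discretization, simulate,
                     volume_average, pk_metrics, percent_protected,
                     pd_metrics, build_variation_grid, run_cohort,
                     sample_cases, train_metric_maps)

params = default_params()
disc = default_discretization()
res = simulate(params, disc)
blood = pk_metrics(volume_average(res, "blood"), res.times, disc.t_end)
pp = percent_protected(res.dp_stroma, params.EC50)
pdm = pd_metrics(pp, res.times)

cohort = run_cohort(build_variation_grid(), params, disc)
test = sample_cases(40, seed=0)
maps = train_metric_maps(cohort, test_dataset=test)
for name, (net, report) in maps.items():
    print(name, report.slope, report.intercept, report.r2)
```
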