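# ddikit — diagnostic diversity and rare-disease incidence vs travel time

`ddikit` studies a health-services question: **do regions far from a tertiary
referral hospital receive less thorough diagnostic work-up?** It measures the
breadth of discharge coding in each region with a Shannon-entropy–based
**diagnostic diversity index (DDI)**, models how DDI decays with travel time
to the nearest tertiary center, and tests whether the recorded incidence of
rare-disease groups declines with the same travel time. A calibrated
synthetic-registry generator makes every analysis reproducible end to end
without access to confidential hospital data.

The intended audience is health-services and rare-disease epidemiology
researchers, and methodologists interested in entropy-based coding-quality
indicators.

## The model in brief

For a region whose pooled discharge codes have frequencies `p_1 … p_K`:

```
DDI = H = − Σ_i p_i ln p_i        (nats)
```

DDI versus travel time `t` (minutes) follows a 4-parameter log-logistic decay

```
DDI(t) = DDI_low + (DDI_up − DDI_low) / (1 + exp(τ (t − T_half)))
```

whose onset is summarized by the **tangent threshold** — the point where the
inflection tangent meets the upper asymptote:

```
t* = T_half − 2/τ
```

Rare-disease incidence per region and disease group is modeled with Poisson
regression on travel time with a log-population offset
(`rate ratio per 10 min = exp(10 β1)`), plus indirectly standardized incidence
ratios (SIR). Full details, estimation choices, and generator design are in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate a registry of 120 regions and run the full pipeline (DDI → decay fit
→ rare-disease flagging → incidence models):

```bash
python - <<'EOF'
from ddikit.config import ScenarioConfig
ScenarioConfig(n_regions=120, pop_median=1500, pop_sigma=0.4,
               hospitalization_rate=0.5, seed=7).to_yaml("quick.yaml")
EOF
ddikit run --config quick.yaml --seed 7 --outdir quickrun --no-plots
```

Output (about 5 seconds):

```
ddikit run report
=================
cases: 99315  regions: 120  distinct codes: 1853
diagnoses per case: median 3.0 (IQR 1.0-5.0)
rare-disease cases: 4% of all cases

DDI decay (4-parameter log-logistic):
  DDI_low=3.996  DDI_up=6.583  tau=0.1019/min  T_half=41.8 min
  tangent threshold t* = 22.2 min

incidence: 32 of 35 groups significant
```

The output directory contains the simulated tables (`cases.csv`,
`regions.csv`, `mapping.csv`), intermediates (`region_ddi.csv`,
`decay_fit.json`, `group_region_counts.csv`, `sir.csv`, `group_fits.csv`), the
machine-readable `report.json`, and — without `--no-plots` — the decay figure
with its tangent-threshold marker plus the underlying CSV data.

At the full default study scale (705 regions, ~3 million cases,
`ddikit run --seed 42 --outdir out`, ~3 minutes) the generating curve
(`DDI_low = 4.0`, `DDI_up = 6.9`, `τ = 0.1`, `T_half = 41` ⇒ `t* = 21` min) is
recovered closely:

```
ddikit run report
=================
cases: 2959646  regions: 705  distinct codes: 2000
diagnoses per case: median 3.0 (IQR 1.0-5.0)
rare-disease cases: 3% of all cases

DDI decay (4-parameter log-logistic):
  DDI_low=4.021  DDI_up=6.813  tau=0.1003/min  T_half=41.1 min
  tangent threshold t* = 21.2 min

incidence: 33 of 35 groups significant
```

(33 of 35 is exact here: two groups are generated with a zero travel-time
slope and are correctly not flagged.)

### Python API

```python
from ddikit import (ScenarioConfig, generate_scenario, region_ddi_table,
                    fit_loglogistic)

ds = generate_scenario(ScenarioConfig(seed=42))
ddi = region_ddi_table(ds.cases, ds.regions).merge(ds.regions, on="region_id")
fit = fit_loglogistic(ddi[["travel_time_min", "H"]].to_numpy())
print(fit.params, fit.tangent_threshold)
```

Each pipeline stage is also a standalone subcommand (`simulate`, `validate`,
`ddi`, `fit-decay`, `rd-flag`, `incidence`, `report`) operating on the CSV
files on disk, so a run can be resumed or inspected stage by stage.

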