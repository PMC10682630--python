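# aquarisk

Probabilistic human-health risk assessment of drinking-water
contaminants, built around the Gaza Strip municipal groundwater
network — one of the most stressed drinking-water systems in the world,
where a 115-well monitoring campaign across five governorates found
nitrate, fluoride and salinity well above WHO guideline values.

The package is for environmental-health scientists and water-quality
engineers who have per-contaminant monitoring data (well-level or
summary-level) and want defensible, reproducible exposure and risk
numbers for defined population groups.

## What it computes

Chronic daily intake of chemical *i* through drinking water is
simulated by Monte Carlo as

    Exp_i = C_i · I_w / BW        [mg/kg/day]

with lognormal concentrations `C_i` (moment-matched to a summary
table, or fit to well-level data), uniform daily intake `I_w` and
lognormal body weight `BW` per population scenario (adult male, adult
female, children 1–3 years). Risk per chemical is the hazard quotient

    HQ_i = Exp_i / RfD_i

against the USEPA oral reference dose, plus exceedance probabilities
Pr(Exp > threshold) for the RfD and alternate WHO/EFSA benchmarks.
Around this core: WHO-guideline screening of summary tables, explicit
left-censoring policy (LOD/2 default), a synthetic 115-well generator
for end-to-end validation, and a CLI that reproduces the whole analysis
from the packaged reference tables with zero downloads.

## Worked example

```python
from aquarisk import (lognormal_from_mean_sd, sample_exposure,
                      hazard_quotient, exceedance_probability, ADULT_MALE)

# nitrate across the network: mean 112, SD 74 mg/L (guideline: 50)
no3 = lognormal_from_mean_sd(112, 74)
exp = sample_exposure(no3, ADULT_MALE, n_iter=100_000, seed=1, parameter="NO3")
print(exp.summary())
hq = hazard_quotient(exp, rfd=1.6)
print("HQ P50", round(hq.percentile(50), 2), "Pr(HQ>1)", round(hq.exceedance_fraction, 3))
est = exceedance_probability(exp, 3.7)   # WHO/EFSA acceptable daily intake
print("Pr(exp > 3.7) =", round(est.fraction, 3), "+/-", round(est.se, 4))
```

prints

```
{'mean': 1.76, 'sd': 1.41, 'p50': 1.374, 'p75': 2.231, 'p90': 3.436, 'p95': 4.404, 'p99': 6.93}
HQ P50 0.86 Pr(HQ>1) 0.415
Pr(exp > 3.7) = 0.083 +/- 0.0009
```

Read: the median adult male ingests 1.37 mg nitrate per kg body weight
per day — 86 % of the reference dose — but 41.5 % of simulated
person-days exceed the USEPA RfD of 1.6 mg/kg/day, and 8.3 % exceed
even the laxer WHO/EFSA acceptable daily intake of 3.7 mg/kg/day.
Children aged 1–3 fare far worse: their lower body weight raises median
per-kg intake by ~220 %, pushing the nitrate HQ median to ~2.7.

## Command line

```
aquarisk generate --wells 115 --seed 3 --out wells.csv   # synthetic campaign
aquarisk summarize wells.csv                             # per-parameter stats
aquarisk screen                                          # WHO-guideline flags
aquarisk simulate --scenario adult_male --seed 7 --out exposure.csv
aquarisk report --out results/ --seed 7                  # full bundle
```

`report` emits the summary, screening, per-scenario exposure and HQ
tables, an exceedance report and a provenance log; identical config and
seed reproduce the bundle byte-for-byte.

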