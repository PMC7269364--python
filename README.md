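# muacdose

Growth velocities, energy needs and simplified MUAC-based dosing for
acute-malnutrition feeding-program data.

Children recovering from severe acute malnutrition (SAM, mid-upper arm
circumference MUAC < 115 mm) and moderate acute malnutrition (MAM, MUAC
115 to < 125 mm) are treated in separate outpatient programs —
therapeutic feeding programs (TFP, weekly visits) and supplementary
feeding programs (SFP, two-weekly visits) — with weight-based rations. A
simplified combined protocol would instead dose ready-to-use therapeutic
food (RUTF, one 92 g sachet ≈ 500 kcal) by MUAC band alone. `muacdose`
implements the analysis chain needed to design and stress-test such a
protocol from longitudinal patient-card records, and ships a synthetic
cohort generator so every stage is testable without confidential program
data.

## What it computes

For each between-visit interval of duration *d* days the package forms
interval-normalized growth rates, indexed by the MUAC at the prior visit:

    MUAC velocity          v = ΔMUAC / (d/7)            [mm/week]
    proportional weight gain  g = ΔW·1000 / W_prior / d [g/kg/day]

After usability, plausibility and outcome-eligibility filtering (see
`docs/methods.md`), four analyses follow:

1. **Growth trends** — local polynomial (kernel) smoothing of both rates
   against prior MUAC, OLS slopes of each rate on MUAC, and a
   country-stratified resampled test of whether the two min-max
   normalized trends diverge linearly in MUAC.
2. **Energy needs** — per visit,
   `need = W_prior·82 kcal/kg/day + gain_g/day·5 kcal/g`, i.e. maintenance
   plus the cost of observed tissue deposition.
3. **Dosage levels** — the 95th percentile of needs within 5-mm MUAC
   bands: the smallest dose sufficient for observed growth in 95% of
   visits, with subgroup comparisons by age group, continent, and
   admission MUAC category.
4. **Protocol performance** — coverage of a dosing rule (the proposed
   1000 kcal for MUAC 100–<115 mm and 500 kcal for 115–<125 mm, plus
   weight-based comparators) over 100 country-stratified subsamples of
   visits.

## Worked example

```python
from muacdose import RunConfig, run_pipeline

cfg = RunConfig(rng_seed=7)
report = run_pipeline(cfg, preset="band_anchor", n_per_country=400)
print(report.growth.summary())
print(report.energy.summary())
```

which prints (synthetic cohort of 2000 cards, 11 451 analyzable
intervals):

```
Growth trend analysis
======================================================
observations: 11451
smoother: kernel=epanechnikov, degree=0, bandwidth=1.00 mm
MUAC velocity slope:    -0.0541 mm/week per mm (F p=1.2e-289)
weight gain slope:      -0.0760 g/kg/day per mm (F p=0)
normalized-difference trend over 100 replicates:
  slope mean +0.0002 (range -0.0075 to +0.0061)
  non-significant at level 0.05: 100%

Energy needs analysis
======================================================
visits: 11451  (maintenance 82 kcal/kg/day, tissue cost 5 kcal/g)
95th percentile of need by 5-mm band of prior MUAC:
  [100,105) mm  n=   447      993 kcal/day
  [105,110) mm  n=   979     1032 kcal/day
  [110,115) mm  n=  1824     1088 kcal/day
  [115,120) mm  n=  3294     1108 kcal/day
  [120,125) mm  n=  4907     1168 kcal/day
stratum SAM-associated [100,115): 1063 kcal/day
stratum MAM-associated [115,125): 1143 kcal/day
```

Reading this: MUAC velocity falls by about 0.054 mm/week per mm of MUAC
(children grow slower as they approach recovery), the normalized MUAC and
weight-gain trends are statistically indistinguishable (as they should be
— this generator preset gives them one shape), and a 1000-kcal/day dose
sits near the 95th percentile of energy needs in the SAM-associated MUAC
band of this synthetic cohort. `report.protocol.performance.summary()`
tabulates, per MUAC stratum and subgroup, the median share of needs a
protocol provides and the share of visits whose coverage target it meets.

The same stages are available from the shell:

```sh
muacdose simulate --preset band_anchor --n-per-country 400 --seed 7 --out cards.csv
muacdose qc --in cards.csv --summary attrition.csv
muacdose growth --in cards.csv --curves curves.csv
muacdose energy --in cards.csv --out energy_bands.csv
muacdose protocol --in cards.csv --performance perf.csv --dose-curves dose_curves.csv
muacdose run --preset band_anchor --outdir runs/demo
```

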