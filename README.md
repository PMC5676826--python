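# fraxbuild

Tools for building a country-specific FRAX-style fracture-risk model from
regional fracture-registry data, for epidemiologists and bone-health
researchers working in settings without national fracture registers.

Many countries lack the nationwide fracture surveillance needed to calibrate
a fracture risk calculator, and a large share of fragility fractures never
reaches hospital care at all. `fraxbuild` implements the full analysis chain
used to build such a model from a two-regime regional survey:

- **Case ascertainment** — inclusion/exclusion filtering of registry records
  (fragility fractures in residents aged 50+, excluding pathological and
  high-energy trauma, deduplicating readmissions for the same fracture),
  age/sex/site-specific incidence per 100,000 person-years in 5-year bands,
  direct age standardization, and population-weighted pooling of regions.
- **Under-reporting quantification** — comparing mean annual counts under a
  partial (hospital-only) capture regime against a year with full
  (hospital + primary care) capture: missed fraction
  `1 − mean(partial annual counts) / full-capture count`.
- **Hip-anchored imputation** — incidence for unobserved sites (typically
  clinical spine) imputed as hip incidence × reference site/hip ratio, with
  an adequacy check comparing empirical and reference ratio profiles on a
  common standard population.
- **Competing-risk probability engine** — the 10-year probability that a
  fracture occurs before death, from an annual fracture hazard *h<sub>f</sub>*
  and death hazard *h<sub>d</sub>*:

  P = Σ<sub>t=0..9</sub> S(t) · [h<sub>f</sub>/(h<sub>f</sub>+h<sub>d</sub>)] · (1 − e^(−(h<sub>f</sub>+h<sub>d</sub>))),
  S(t) = e^(−Σ<sub>s&lt;t</sub>(h<sub>f</sub>+h<sub>d</sub>)),

  with hazards evaluated mid-interval and clinical risk factors / BMD
  entering as user-supplied positive multipliers on *h<sub>f</sub>*.
- **Model comparison** — surrogate vs authentic models evaluated on the full
  array of 2⁶ clinical-risk-factor combinations × 8 BMD T-scores (512
  scenarios per age and sex), summarized by Pearson/Spearman correlation,
  continuous piecewise-linear regression with fixed knots, and percentile
  tables with 95% tolerance intervals.
- **Synthetic registry generator** — seeded simulations of the two-region,
  two-regime surveillance design (Gompertz age-increasing incidence,
  configurable capture probabilities per year and care source, injected
  contaminant records with hidden truth labels), so every estimator is
  testable against known parameters.

## Worked example

Under-reporting and sex ratios from annual surveillance counts (hip counts
93 and 106 in two hospital-only years, 177 under full capture; 114 women vs
63 men in the full-capture year):

```python
>>> from fraxbuild import missed_fraction, fm_ratio, site_hip_ratio
>>> est = missed_fraction([93, 106], 177, site="hip")
>>> print(f"{est.missed_fraction:.4f} -> {est.percent:.0f}%")
0.4379 -> 44%
>>> fm_ratio(114, 63)
Ratio(value=1.8095238095238095, rounded=1.8)
>>> site_hip_ratio(56.1, 136.0)          # forearm vs hip, standardized rates
Ratio(value=0.41250000000000003, rounded=0.41)
```

44% of hip-fracture cases were invisible to hospital-only capture; women
sustained 1.8 hip fractures for every one in men; forearm incidence was 0.41
of hip incidence in men.

Ten-year fracture probability under competing mortality, for constant annual
hazards (fracture 1%, death 2%):

```python
>>> from fraxbuild import HazardFunction, ten_year_probability
>>> h = lambda v: HazardFunction(sex="female", ages=(50., 100.), hazards=(v, v))
>>> round(ten_year_probability(h(0.01), h(0.02), age=60), 5)
0.08639
```

(the constant-hazard closed form gives ⅓·(1 − e^(−0.3)) ≈ 0.08639 — fewer
than the naive 1 − e^(−0.1) ≈ 0.09516 because death competes).

The full pipeline — simulate, filter, estimate, impute, build models,
compare — runs from the shell:

```sh
fraxbuild run --out-dir out --seed 1     # writes out/summary.json + artifacts
fraxbuild simulate --out-dir sim --seed 1
fraxbuild incidence --registry sim/registry.csv --population sim/population.csv \
    --standardize-to sim/population.csv --out inc
```

## Limitations

The proprietary FRAX clinical-risk-factor coefficients are not published;
the engine therefore takes relative-risk multipliers as configuration (a
clearly-labelled illustrative set is included so the comparison machinery is
runnable) and makes no claim to reproduce any published absolute probability
table. Reference site/hip ratio tables must likewise be supplied by the
user for real analyses. See `docs/methods.md` for the modelling assumptions
and numerical conventions.
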