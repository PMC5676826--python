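# Methods

This note documents the statistical model behind each stage of the package,
the conventions chosen where the methodology is genuinely open, and what the
synthetic-data generator does and does not emulate.

## Case ascertainment and incidence

A registry record is a candidate fragility-fracture event at one of three
surveyed sites, identified by ICD-10 code (hip S72.0–S72.2, distal forearm
S52.5/S52.6, proximal humerus S42.2). Filtering applies, in any order, the
record-level rules — age ≥ 50, low-energy trauma only, non-pathological,
resident of a study region, ICD/site consistency — and then deduplication:
a later same-person, same-site event within the deduplication window of a
retained event is treated as a readmission for the same fracture; outside
the window it is a genuine repeat fracture and counts as a new event.

*Deduplication window:* 90 days by default, configurable. Surveillance
protocols distinguish readmissions from re-fractures without stating a
numeric window; 90 days comfortably exceeds typical readmission horizons
while rarely swallowing true re-fractures. Ties are resolved
deterministically (events sorted by date, then person id; earliest
retained). Records failing ICD/site consistency are quarantined into the
audit output, never silently dropped or corrected.

Incidence is events / person-years × 100,000 in 5-year bands from age 50
with an open 85+ terminal band (the standard scheme in fracture
epidemiology; configurable). Person-years are mid-period population ×
observation years; per-year population tables are supported but a single
mid-period table is the default, since registries rarely publish more.
Direct age standardization is the reference-population-weighted mean of band
rates. Pooling regions sums counts and person-years cell-wise, which equals
population-size weighting of regional rates.

The under-reporting (missed-fraction) estimator assumes the partial and
full capture regimes observe the same underlying incidence, so the expected
count ratio equals the capture ratio: missed = 1 − mean(partial annual
counts)/full-capture count. A negative estimate (sampling noise or a true
secular increase) is flagged, not clamped. Which calendar year constitutes
full capture is configuration, never inferred from the data.

Reported percentages round half-up to integer per cent; ratios half-up to
one (female/male) or two (site/hip) decimals. Full-precision values are
always retained alongside; rounding exists only at the reporting layer.

## Hip-anchored ratio imputation

Incidence for an unobserved site is imputed per (sex, band) as hip rate ×
reference site/hip ratio. Imputed rates carry no counts. The operation is
linear in the hip table, and ratios recomputed from an imputed table return
the input ratios exactly — both properties are tested.

Band harmonization: a ratio defined on a wider band applies uniformly to
nested narrower bands. The adequacy comparison collapses empirical and
reference ratio profiles onto the finest common band scheme and weights by
the standard population, splitting a coarser standard band's person-years
across nested bands proportionally by width (open bands capped at age 100
for width computations). The comparison is descriptive — one standardized
ratio per sex and site and the absolute difference — with no hypothesis
test, since the ratio-borrowing assumption is a modelling judgement rather
than a testable null at these sample sizes.

The shipped reference ratio table (`illustrative_reference_ratios`) is a
clearly-labelled synthetic stand-in, flat in age: its forearm and humerus
values equal the standardized collapses commonly quoted for a Northern
European reference population, its clinical-spine values are plausible
round numbers. Authoritative per-band values must be supplied for any real
analysis.

## Competing-risk probability engine

Annual fracture hazards come from incidence tables as rate/100,000 anchored
at band midpoints (open terminal band treated as ending at 100), linearly
interpolated between midpoints, constant beyond the outer midpoints. Death
hazards come from a per-age life table evaluated the same way.

The 10-year probability discretizes time into 1-year intervals, evaluates
both hazards at the interval midpoint, and accumulates

P = Σ S(t) · h̃f/(h̃f+hd) · (1 − e^(−(h̃f+hd)Δ)),  S(t) = e^(−Σ_{s<t}(h̃f+hd)Δ)

with h̃f = rr·hf. The step size is exposed; halving it changes results by
well under 10⁻³ on realistic hazards (tested), and for constant hazards the
sum telescopes to the exact closed form hf/(hf+hd)·(1 − e^(−10(hf+hd))),
which the tests verify to machine precision. Intervals where both hazards
vanish contribute nothing. Probability is strictly increasing in the
fracture multiplier and non-increasing in a death-hazard shift; no
monotonicity in age is asserted, since rising competing mortality can
reverse it.

The major-osteoporotic-fracture (MOF) hazard is the sum of the four site
hazards (hip, clinical spine, forearm, humerus), a first-event
approximation that ignores the small double-count of same-person multi-site
events; sites without direct hazards resolve through the site/hip ratio
table. Clinical risk factors and BMD enter as a log-linear multiplier
specification: per-factor relative hazards per outcome, plus a relative
hazard per SD of femoral-neck T-score below zero. The baseline profile maps
to 1.0 by construction. No fitted coefficient set ships with the package —
consortium-fitted coefficients are proprietary — so all multipliers are
user configuration; `illustrative_multipliers()` provides a plausible,
clearly-labelled set (factor RRs 1.2–2.0, BMD gradients 1.5/SD for MOF and
2.0/SD for hip) purely so the machinery runs end to end. Risk factors do
not modify the death hazard by default; optional death multipliers are
supported.

## Model comparison

The comparison evaluates two models on an enumerated array — not a
population sample — of all 2⁶ risk-factor combinations × 8 T-scores (0 to
−3.5 in 0.5 SD steps) at BMI 25, per age (50, 60, 70, 80) and sex, in a
deterministic order (CRF bit-pattern major, T-score minor). Per cell it
reports Pearson and Spearman correlation, a continuous piecewise-linear
regression of authentic on surrogate probabilities (truncated-power basis
{1, x, (x−k₁)₊, (x−k₂)₊}, fitted by OLS), and a percentile table at the
10th/50th/90th percentiles of the surrogate distribution (linear
interpolation between order statistics) giving the authentic fitted value
with a 95% tolerance interval. Knots sit on the surrogate axis in
probability per cent — 10 and 30 for MOF, 5 and 20 for hip, reflecting the
outcomes' different probability ranges — and a knot outside the data range,
or one leaving a segment with fewer than two points, collapses the model to
fewer segments with an explicit warning rather than failing.

"95% tolerance interval" admits several conventions; the implementation
uses a normal-theory two-sided interval for 95% content of the predictive
distribution at the evaluation point — Wald form, fitted ± 1.96·s — with an
exact-content option that inflates s by √(ν/χ²₀.₀₅,ν). The choice is
isolated in one function so users can swap conventions. Exact fits give
zero-width intervals.

Rank-order preservation is read from the Spearman coefficient. Note a
floating-point subtlety: scaling can merge probabilities one ulp apart into
ties, so a strictly monotone transform of one model preserves Spearman's
rho only to ~10⁻⁵ rather than exactly; tests assert at that resolution.

## Synthetic registry generator

The generator emulates the study design the estimators assume: two regions
(total populations 284,574 and 52,252; combined 50+ populations 45,871 men
and 55,838 women, apportioned across 5-year bands by a fixed post-50 age
structure using largest-remainder rounding), three survey years with
hospital-only capture in the first two and full capture in the third, and
Gompertz (exponentially age-increasing) site- and sex-specific incidence
and mortality.

Events are Poisson per (region, sex, band, year, site) at the band-midpoint
rate — recurrence allowed, since a later same-site fracture is a new event —
with ages uniform within band (terminal band truncated at 100). Each case
is hospital-reachable with probability 0.54 per site (so 46% of cases are
invisible to hospital-only capture — the primary-care-only share is not
separately identifiable from a two-regime design and is exposed as a free
parameter); care sources are drawn within the reachability group, and a
case enters the registry with the year- and source-specific capture
probability. Contaminant records — high-energy (5%), pathological (2%),
non-resident (3%), under-age (2%) and duplicate admissions (2% of true
cases) — are injected and flagged in a hidden truth column so filter tests
have ground truth. The under-age and duplicate rates are additions beyond
the three basic contamination knobs, needed to exercise the age and
deduplication rules.

Default incidence targets the observed 2013 crude 50+ rates (hip 201/136,
forearm 176.4/56.1, humerus 86.0/39.2 per 100,000 for women/men): the
Gompertz level at age 50 is solved so the population-weighted expected rate
equals the target given the chosen slope (0.105/0.09 per year for hip in
women/men, shallower for forearm and humerus) and the default age
structure. Mortality defaults (level 0.003/0.006 at 50, slope 0.10/0.09 for
women/men) give a life expectancy consistent with a middle-income setting.
All randomness flows from one seed through a fixed stream-splitting order
(events, attributes, capture, contamination), giving bit-identical
registries for identical seeds.

What the generator does *not* emulate: longitudinal follow-up of
individuals (no death-censoring of subsequent fractures within a year),
BMD distributions, seasonality, secular trends, or urban/rural structure.
Tests passing on synthetic data therefore validate estimator correctness
under the stated sampling model, not robustness to those real-world
features.

## Problem sizes and determinism

The parameter-recovery study runs 200 seeded replicates of the full-scale
default conditions (~100,000 persons 50+, ~900 registry records per
replicate), checking that the mean estimated missed fraction is within 3
Monte-Carlo standard errors of 0.46 and that estimated incidence is
unbiased: each of the six aggregate (sex, site) crude rates within 2 SE of
its calibrated target, and ≥ 90% of the 48 (sex, site, band) cells within
2 SE — a simultaneous per-cell 2-SE requirement would fail by chance for an
unbiased estimator (expected coverage ~95% per cell). The acceptance script
uses 60 replicates for its recovery statistics. Everything downstream of a
seed is deterministic; pipeline summaries are byte-identical across reruns
with the same configuration.
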