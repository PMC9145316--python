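# Methods

`mixtox` implements a tiered risk assessment for combined dietary exposure to
co-occurring contaminants (the motivating application is mycotoxins measured
in total diet studies). This note records the models, the defaults and why,
the numerical choices, and what the synthetic data do and do not represent.

## Hazard characterisation

Each compound in an assessment group carries a toxicological reference value
(TRV, µg/kg bw/d). When the group corresponds to the compound's critical
effect and a health-based guidance value (HBGV, e.g. a TDI) exists, the HBGV
is adopted verbatim. Otherwise the TRV is derived as

    TRV = RP / ∏ AF

where RP is the reference point (NOAEL, LOEL, BMDL05 or BMDL10) and the
assessment factors follow the EFSA-convention scheme: interspecies 10
(omitted for human studies), intraspecies 10, duration 2 for
subchronic-to-chronic extrapolation and 10 for a non-chronic clinical study,
3 for LOEL-to-NOAEL, plus opt-in extra factors (e.g. a 1.5 data-limitation
factor, which the packaged white-blood-cell record for nivalenol deliberately
omits so that the endpoint-specific TRV of 1.75 µg/kg bw/d is reproduced
rather than the HBGV that includes the 1.5).

Internal TRVs keep full precision; only the `reported` accessor rounds, to
two significant figures. Combined-risk ratios are therefore computed from
unrounded values and rounded once for display.

Read-across is explicit: fumonisins B2 and B3 receive copies of the FB1
record, and T2 and HT2 toxin are assessed as a single compound record
(`T2HT2`) whose two exposure components are summed per individual before any
risk calculation, reflecting their group HBGV.

The packaged reference-point table resolves one printed ambiguity: the
fumonisin kidney record lists two candidate NOAELs (250 and 200 µg/kg bw/d);
the table stores 200, the value consistent with the adopted TDI of
2 µg/kg bw/d under the default factor of 100.

## Exposure

Long-term exposure uses the observed individual mean (OIM): per individual,
daily intakes (amount of food × concentration in the linked composite
samples, through a food-conversion table with proportional mapping) are
summed within days, averaged over the individual's survey days and divided
by body weight. "Averaged over days" is interpreted as *survey* days, not
consumption days; the two coincide for daily consumers and the survey-day
reading keeps the estimator an unbiased mean of daily intake. Units are
fixed per schema (g, µg/kg, kg) with a single explicit 10⁻³ g→kg factor.

Left-censored concentrations are resolved per scenario: lower bound (LB)
substitutes 0, medium bound (MB) half the limit, upper bound (UB) the limit.
The limit is the LOQ when the record is flagged detected-but-not-quantified
(both LOD and LOQ on record) and the LOD otherwise; the flag makes the
"LOD or LOQ" choice explicit per record. LB ≤ MB ≤ UB holds pointwise by
construction. LB and UB are always computed; MB on demand.

Percentiles are empirical quantiles with linear interpolation between order
statistics. Uncertainty comes from a bootstrap that resamples *individuals*
with replacement (B = 100 by default, seed mandatory); the reported estimate
is the median of the bootstrap replicates plus a central 95% interval.
Resampling only individuals — not concentration values — is a deliberate
one-dimensional design; it propagates consumption-survey sampling error but
not concentration sampling error, so the uncertainty intervals are lower
bounds on the total sampling uncertainty.

## Mixture risk

All combination methods assume dose addition; interactions are out of scope.

* **Percentile summation** — hazard index (HI = Σ exposure/HBGV) and the
  modified reference point index (mRPI = Σ RPQ, with RPQ = exposure·AF/RP =
  exposure/TRV) summed at a common percentile and scenario. The HI tier can
  be skipped when HBGVs are incomplete.
* **Individual-level combination** — exposures are scaled to
  reference-compound equivalents and summed within individuals before taking
  percentiles. With TRV-ratio scaling (factor TRV_ref/TRV_i) the resulting
  risk quotient is algebraically independent of the reference compound
  (it reduces to Σ E_i/TRV_i); with relative potency factors the choice of
  reference matters, and the ratio of metrics under two references equals
  RPF · TRV_alt/TRV_ref at every percentile.

For identically ranked (comonotonic) per-compound exposures the quantile of
the sum equals the sum of quantiles, so the two mRPI variants coincide; with
independent exposures the summed-percentile variant tends to overstate the
high-percentile combined risk. The package asserts the latter as a
stochastic tendency (≥ 90% of seeded replicates at P95), not a theorem.

The tier flow evaluates organ-level groups first; a group proceeds to the
phenomenon tier only if some combined metric exceeds 1 (strictly, on the
unrounded value), and to the RPF tier only if a phenomenon-level concern
remains and a common-endpoint dose-response pair exists. Groups that cannot
be refined are reported as such rather than silently dropped.

## Dose-response / benchmark dose

Inputs are dose-group summaries (dose, arithmetic mean, SD or SEM, n) for a
continuous endpoint. SEMs are converted to SDs (sd = sem·√n). Responses are
assumed lognormal within groups; arithmetic summaries are converted exactly
to log-scale moments (σ²_log = ln(1+CV²), µ_log = ln(mean) − σ²_log/2) and
the likelihood is the normal likelihood of the group log-means and
log-variances with a shared residual variance.

The model set is exponential and Hill, each in 3- and 4-parameter form
(median(d) = a·h(b·d; c, g)), plus null and full models for goodness of
fit. Background `a` and residual variance are profiled out in closed form,
so the numerical search (Nelder–Mead, ≥ 10 log-spaced potency starts,
tolerance 1e-9 on the profiled objective) runs over 2–3 shape parameters.
The steepness g is bounded in [1, 8] to avoid infinite slope at dose 0.

The BMD at benchmark response BMR solves median(BMD) = median(0)·(1 − BMR)
for a decreasing endpoint (1 + BMR for increasing), in closed form through
the shared argument u = b·d. A BMD beyond ten times the highest tested dose
(or an asymptote that never reaches the BMR) is flagged unbounded.

Model-averaged confidence bounds use Akaike weights and a seeded parametric
bootstrap: each replicate draws a family by weight, simulates group
summaries from that family's fit, refits and records the BMD; the reported
BMD is the bootstrap median and BMDL/BMDU the 5th/95th percentiles (a
two-sided 90% interval), so BMDL ≤ BMD ≤ BMDU by construction.

The simultaneous fit constrains curves to be parallel on log dose: shared
c, g and residual variance, per-compound background and potency. The
relative potency RPF_i = BMD_ref/BMD_i = b_i/b_ref is then exactly the same
at every BMR. A parallelism check compares the joint fit against fully
separate fits; if the joint model is worse by more than 2 AIC units per
parameter saved, the fit is flagged (RPFs are still reported with the
flag). The reference compound is chosen as the one with the smallest
BMDU/BMDL ratio (the interval-width criterion), ties broken
lexicographically. HT2 inherits T2's RPF without fitting, mirroring their
shared guidance value.

## Synthetic data

All generators draw from one root seed through named substreams
(survey/concentration/dose-response), so components regenerate independently
and deterministically.

* Surveys: lognormal body weights (toddler default, median 11.5 kg) and
  amounts, Bernoulli consumption per food per day, two survey days.
* Concentrations: Bernoulli occurrence then lognormal levels; values below
  LOD are emitted censored with the LOD only, values between LOD and LOQ
  censored with both limits. An optional shared latent normal couples
  compounds within a sample (rank correlation 1 gives the comonotonic
  fixture).
* Dose-response: group summaries drawn around true curves. Non-reference
  compounds follow the reference curve with doses divided by their true RPF
  (parallel curves). By default compounds with equally sized grids *share*
  the group-level noise realisation — the scaled dataset is the reference
  dataset translated along log dose — which is what makes potency-ratio
  recovery a sharp (±5%) test; independent noise is available and is used
  for single-compound BMD recovery and coverage experiments.

The white-blood-cell fixture (`synthetic_wbc_datasets`) is a synthetic
stand-in for a pair of 90-day rat datasets: parallel exponential curves with
a true potency ratio of 140, the weaker compound reaching a 10% median
decrease near 1400 µg/kg bw/d and the stronger near 10 µg/kg bw/d, n = 10
per group, residual log-scale SD 0.15 (a typical white-blood-cell CV), one
dataset reported as SD and the other as SEM. It exercises the SD→SEM
alignment and the simultaneous fit; it is simulated, not measured, data.

Problem sizes used by the test-suite experiments, chosen as standard
designs: 150 individuals × 2 days for survey fixtures; 5 dose groups with
n = 10 (single-sex) or n = 20 (two-sex haematology, used for the BMD
recovery experiment) per group; bootstrap sizes 100–200 in tests (library
default 1000 for model averaging); 100 seeded replicates for interval
coverage; 200 seeded replicates for the percentile-summation tendency.

What passing these tests does *not* show: the generators use parametric
(lognormal/Bernoulli) structure without seasonality, brand effects,
food-processing factors, unit-to-unit variability or usual-intake
(between/within-person) modelling, so agreement on synthetic data does not
certify behaviour on real survey data with those features. Usual-intake
models (e.g. LNN) are deliberately out of scope.

## Known limitations

* The bootstrap ignores concentration sampling uncertainty (see above).
* The OIM overestimates the upper tail of *usual* (long-term) exposure when
  within-person variance is large.
* Quantal endpoints, Bayesian model averaging, and covariates other than
  compound are not supported in the BMD engine.
* Genotoxic/carcinogenic compounds are rejected from assessment groups; the
  margin-of-exposure approach they require is not implemented.
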