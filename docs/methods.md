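# Methods

## Demand model

The package estimates annual emergency-department (ED) visits arriving by
ambulance per neighborhood *i* and period *j* (day/night) as

    need_ij = P_ij · ε_j · λ · δ_i,

summed over neighborhoods and periods for the regional total. The model
assumes (a) the per-capita ED-visit rate λ is uniform over the region,
(b) emergencies split between day and night with probabilities ε_j that do
not vary by neighborhood, (c) patients are independent, so per-neighborhood
ambulance counts are binomial, and (d) commuting only shifts people between
neighborhoods between the two periods, leaving the regional day total equal
to the night total plus the net commuter inflow. δ is estimated city-wide;
the demand routines nevertheless accept a per-neighborhood δ mapping for
users who have area-level rates.

The ambulance total is converted into total emergency-care need by dividing
by the pooled survey usage rate (default 0.093): if only 9.3% of ED
attendees arrive by ambulance, each ambulance-borne visit stands for
1/0.093 visits overall. The conversion always uses the pooled rate, not the
method-specific δ, because the pooled rate is the survey's direct estimate
of the ambulance share among all ED attendees, whereas the naïve-family δs
average neighborhood proportions and answer a different question.

## Parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| base population | 10,500,000 | persons | mid-2019 official nighttime estimate for the mainland city |
| net commuter inflow | 1,100,000 | persons | official 2019 commuting statistics; 524 k Central, 418 k South, remainder split 70/60/28 k East/West/North |
| day window | [06:00, 18:00) | — | half-open so boundary minutes are counted once |
| ε (day, night) | estimated | probability | from surveyed call times; the reference survey gives 1228/736 → (0.625, 0.375) |
| λ scenarios | q1/median/q3 × 86 ÷ population | visits/person·yr | hospital-sample quartiles scaled to the 86 ED-equipped general hospitals |
| survey size | 1,964 | patients | size of the reference arrival survey |
| true ambulance rate (generator) | 0.093 | probability | the pooled usage rate observed in the reference survey |
| day share (generator) | 0.625 | probability | observed daytime call share |
| usage rate (conversion) | 0.093 | probability | pooled 183/1964 |
| bootstrap replicates | 10,000 | — | standard choice; Monte Carlo SE of the mean ≈ sd/100 |
| CI multiplier | 1.96 | — | normal-approximation 95% interval, justified by the CLT across replicate means |

λ is carried unrounded by default; `use_rounded_rates=True` switches the
demand arithmetic to the two-decimal label values (0.10/0.20/0.29 for the
reference sample), which is the convention printed reports use. Reported
rates follow the two-decimal convention even though one-decimal rounding is
sometimes quoted; the two-decimal values are what the operative tables use.

## Rate estimators

*Naïve*: unweighted mean of per-neighborhood proportions; every surveyed
neighborhood counts equally. *Weighted naïve*: weights each proportion by
the neighborhood's daytime-population share — sample-size weights would
merely reproduce the pooled rate, while population weights answer "what
rate does the average resident face". *Simulation*: a parametric binomial
bootstrap; replicate r redraws each neighborhood's count from
Binomial(n_i, p̂_i) and records the mean of resampled proportions. The
estimator is the mean of replicate means with CI
delta ± 1.96·sd/√R. The bootstrap is mean-unbiased for the naïve value, so
on synthetic data the simulation and naïve estimates agree to Monte Carlo
error; with real survey counts the two can differ, and the one-sample
two-sided t-test (`compare_to_reference`) quantifies the discrepancy
against each naïve value separately. Zero-variance replicate distributions
raise a dedicated error rather than returning NaN.

Neighborhoods with no survey respondents are excluded from δ estimation;
in the demand tables they receive the city-level δ of the chosen method,
which is how single-aggregate-rate reports handle them.

## Synthetic-data generator

The generator emulates the structure the estimators assume, not any real
microdata:

- **Registry.** Municipality nighttime totals follow fixed census-scale
  weights; within a municipality, district shares are Dirichlet with
  concentration proportional to neighborhood count, and neighborhood shares
  within a district are symmetric Dirichlet (concentration 50, giving ~14%
  coefficient of variation — areas are comparable, as aggregate reports
  describe). Largest-remainder apportionment converts shares to integers,
  so population totals are conserved exactly and every area is strictly
  positive. Daytime populations add the municipality inflow proportionally
  to nighttime population, again with exact integer conservation.
- **Survey.** Patients are assigned to neighborhoods proportionally to
  daytime population (ED attendance scales with exposed population), with
  Bernoulli day-period and ambulance flags. The ambulance rate may be a
  scalar or per-neighborhood mapping.
- **Hospital volumes.** Log-normal (meanlog log 20,000, sdlog 1.2), rounded
  to positive integers — right-skewed positive counts of the magnitude seen
  in the reference sample. `reference_hospital_volumes()` instead returns a
  fixed synthetic 10-value sample constructed so its five-number summary
  and total match the published hospital-sample summary exactly (the raw
  volumes were never published); use it whenever the published quartiles
  are the intended input.

What the generator does **not** emulate: spatial correlation between
neighboring areas, transport modes other than ambulance/other, seasonality
of arrivals, or any systematic association between neighborhood size and
ambulance use. Consequently the generator's naïve and pooled rates coincide
in expectation, whereas real surveys can show a naïve rate well below the
pooled rate when larger neighborhoods use ambulances more. Passing tests
therefore demonstrate that the estimation machinery is correct and
internally consistent, not that real-city rates equal 9.3%.

## Numerical choices

- Quantiles use linear interpolation between order statistics (for even n
  the median is the mean of the two central values); this is the convention
  the published summary totals are consistent with.
- Report integers are produced by half-up rounding of aggregates only; the
  reported total is the sum of the two reported period entries, so the
  printed day + night = total identity holds by construction. Per-row
  values are never rounded before summation.
- The reported emergency-care total converts the *reported* ambulance total
  (rounded / usage rate, then half-up), mirroring printed-table arithmetic;
  exact unrounded values are carried alongside in `*_exact` columns.
- Largest-remainder allocation breaks ties by stable sort order,
  deterministic for a given weight vector; negative totals (net outflows)
  are allocated symmetrically, and an outflow exceeding an area's
  population is an error.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  (template, config, seed) gives byte-identical tables.

## Problem sizes

Default runs use the full 261-neighborhood city, 1,964-patient surveys,
and 10,000 bootstrap replicates; property tests that need many independent
replicates (CI coverage, distributional recovery) use 200 replicates of
smaller configurations, which is enough to bound coverage within the
±5-percentage-point band being asserted.

## Limitations

- δ is estimated city-wide; genuine neighborhood heterogeneity beyond
  binomial sampling noise is not modelled.
- The λ scenarios inherit the purposive 10-hospital sample's
  representativeness; the quartile-scaling step assumes the sampled
  hospitals' volumes are typical of all 86 ED-equipped hospitals.
- No geography: travel times, ambulance posts, and fleet sizing are out of
  scope; outputs are annual expected volumes, not operational capacity
  plans.
- Estimates cannot be validated against routinely collected EMS data,
  because none exist for the study setting — that absence is the problem
  the method is designed around.
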