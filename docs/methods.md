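# Methods

## Time integration and its conventions

The annual (or seasonal) value of a station is the time-weighted mean
`Σ Xᵢ·wᵢ / Σ wᵢ` of its irregular series, with weights defined by midpoint
splitting: interior sample `i` owns `(t_{i+1} − t_{i−1})/2`, and the period
extends half a gap beyond the first and last samples, so the end weights are
the full adjacent gaps. This end convention is deliberate: it makes an
equally spaced series reproduce its plain arithmetic mean exactly, which is
what lets weekly pilot data, thinned schedules and the frequency analysis
share one scale. A single-sample series gets unit weight. The integrated
mean is bounded by the sample extremes and invariant to shifting or
rescaling the time axis; the test suite checks it against an independent
piecewise integration of the midpoint step function to 1e−10 relative.

Stations with fewer than `min_occasions_per_station` (default 4) retained
occasions are excluded from integration with a logged warning rather than
interpolated; the package deliberately does no gap-filling, seasonal
decomposition or autocorrelation modelling — time integration is the whole
treatment.

## Variability statistics

All CVs are `100·SD/mean` with the sample SD (denominator n−1). The
between-station CV of integrated means drives the design calculus; the
variability tables additionally report, for context, one CV across stations
per occasion ("over time", the spatial spread on a single day) and one CV
across occasions per station ("over stations", the temporal spread of a
fixed station), each summarized by mean and range, on raw and on
natural-log-transformed values. For log tables the grand mean is reported
back-transformed (the geometric mean). Natural log is a convention choice;
log₁₀ would change CV magnitudes on the transformed scale but not any
qualitative ordering. CV is reported as missing when a mean is exactly 0,
never as infinity. Normality of the station integrated means is assessed
with the Shapiro–Wilk test (scipy implementation).

## Cast reduction

Scalar variables are reduced per cast to the arithmetic mean over the
closed depth band [0, 3] m (boundary samples included; the band is
configurable). Light profiles are fitted to `I_d = I₀·e^(−k·d)` by ordinary
least squares of ln(I) on depth; `k` is the negative slope, `I₀` the
exponentiated intercept, and the log-scale R² is reported as fit quality.
Nonpositive irradiance makes the fit impossible and raises; a configurable
detection floor may instead drop dim readings before fitting, and at least
three usable points are required. Fit quality is not used as a filter by
default — a configurable minimum only emits a warning, because silently
dropping poor fits would bias station coverage. The euphotic depth is
`−ln(0.01)/k`.

## Frequency reduction

Thinned schedules keep `n_keep` of `n_total` occasions at indices
`⌊j·n_total/n_keep⌋ + phase`; phase defaults to 0 (keep the first
occasion), since which weekly visits a program would retain is a design
choice, and a phase sweep is available to report sensitivity. Standardized
means (reference = 100%) carry 95% CIs computed across stations with the
Student t quantile at `n_stations − 1` df — across stations, not across
phases, because the stations are the replication unit of the whole design.
The recommended frequency uses a monotone acceptance rule: walking down
from the reference, acceptance stops at the first count outside the ±5%
band, so an isolated lower count that drifts back inside the band does not
qualify. If nothing but the reference passes, the reference count is
returned with a warning.

## Precision and cost calculus

`CI% = t·CV%/√N` with two t conventions: `fixed` uses the constant 2.01
(the two-sided 5% t multiplier at the ~50 df of a reasonably sized pilot;
keeping it fixed makes precision curves depend on N only through √N and
keeps budget inversions algebraic), and `exact_df` uses the 97.5th t
quantile at `⌈N⌉ − 1` df, which requires N ≥ 2. Budget inversions keep
`N_space` fractional — cost–precision curves are smooth — and integer
station counts are an explicit reporting step (ceiling). The portfolio
budget takes the worst (largest) CV variable, solves for the fractional
`N_space` giving the target CI%, prices it through the cost model, and
rounds to the nearest whole relative unit for reporting while retaining
full precision internally; achieved CI% for every other variable at that
allocation is reported alongside. In `exact_df` continuous mode the t value
depends on N and is resolved by fixed-point iteration from the normal-limit
quantile.

## Power analysis

Inter-annual change detection is modelled as a two-sided one-sample t test
on the station integrated means at significance α (default 0.05): with the
change expressed as δ% of the mean and CV% the percent SD, the standardized
effect is `d = δ%/CV%`, and power at sample size n is
`P(|T′| > t_{1−α/2,n−1})` for `T′` noncentral t with n−1 df and
noncentrality `d·√n`. Two-sided is the package convention; it is also the
variant consistent with all the reference sample sizes the acceptance suite
checks. The minimum-n search scans upward from a normal-approximation
start; power is monotone in n so termination is immediate. Note that the
search floor n = 2 is reached only for very large effects: at d = 10 the
single-df denominator still caps power at 0.73, so the minimum there is 3.
scipy's noncentral-t CDF underflows to NaN deep in the lower tail at large
noncentrality; that term is below machine epsilon and is guarded to 0.

## Synthetic data generator

The generator emulates a high-latitude coastal pilot season: `n_stations`
stations sharing an occasion grid (default 24 visits spread evenly over
days 155–338, i.e. approximately weekly from early June to early December),
each visit a cast over 0–3 m at half-meter steps. A scalar variable is

```
value(s, t, z) = trend(t) · (1 + g·z) · F_s · F_{s,t}
```

with `trend` one of five seasonal shapes (linear drift, rise-then-fall peak,
exponential decay, baseline-plus-pulse, irregular sum of sinusoids), `g` a
linear vertical gradient, `F_s = 1 + e_s` a Gaussian station effect with
the configured between-station CV, and `F_{s,t}` occasion noise with the
configured within-station CV and AR(1) correlation (default ρ = 0.3) on the
underlying Gaussian. Occasion noise is mean-1 *lognormal* with matched CV
rather than `1 + ε` Gaussian, so generated concentrations and irradiances
are strictly positive by construction at any noise level; at the CV values
in play the two parameterizations are otherwise nearly indistinguishable.
Light is generated as `I₀(t)·e^(−k_{s,t}·z)` with the station's attenuation
coefficient carrying the between-station spread, so the fit-then-integrate
path is exercised end to end. A single seed expands into independent
per-variable substreams (`SeedSequence.spawn`), making datasets reproducible
bit for bit and insensitive to adding variables.

The default six-variable world uses between-station CVs of 6.2 (salinity),
1.0 (temperature), 0.55 (oxygen), 10.8 (CDOM), 4.8 (chlorophyll *a*) and
12.4% (PAR extinction, mean k = 0.77 m⁻¹) — the magnitudes typical of
time-integrated station means in a heterogeneous coastal area — with
occasion noise several times larger (4–40%), the regime in which pooling
over time pays off. The CDOM pulse sits in days 220–245.

What the generator does *not* emulate: spatial correlation between stations
(stations are exchangeable replicates), weather/tide forcing, sensor drift
or biofouling, detection limits, and missing visits. Passing tests
therefore demonstrate the statistical machinery under exchangeable-station
conditions, not robustness to spatially structured field data.

### CV propagation, exactly

One statement needs care: the pipeline-estimated between-station CV of
integrated means is *not* the configured `station_effect_cv` alone. The
integrated mean of a station retains a residual of its occasion noise with
relative SD `noise_cv·√(Σw′²)` (w′ the normalized trend-weighted interval
weights — about `noise_cv/√24` for 24 occasions and ρ = 0), which adds in
quadrature. At 6% station spread and 30% occasion noise the estimator
concentrates near `√(6² + 6.1²) ≈ 8.6%` (shrunk ~1.3% by the c4
small-sample bias of the SD), and the test suite asserts exactly this
quadrature value. Recovery of the configured spread to within a percentage
point holds only when `noise_cv/√N_occ ≪ station_effect_cv`; one
acceptance-level check that asserts a tighter recovery at 30% noise fails
for this structural reason, and is retained unmodified as documentation of
the discrepancy. The pooling property itself — integrated-mean CV far below
both per-occasion spatial CV and per-station temporal CV — holds throughout
and is asserted on seeded simulations.

## Problem sizes in the test suite

Simulation-based checks use seeded replicate counts chosen to make the
Monte-Carlo standard error far smaller than the asserted tolerance:
10,000 replicates for rejection-rate vs analytic power (tolerance ±0.02),
300 full-pipeline replicates for the CV-propagation checks (SE ≈ 0.08 pp),
200 for the Shapiro–Wilk behavioural checks, and brute-force power scans
over n = 2..5000 across a grid of 30 effect sizes. The whole suite runs in
about a minute on one CPU.

## Known limitations

- The cost model is linear; stepwise costs (a second ship day once
  `N_space > n`) must be approximated through `A/n`.
- Worst-variable budgeting is the only multi-variable policy; no
  unequal-allocation or stratified designs.
- The frequency analysis compares uniform thinnings only; seasonally
  weighted schedules (more visits in the productive season) can be supplied
  as explicit occasion lists but are not searched.
- `fixed`-mode precision uses t = 2.01 regardless of N, which overstates
  precision slightly for very small station counts; use `exact_df` when
  N is small and honesty about df matters more than curve smoothness.
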