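# monalloc

Cost–precision allocation and power analysis for multi-station environmental
monitoring surveys.

Marine monitoring programs rarely have the statistical power to say whether
this year differed from last year: raw station time series are seasonal,
autocorrelated and non-normal, so the variance feeding any annual comparison
is huge. `monalloc` implements the alternative strategy of *pooling over
time*: each station's season is first collapsed to a single time-integrated
average,

```
x̄_s = Σᵢ Xᵢ·tᵢ / Σᵢ tᵢ
```

where the weight `tᵢ` is the interval owned by sample `i` under midpoint
splitting of the sampling times. The between-station coefficient of
variation of these integrated averages (CV%) is typically several times
smaller than the spatial or temporal CV of the raw data, and the integrated
averages are close to normally distributed (checked with Shapiro–Wilk), so
plain t-based precision and power calculus applies:

- **Precision.** `CI% = t · CV% / √N` — the half-width of the 95%
  confidence interval of the area mean, as a percent of the mean, for `N`
  stations.
- **Cost.** `Cost = N_time · N_space · (A/n + Σmᵢ) + B`, linking the two
  allocation knobs (surveys per year `N_time`, stations per survey
  `N_space`) to ship cost per day `A`, stations per cruise day `n`,
  per-variable analysis costs `mᵢ`, and fixed overhead `B`. Inverting for
  `N_space` at a given budget and substituting into the precision relation
  prices any target CI%.
- **Power.** Detecting a `δ%` inter-annual change of the mean is a
  one-sample t test on the station integrated means with standardized
  effect `d = δ% / CV%`; power follows the noncentral t distribution, and
  `min_n_for_power` returns the smallest station count reaching a target
  power.

Supporting stages cover the rest of a pilot-survey workflow: reduction of
vertical sensor casts to 0–3 m band means and PAR extinction coefficients
(`I_d = I₀·e^(−k·d)`, fitted by log-linear least squares), raw/log
variability tables along both axes of the station × occasion grid, and a
sampling-frequency thinning analysis (24 → 12/8/6/5/4 occasions with a ±5%
acceptance band) that recommends `N_time`. A seeded synthetic-data module
generates full multi-station, multi-depth seasons with known ground truth.

## Worked example

With the six pilot-survey CV% values in `cv.csv`
(salinity 6.21, temperature 0.97, PAR extinction 12.36, oxygen 0.55,
CDOM 10.83, chlorophyll *a* 4.76):

```
$ monalloc power --cv-table cv.csv
variable,delta_percent,cv_percent,effect_d,min_n,power_at_min_n
salinity,5.0,6.21,0.805...,15,0.826
par,5.0,12.36,0.404...,50,0.801
cdom,5.0,10.83,0.461...,39,0.802
chlorophyll,5.0,4.76,1.050...,10,0.840
salinity,10.0,6.21,1.610...,6,0.879
par,10.0,12.36,0.809...,15,0.830
cdom,10.0,10.83,0.923...,12,0.829
chlorophyll,10.0,4.76,2.100...,5,0.932
...
```

Reading: detecting a 5% change in the chlorophyll *a* integrated mean with
power 0.8 (α = 0.05, two-sided) needs 10 stations; a 10% change needs 5.
PAR extinction, the most variable quantity, needs 50 and 15.

```
$ monalloc allocate --cv-table cv.csv --target-ci 20
variable,cv_percent,ci_at_1_station,stations_for_5pct,...
par,12.36,24.84,25,...
cdom,10.83,21.77,19,...
# portfolio budget for CI <= 20%: 28 units (N_space = 1.543)
```

At one station, salinity's precision is `2.01 × 6.21 = 12.48%`; PAR
extinction and CDOM need 25 and 19 stations to reach 5% precision; and
under the default cost constants (A=1, B=20, n=3, Σm=0.1, N_time=12) a
budget of 28 relative units buys ≤ 20% precision for all six variables.

The profile layer works the same way from Python:

```python
>>> from monalloc import LightProfile, fit_extinction, euphotic_depth
>>> fit = fit_extinction(LightProfile("st01", 172, depths, irradiance))
>>> print(f"k = {fit.k:.3f} /m, euphotic depth = {euphotic_depth(fit.k):.2f} m")
k = 0.771 /m, euphotic depth = 5.97 m
```

A full synthetic season (21 stations × 24 occasions × 6 variables) and the
complete report pipeline:

```
$ monalloc simulate --seed 1 --out obs.csv
$ monalloc report --obs obs.csv --out-dir report/
```

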