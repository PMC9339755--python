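# Methods

## Velocity decomposition

Each vertical-profile record carries the bird ground-velocity components
(u, v) [m/s, east/north].  With the local wind (U, V) attached, the triangle
of velocities gives ground speed `Vg = hypot(u, v)`, airspeed
`Va = hypot(u − U, v − V)` and wind speed `W = hypot(U, V)`.  The
decomposition is purely local: no smoothing or pooling happens before the
subtraction, so `|Vg − W| ≤ Va ≤ Vg + W` holds record by record.

Wind profit is the signed scalar projection of the wind vector on the
preferred migration direction α, `wp = U·sin α + V·cos α`, with α = 45°
(toward NE) in spring and 225° (toward SW) in autumn.  One compass
convention is used throughout: degrees clockwise from geographic north,
"toward" semantics for bird track and wind alike, so `bearing(U, V)` is
directly comparable with the bird's track bearing.  Seasons switch at a
configurable month-day cutoff, default July 15, with the cutoff day itself
assigned to autumn (strictly-before = spring); α switches at the same
cutoff.

## Wind attachment

Wind grids are native in pressure coordinates.  A query altitude z is mapped
to pressure with the International Standard Atmosphere troposphere branch,

    z = (T₀/L) · (1 − (p/p₀)^(R·L/(g·M))),
    p₀ = 1013.25 hPa, T₀ = 288.15 K, L = 0.0065 K/m,

and its exact closed-form inverse (round trip < 1e−6 hPa).  Wind is then
interpolated multilinearly over the 2⁴ surrounding nodes in
(time, lat, lon, pressure).  The interpolation is exact at nodes and for any
field multilinear in the axes, and every result is a convex combination of
node values.  There is no extrapolation: point queries outside the grid
raise, and bulk attachment drops out-of-coverage records into a reported
tally (input count = attached + dropped, always).  Time enters as exact UTC
instants — no nearest-hour snapping.

ISA was chosen over geopotential-height mapping because the input contract
carries no geopotential field; the choice is documented here precisely
because radar altitudes and reanalysis levels can be matched several ways.

## Weighted statistics

Averages over birds weight each record by its bird density ρ ("experienced"
statistics); unweighted averages over the same records describe the
"available" conditions.  Weighted SDs use the population form
`√(Σw(x−m)²/Σw)` — weights are densities, not replicate counts.  Vectorial
averages are component-wise weighted means; their magnitude is bounded above
by the weighted mean of the individual magnitudes, with equality only for
perfectly aligned directions, so scattered headings shrink vector averages —
the same mechanism by which single-volume Doppler speeds underestimate
individual birds.

## Aggregation scales

* **Nightly**: records are assigned to nights by solar elevation < 0° at the
  radar (standard NOAA low-precision solar position, accurate to a few
  tenths of a degree); a night carries the civil date of its sunset, so
  23:00 and 02:00 share one id.  Daytime records are excluded and tallied.
  Nightly means are scalar density-weighted means pooled over all radars and
  altitudes.  Smoothing is a centered 7-night moving average whose window
  shrinks at the edges; missing nights are skipped, never zero-filled.
* **Trends**: nightly mean vs time in months of 30.44 days, weighted least
  squares with nightly total density as precision weights; the 95% CI is the
  WLS t-interval (statsmodels).  On synthetic nightly series whose noise
  variance scales inversely with the weight this interval covers the true
  slope at nominal rate; on real data, where that variance model is only an
  approximation, it should be read as a minimal defensible default.  In an
  exact-fit (noiseless) series the residual variance is zero and the CI
  collapses onto the slope.
* **Spatial**: per (radar, period) density-weighted vectorial averages of
  the ground, air and wind vectors.  The four default periods are
  Feb–Apr, May–Jul, Aug–Oct, Nov–Jan (half-open, config-driven; periods
  must be disjoint).
* **Altitudinal**: per (season, 200-m bin) vectorial and scalar weighted
  means of the three vector fields plus the weighted mean `sd_vvp` and the
  summed density.

Every record lands in exactly one night, one season, one altitude bin and at
most one spatial period.

## Seasonal statistics

`season_summary` reports density-weighted means/SDs per season and pooled,
plus the exceedance probability P(Va_spring > Va_autumn) between the exact
(unbinned) weighted empirical distributions, ties counted ½.  The half-tie
convention makes P(X>Y) + P(Y>X) = 1 identically, so identical distributions
give exactly 0.5.  The implementation sorts the second sample once and reads
its weight CDF at each first-sample value (O((n+m) log) versus the O(n·m)
double sum it equals, which the tests enumerate on small instances).

`worked_ratios` turns seasonal/pooled mean speeds into headline ratios:
percent excess of ground over airspeed `100·(Vg/Va − 1)`, percent wind
speed-up `100·wp/Vg` (pooled and per season), seasonal speed ratios, and
flight hours saved `journey_hours · wp/Vg` on a reference journey
(default 3000 km in 80 h).  Percentages are rounded half-up to integers,
ratios to 2 decimals, hours to integers, so values are comparable at print
precision; all ratio fields are invariant to a common rescaling of speed
units.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
verified:

* **Network**: radar sites uniform in a lat/lon box (defaults 43–55° N,
  −5–15° E, 37 radars — a western-European-scale network).
* **Wind**: seasonal mean vector + linear vertical shear in ISA altitude +
  low-order sinusoids in lat/lon/time + small Gaussian noise, on a
  config-driven grid (default 1° / hourly — coarser horizontally than a
  0.25° reanalysis purely to keep year-long grids small; the interpolation
  code is resolution-agnostic).  Default seasonal means point toward 45° at
  4.6 m/s in spring and toward 225° giving ≈ +1.1 m/s wind profit in
  autumn, so the generator's mean seasonal wind profits sit near 4.6 and
  1.1 m/s.  Default grid levels span 1013.25–500 hPa, slightly wider than a
  1000–550 hPa reanalysis column, so that all 25 default altitude bins
  (100–4900 m) are inside interpolation coverage and the generator can
  evaluate its own truth everywhere; attachment against narrower grids
  still exercises the documented drop rule.
* **Birds**: true airspeed ~ Normal(μ_season, σ) rejected at 0 (defaults
  μ_spring = 8.7, μ_autumn = 8.2, σ = 3 m/s); heading ~ von Mises around the
  seasonal preferred direction (κ = 4 spring, 2 autumn — autumn more
  scattered, as juvenile-heavy passage suggests); ground velocity composed
  *exactly* as air vector + wind, where the wind is obtained from the
  generated grid with the same 4-D interpolator the attachment stage uses.
  Downstream decomposition therefore recovers the true airspeed to machine
  precision, and any discrepancy is a genuine pipeline defect.
* **Behavior**: records exist only while the sun is below the horizon.
  Nightly intensity is `exp(base + slope · w̄p_night)` with w̄p_night the
  generator's own mean wind profit at that radar that night (slope 0.25 by
  default) — a deliberately simple log-linear stand-in for night selection,
  not an empirically fitted model.  Across altitude bins, densities follow a
  softmax of wind profit (inverse temperature 0.3 per m/s).  Densities are
  Gamma-distributed (shape 2) around the intensity mean: positive and
  overdispersed.
* **sd_vvp** is emulated as `c₀ + c₁ · circSD(κ) · μ_season` — any monotone
  function of heading scatter suffices, since the analysis uses it only as a
  scatter proxy.

What the generator does **not** emulate: insect contamination, the
vector-averaging bias of single-volume Doppler retrievals, coastal effects,
species composition shifts, rain gaps and radar outages.  Passing tests
therefore demonstrate that the pipeline's arithmetic and plumbing are
correct under the stated statistical structure, not that real radar data are
free of those biases.

## Numerical and design choices

* Reproducibility: every stochastic routine takes an explicit seed
  (`numpy.random.default_rng`); identical config + seed gives bit-identical
  outputs, including the CLI's CSV files.
* VPTS round trip: floats printed with 17 significant digits and parsed with
  the round-trip parser, so write→read is bit-faithful.
* Degenerate inputs: zero vectors have undefined bearing (error scalar,
  NaN vectorized); all-zero weights are an error, not NaN; nights with zero
  total density are omitted from series; below-3-night seasons refuse a
  trend fit.
* Problem sizes in tests: module tests run ten-night three-radar windows;
  the headline parameter-recovery check uses two two-week windows
  (spring + autumn, 6 radars, 15-min cadence, 15 bins, ≈ 1.4 × 10⁵ records),
  sized so Monte-Carlo error in the weighted seasonal means is well under
  the 0.05 m/s recovery tolerance.

## Known limitations

* The ISA mapping ignores actual atmospheric state; against reanalysis data
  a geopotential-based mapping would be more faithful where available.
* Nightly averages pool all records rather than weighting radars equally;
  radars with heavier passage dominate the network mean.
* The season cutoff is a hard calendar split; late-winter records in
  January of the following year count as "spring" of their own calendar
  year.
* The trend CI's weight model (variance ∝ 1/density) is a convention, not a
  fitted error structure.
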