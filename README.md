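# birdwind

Decompose weather-radar observations of nocturnal bird migration into
airspeed and wind support.

## The problem

Weather radars measure the *ground* velocity of migrating birds — the vector
sum of what the birds do (their air velocity) and what the atmosphere does
(the wind).  Whether birds fly harder in spring than in autumn, higher up
than lower down, or here rather than there can only be judged after the wind
is removed.  `birdwind` does that removal at scale for vertical-profile time
series (VPTS): per radar, per 5-minute timestamp and per 200-m altitude bin,
a bird density ρ [birds/km³], ground-velocity components (u, v) [m/s] and
the radial-velocity standard deviation `sd_vvp`.

Given a gridded wind field (U, V) on (time × lat × lon × pressure level),
the package interpolates wind onto every radar observation (4-D multilinear,
after mapping the bin altitude to pressure with the International Standard
Atmosphere) and applies the triangle of velocities:

    Vg = √(u² + v²)                       ground speed
    Va = √((u − U)² + (v − V)²)           airspeed, computed locally per record
    wp = U·sin α + V·cos α                wind profit toward the preferred
                                          migration direction α
                                          (45° NE spring, 225° SW autumn)

Results are aggregated at four scales — seasonal (spring/autumn split at
July 15), nightly (density-weighted means with 7-night smoothing and
within-season linear trends in m/s per month), spatial (per-radar vectorial
averages by period) and altitudinal (200-m profile) — always distinguishing
the *experienced* wind (density-weighted: the wind birds actually flew in)
from the *available* wind (unweighted: the wind on offer).

A synthetic-data generator produces radar networks, wind grids and bird
profiles with known ground truth (von Mises headings, truncated-Normal
airspeeds, wind-profit-driven night and altitude selection), so the whole
pipeline is verifiable without any external download.

## Worked example

```python
import birdwind as bw
from birdwind.synthetic_data import SimulationConfig

cfg = SimulationConfig(
    n_radars=4, start_date="2018-03-01", end_date="2018-03-15",
    cadence="15min", n_altitude_bins=15,
)
network = bw.make_network(cfg, seed=1)
grid = bw.make_wind_grid(cfg, seed=2)
records, truth = bw.simulate_profiles(network, grid, cfg, seed=3)

kin = bw.decompose(bw.attach_wind(records, grid, network).records)
w = kin["dens"].to_numpy()
for q in ("Vg", "Va", "W", "wp"):
    s = bw.weighted_stats(kin[q].to_numpy(), w)
    print(f"{q}: mean {s.mean:.2f} m/s (SD {s.sd:.2f})")

exposure = bw.experienced_vs_available(kin)
print(f"experienced wind profit: {exposure.experienced_wp.mean:.2f} m/s, "
      f"available: {exposure.available_wp.mean:.2f} m/s")
```

prints

```
Vg: mean 16.24 m/s (SD 3.81)
Va: mean 8.70 m/s (SD 2.99)
W: mean 8.19 m/s (SD 2.36)
wp: mean 8.03 m/s (SD 2.44)
experienced wind profit: 8.03 m/s, available: 6.27 m/s
```

The generator was asked for a spring mean airspeed of 8.70 m/s; the pipeline
recovers exactly that after subtracting the wind it attached, while the
ground speed (16.24 m/s) is inflated by the strong supporting spring wind.
The experienced wind profit exceeds the available one because simulated
birds concentrate on favorable nights and altitudes — the selection
signature the density weighting is designed to expose.

The same analysis runs from the shell on any VPTS + wind-grid + radar
metadata triple:

```sh
birdwind simulate --config config.yml --out sim/
birdwind run --config run.yml --seed 1 --out out/
birdwind report --out out/
```

writing `nightly_series.csv`, `season_summary.csv`, `ratio_report.csv`,
`altitude_profile.csv`, `spatial_summary.csv` and a run log with full
record-conservation tallies.

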