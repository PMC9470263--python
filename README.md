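# preyfield

Quantifying how well a central-place marine forager encounters prey.

Breeding seabirds such as little penguins are constrained to short foraging
trips around a fixed colony, which makes it possible to survey the
three-dimensional prey field inside their entire foraging range with
boat-based acoustics while the birds are being tracked.  `preyfield`
implements the complete analysis that links the two data streams:

1. **Prey field reconstruction** — acoustic samples of mean volume
   backscattering strength S_v (dB re 1 m⁻¹) taken along survey transects are
   mapped to normal scores, a variogram γ(h) with nugget, Gaussian and cubic
   structures is fitted, and the field is reconstructed on a 200 × 200 × 1 m
   grid by ordinary kriging with an anisotropic moving neighbourhood
   (50 km horizontal / 20 m vertical search, 3–10 neighbours, edge
   penalization), then back-transformed to dB.
2. **Track regularization** — GPS fixes are speed-filtered (recursive
   20 m s⁻¹ rule), restricted to single-day trips, and smoothed to exact
   5-minute positions with a continuous-time correlated random walk
   (integrated Ornstein–Uhlenbeck velocity, Kalman MLE, observation SE fixed
   at 5 m).
3. **Behavioural classification and null model** — a two-state hidden Markov
   model with gamma step lengths and von Mises turning angles separates
   *foraging* from *transiting*; the fitted kernel simulates thousands of
   random-but-realistic tracks that avoid land, forming the null ensemble.
4. **Prey-encounter index** — the kriged field is collapsed to 2-D by
   weighting each 1 m depth layer with the year's maximum-dive-depth
   frequencies, in the linear domain s_v = 10^(S_v/10).  Each track scores

   E = Σᵢ s_v(xᵢ, yᵢ) / T  (linear acoustic density per hour of trip),

   and real tracks are compared to the ensemble by drawing equal-sized
   samples of simulated tracks many times: `p_better` is the fraction of
   draws the real mean strictly exceeds the simulated mean, and the anomaly
   ΔE = mean(real) − mean(sim) is summarized over draws.
5. **Space use and condition** — 75% kernel utilization distributions of
   foraging locations (normal-reference bandwidth h = 1.06 σ̂ n^(−1/5)),
   vertical profiles of prey density inside/outside the core range, and
   per-sex body-mass anomaly models (no-intercept year-indicator GLM).

A synthetic-data module generates every input with known ground truth —
seascape and transect design, patchy 3-D prey fields with an inshore hotspot,
two-state tracks observed with dropout and GPS noise, dives, and
sex/year-structured masses — so the full pipeline is testable end to end
without field data.

## Worked example

Run the canonical synthetic experiment: a +12 dB prey hotspot of 5 km radius
is planted 2.5 km offshore, surveyed along nine transects 3.5 km apart, and
reconstructed by kriging; 15 hotspot-seeking foragers are scored against 500
random-movement tracks simulated from an HMM fitted to their own regularized
trajectories.

```python
from preyfield.pipeline import encounter_experiment

rep = encounter_experiment(seed=1, hotspot_amplitude_db=12.0, n_draws=10_000)
print(f"p_better           : {rep['p_better']:.4f}")
print(f"encounter anomaly  : {rep['anomaly_mean']:.3e} +/- {rep['anomaly_se']:.1e} s_v/hr")
print(f"anomaly (dB ratio) : {rep['anomaly_db']:.2f} dB")
print(f"kriging RMSE       : {rep['kriging_rmse_db']:.2f} dB "
      f"(nearest-neighbour baseline {rep['nearest_neighbour_rmse_db']:.2f} dB)")
```

prints

```
p_better           : 1.0000
encounter anomaly  : 2.140e-06 +/- 2.1e-07 s_v/hr
anomaly (dB ratio) : 4.46 dB
kriging RMSE       : 1.95 dB (nearest-neighbour baseline 2.14 dB)
```

The informed foragers beat every one of the 10,000 random draws
(`p_better = 1`): they encounter on average 4.5 dB more linear acoustic
density per hour than random movement through the same reconstructed field,
and the kriged reconstruction is more accurate than a nearest-neighbour
read-off of the transect samples.  Setting `hotspot_amplitude_db=0.0`
(and passing the previous report's `reuse` cache as `_cache` to keep the same
tracks) re-scores the experiment on a hotspot-free field — the negative
control, where the advantage disappears.

## Command line

Every stage is also exposed as a CLI:

```sh
preyfield synth --seed 1 --out bundle/          # synthetic input bundle
preyfield tracks bundle/fixes.csv --out reg.csv # CTCRW regularization
preyfield hmm fit reg.csv --out hmm.json        # two-state HMM
preyfield krige bundle/acoustic.csv --out field.nc
preyfield mass bundle/masses.csv --out mass.csv
preyfield run --fixes ... --dives ... --acoustic ... --masses ... \
    --seascape bundle/seascape.geojson --out run/ --seed 1
```

`preyfield run` writes per-year reports, the kriged fields (NetCDF), the full
anomaly-draw vectors and a provenance manifest; rerunning with the same
config and seed reproduces every stochastic output bit for bit.

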