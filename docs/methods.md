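# Methods

This note documents the models, the parameter choices and their units, the
numerical decisions, and what the synthetic experiments do and do not show.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Prey-field reconstruction (kriging)

Acoustic density is mean volume backscattering strength S_v in dB re 1 m⁻¹, a
log-scale proxy for prey density.  Because dB values cannot be averaged, all
spatial averaging happens either in normal-score space (kriging) or in the
linear domain s_v = 10^(S_v/10) (depth weighting, encounter index).

**Normal scores.** Values map to Gaussian quantiles of the tie-averaged ranks
with plotting position (r − 0.5)/n.  The inverse interpolates linearly between
data quantiles; scores beyond the data range clamp to the data min/max.  The
clamped tails are conservative: kriged extremes can never exceed observed
extremes.  Duplicate coordinates are merged by averaging in the linear domain
before the transform.

**Variogram.** γ(h) = c₀ + Σ structures, with Gaussian
(c(1 − exp(−3h²/a²))) and bounded cubic structures; distances are
h = √(Δx² + Δy² + (r·Δz)²) with the anisotropy ratio r defaulting to
h_radius/v_radius = 50 000/20 = 2500, so one scaled metric serves the
variogram and the neighbourhood search.  The empirical variogram is the
method-of-moments estimate per scaled-distance bin (pair counts reported;
empty bins flagged, never interpolated; pairs subsampled at random above
2 × 10⁶).

The weighted least-squares fit defaults to Cressie's n/γ² weights rather than
raw pair counts.  With raw counts the plateau bins carry 10–50 × the weight
of the short lags, and realization-level fluctuation of the plateau (±10% on
a domain ten ranges wide) systematically buys 30–60% nugget bias; with
Cressie weights the known generating model (c₀ = 0.1, c = 0.9, a = 5 km) is
recovered within ~13% across seeds on a transect-style survey.  Pair-count
weighting remains available (`weighting="npairs"`).  Optimization uses
bounded trust-region least squares with Jacobian scaling; non-negativity of
nugget and sills is enforced by the bounds.

**Ordinary kriging.** Per grid cell: neighbours inside the anisotropic
ellipsoid (50 km horizontal, 20 m vertical), the 10 nearest kept, cells with
fewer than 3 masked.  The OK system uses C(h) = total sill − γ(h) with
C(0) = total sill, i.e. the exact-interpolation convention (a zero-nugget
model reproduces data values exactly at data points; kriging variance is 0
there and positive away from data).  A 10⁻¹⁰ diagonal jitter guards
conditioning; singular systems fall back to per-cell least squares and are
masked if still unsolvable.  Edge penalization multiplies the target-to-
neighbour covariances of neighbours beyond 0.8 of the search radius by a
linear taper reaching 0.5 at the boundary, suppressing weight discontinuities
as points enter and leave the moving neighbourhood; the published analysis
cites a penalization method without giving its formula, so this taper is an
explicit approximation and is config-exposed.  Systems are solved in batches
grouped by neighbour count, which keeps a ~300 000-cell grid under a minute
on one CPU.

## Track regularization (CTCRW)

The movement model is the integrated Ornstein–Uhlenbeck velocity process:
velocity decays at rate β (s⁻¹) and diffuses at scale σ; position integrates
velocity.  The Gaussian transition over each time step Δ is exact —
e.g. Var(v_{t+Δ}|v_t) = σ²(1 − e^(−2βΔ))/(2β) and the matching position and
cross terms — never an Euler approximation, so irregular gaps (including time
under water) need no special treatment.  Observation error is fixed at
τ = 5 m SE per axis, the nominal GPS accuracy.  (β, σ) are estimated by
Nelder–Mead on the Kalman-filter likelihood in log-parameter space; x and y
share the state covariance, halving the filter cost.  Positions at the 5-min
grid come from the RTS smoother on the union of observation and prediction
times; the reported SE combines both axes (√(var_x + var_y)), so at
observation times it is bounded near √2 τ.

Before fitting, tracks are speed-filtered: the *later* fix of the first pair
implying more than 20 m s⁻¹ is removed and speeds recomputed to a fixpoint —
the earlier, presumed-anchored position survives.  The filter is idempotent
and matched against a brute-force oracle.  "Single-day" trips are defined by
the local calendar day (a trip crossing midnight is removed); colony
departure/return is detected within 500 m of the colony.

Step lengths and turning angles derive from consecutive smoothed positions:
step i is the distance into fix i, the turn at fix i is the signed heading
change in (−π, π], and zero-length steps propagate the previous heading.

## Movement HMM and the null ensemble

Two states with gamma step lengths (parameterized by mean μ_k and SD σ_k, in
metres per 5-min interval) and von Mises turning angles (mean m_k,
concentration κ_k).  The label *foraging* attaches to the state with the
smaller μ (area-restricted search); *transiting* to the other.  The pooled
forward-algorithm likelihood (scaled, vectorized across tracks) is maximized
directly by L-BFGS-B over 10 unconstrained parameters, best of 10 restarts
(first start moment-based, others perturbed); the initial distribution is
tied to the stationary distribution of the transition matrix.  Direct
maximization rather than EM keeps restarts and bounds simple.  Forward
likelihood and Viterbi are verified against exhaustive path enumeration.

Null tracks are simulated step by step from the fitted kernel: Markov states,
gamma steps (floored at 1 m so headings stay defined), von Mises turns, the
first heading uniform.  A proposal landing on shore redraws step and turn;
after 200 failed redraws the heading proposal broadens to uniform so a track
pressed against the coast with κ ≈ 8 still terminates — a deliberate, local
distortion of the kernel, since the published land-avoidance mechanism is not
specified.  Ensembles sample track lengths and start points with replacement
from the real tracks (colony start by default), and any track with strictly
more than 20% of fixes outside the survey polygon is removed — in the worked
experiment this keeps roughly 280 of 500, a similar retention to the study
design the generator emulates.

Default synthetic kernel (the generator's study conditions): μ = (150, 700) m,
σ = (100, 300) m, κ = (0.5, 8), transition diagonal 0.9 — penguin-like speeds
of 0.5 and 2.3 m s⁻¹ with sticky behavioural bouts.

## Prey-encounter index and bootstrap

Depth weights are the frequencies of maximum dive depths in 1 m bins,
truncated at 30 m (more than 99% of observed dive activity in the emulated
system lies above 30 m) and renormalized.  The 3-D field collapses to 2-D as
a linear-domain convex combination per column; masked layers are excluded
with weight renormalization, and the output is bounded by the per-column
min/max of the linear layers.

The index reads the 2-D field at each fix by bilinear interpolation.
Fixes outside the field (or on masked cells) are skipped and counted, and the
duration denominator is scaled by the in-field fraction of fixes, so E is the
encounter rate over the time the surveyed grid can speak to.  Without this
scaling a track partially leaving the grid is diluted toward zero, and any
systematic difference in grid overlap between the arms mis-calibrates the
comparison — on a flat-field control the informed arm (99% in-field) beat the
random ensemble (94% in-field) essentially always despite identical per-fix
densities.  With all fixes in-field the identity E = n·v/T for a constant
field v is exact.  A `foraging_only` mode restricts the sum to HMM-foraging
fixes while keeping the trip duration, because the published definition
("per hour of foraging across each track") is ambiguous; the default scores
all fixes.

The bootstrap draws, `n_draws` times (100 000 by default; 10 000 in the
synthetic experiments), a without-replacement sample of simulated indices
equal in number to the real tracks, and records ΔE = mean(real) − mean(draw).
`p_better` counts strictly positive anomalies (ties are not wins); the
anomaly is reported as mean ± SE where SE is the SD of the draw distribution,
and additionally as the dB ratio 10 log₁₀(mean real / mean sim).  Sampling
without replacement implies a degenerate edge case: if the two arms are the
same multiset of equal size, every draw is the whole ensemble and the anomaly
is identically zero.

With exchangeable arms, per-replicate `p_better` is a probability integral
transform and therefore near-uniform on (0, 1); a 50-replicate mean has an
irreducible Monte-Carlo SD of ≈ 0.04.  The calibration test asserts the mean
within [0.45, 0.55], which is a ±1.2 SD band — adequately sensitive to real
bias but expected to fluctuate near its edges between seeds.

## Space use, dives, mass

The UD is a bivariate Gaussian KDE with per-axis normal-reference bandwidth
h = 1.06 σ̂ n^(−1/5) (the rule-of-thumb constant 1.06 is a documented choice;
the source analysis names the rule but not the constant), normalized on a
grid spanning the data ± 3 bandwidths.  The 75% region accumulates cells by
descending density until the mass reaches the level, so its mass lies in
[0.75, 0.75 + max cell mass]; membership tests use the cell set exactly,
marching-squares polygons are for reporting only.  Dives join the track by
nearest timestamp within ±150 s (half the 5-min interval); unmatched dives
are excluded from UD-conditional histograms and counted in logs.

Mass condition: anomaly = mass − per-sex pooled mean; the per-sex Gaussian
GLM regresses anomalies on year indicators with the intercept forced to zero,
so each coefficient *is* that year's mean anomaly, tested two-sided.  Because
anomalies are deviations from the pooled mean, a planted effect e in one of k
balanced years implies a year anomaly of e(1 − 1/k) — recovery experiments
score against that implied value — and the tests are mildly conservative
(measured type-I rate ≈ 0.034 at nominal 0.05), a property inherited from the
anomaly definition itself.

## Synthetic data: what it emulates, and what it does not

The seascape is a straight north–south coast with water on one side, a colony
9 km offshore, and 9 coast-perpendicular transects 3.5 km apart (≈ 31 km
alongshore extent).  The prey-field truth is a stationary Gaussian random
field in dB (circulant-embedding FFT; negative embedding eigenvalues clipped
to zero, which can only shrink the realized variance and is covered by the
covariance-recovery test), defaults: mean −75 dB, nugget 0.5 dB², Gaussian
partial sill 4 dB² (SD 2 dB),
horizontal range 2 km — mesoscale patchiness — plus an optional additive
hotspot, a Gaussian-profile dB bump (default +12 dB, 5 km radius, 2.5 km
offshore, centred on a transect).  Surveys read the truth tri-linearly along
transects every 200 m × 1 m depth with 0.5 dB noise.  Tracks are HMM paths
observed with 5 m GPS noise and 20% dropout at jittered times; dives attach
one per fix with depth 2 + Exp(8) m truncated at 70 m (≈ 63% of dives above
10 m, ≈ 97% above 30 m) and duration 2 × depth + Exp(10 s), plus an optional
sub-threshold contamination to exercise the 2 m / 5 s filter.  "Informed"
foragers redirect their heading toward an attractor with probability 0.7 when
outside its radius.

Not emulated: echogram-level acoustics (beam geometry, school detection),
tides and diel prey movement, multi-day trips, device effects, and any
space–time evolution of the prey field between survey and tracking — the
field is one frozen snapshot, as in the study design.  Passing tests
demonstrate the pipeline recovers known structure under these idealized
conditions; they do not validate the snapshot assumption on real data.

## Problem sizes and determinism

The test suite and acceptance script run everything from scratch on one CPU:
the hotspot experiment uses 15 informed tracks × 140 fixes against 500
simulated tracks on a ~67 × 153 × 30 grid (~2 min including the flat-field
control); HMM recovery uses 50 × 140 fixes; CTCRW recovery 20 tracks × 2000
fixes; variogram recovery a 16-line × 200-point survey; bootstrap calibration
50 replicates × 10 000 draws; mass calibration 500 replicates.  One master
seed deterministically derives every stage seed via
`SeedSequence(master, crc32(stage))`, and reruns are bit-reproducible.

## Known limitations

* The flat-field negative control compares a spatially clustered arm with a
  dispersed one on a *single* field realization; its p_better has
  realization-level spread and can land outside the central band for some
  seeds even though the index is calibrated on average (verified over 200
  replicates of the same-generator null).
* Kriging variance is reported but not propagated into the encounter index.
* The back-transform's clamped tails bias extreme kriged cells toward the
  observed data range.
* The edge-penalization taper and the land-avoidance redraw broadening are
  explicit approximations of published-but-unspecified mechanisms.
* No covariate-dependent transitions, no >2-state models, no dive-resolved
  behaviour.
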