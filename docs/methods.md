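# Methods

This note documents the models behind `preyscape`, the defaults they
ship with, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter when interpreting its
output.

## Acoustic processing

Echo integration follows the standard fisheries-acoustics definitions:
Sv values are only ever averaged in the linear domain
(`s_v = 10^(Sv/10)`), per along-track interval (default 30 s, ~150 m
at 10 kn) and 1-m depth bin, with bin *i* covering [i, i+1) m
(half-open throughout the package). Three sample states are kept
distinct on purpose:

* finite Sv — a measurement;
* below detection (stored as −∞ dB) — a *measured absence*: it enters
  linear means as 0 and maps to density 0, so empty water pulls
  means down rather than disappearing from them;
* unsampled (NaN) — missing, excluded from every mean.

NASC uses `4π·1852² Σ s_v Δz` with the vertical sum over bins whose
lower edge lies in the half-open depth window, which makes NASC
exactly additive over a partition of the water column.

Seabed detection is a per-ping threshold-plus-gradient search (default
threshold −35 dB, searched below 10 m — a hard bottom exceeds any
biological layer by tens of dB), median-smoothed across pings, with a
0.5-m backstep above the detected bottom. Near-surface exclusion
(default 5 m) reflects transducer draft and bubble entrainment; an
optional schedule of trawl windows removes vessel-slowdown periods.

## Target strength (DWBA)

Small crustacean scatterers are modelled as uniformly bent fluid
cylinders under the distorted-wave Born approximation: backscattering
amplitude integrated along the discretised centreline with the
J₁-aperture term, phase `2i k₂·r` (k₂ = k₁/h inside the body),
contrast γ_κ − γ_ρ, then |f|² averaged over a truncated-normal tilt
distribution and over the supplied length distribution. The ensemble
TS is 10 log₁₀ of the *mean cross-section* (energy-consistent), never
the mean of per-animal TS.

Defaults (all configurable, units in the dataclass): g = 1.0357,
h = 1.0279 (standard euphausiid contrasts), length-to-radius ratio
L/a = 16, bend radius 3L, tilt ~ N(−20°, 20°), 50 body segments,
61 tilt nodes over ±3σ, sound speed 1540 m s⁻¹, 100 lengths uniform
on 8–13 mm at 120 kHz. The implementation is validated against a
brute-force 3D Born volume integral (they agree up to the conventional
1/h prefactor of the deformed-cylinder line-integral form, ≈0.24 dB)
and reproduces exact k⁴ Rayleigh scaling.

Interpretation caveat: the ensemble TS is *extremely* sensitive to the
unmeasured shape and orientation parameters — moving L/a from 16 to 12
adds ~+5 dB, and broadside-only orientation adds ~+4 dB relative to
the default tilt spread. Under the defaults above the 8–13 mm ensemble
computes to −93.7 dB at 120 kHz; any application with measured animals
should set g, h, L/a and the tilt distribution from its own data
rather than lean on these defaults.

## Tag processing

A floating tag transmits on its programmed schedule, so the
detachment filter looks for a trailing run of fixes whose consecutive
gaps equal the programmed interval (30 min ± 2 min tolerance, minimum
run of 3 fixes — a rule needs a minimum run; one on-schedule gap is
routinely produced by chance) and drops everything from the run's
start. Time-at-depth/temperature histograms count 1-Hz samples per
1-m/1-°C bin; they conserve the record length by construction and the
day and night histograms sum bin-wise to the full-period one. Day is
defined as solar elevation ≥ 0° at the site (computed with the NOAA
low-precision ephemeris, ~0.1° accuracy — ample for a boolean flag).
Pseudo-tracks are natural cubic splines of easting/northing against
time through the attached fixes, evaluated at the 1-Hz record
timestamps strictly inside the fix span (no extrapolation; splines
extrapolate badly). Depth-sensor jitter in (−1, 0) m is clipped to 0;
values below −1 m are rejected as corrupt.

## Utilisation distributions

Gaussian product kernels with per-axis normal-reference bandwidths
h_j = σ_j n^(−1/(d+4)) by default; the selector is pluggable because
home-range areas are bandwidth-dominated and any serious application
should report its choice. Grids are padded 5–6 bandwidths so the
discrete density integrates to 1 without renormalisation (verified to
1e-6). Isopleths accumulate cells by descending density (ties broken
by cell index) until the target mass; areas/volumes are cell counts ×
cell measure, reported in km²/km³. Single-kernel closed forms are
reproduced to well under 1%: the 2D 95%/50% area ratio ln 20/ln 2 and
3D volumes (4/3)π h_x h_y h_z r³ with r² the χ²(3) quantile.

In 3D the exact per-point sum is used up to 2000 points; longer 1-Hz
tracks switch to a histogram-plus-Gaussian-convolution evaluation
(truncation 6σ) whose isopleth volumes agree with the exact method to
a few percent at the default voxel of one-eighth bandwidth. The
pipeline uses 25 × 25 × 1 m voxels (matching the 1-m depth bins) and
floors bandwidths at twice the voxel so volumes stay resolved.
Density below the local seabed is zeroed and the distribution
renormalised — a deliberate physicality constraint, since an
unclipped kernel places mass inside the substrate for
bottom-following animals.

## Spatial matching and models

The matching radius is justified by the spatial autocorrelation of
backscatter: an empirical semivariogram (lag width 100 m, max lag
3 km, computed on column MVBS in dB, censored at the −100 dB
detection floor as on a thresholded echogram) fitted by
count-weighted least squares with the Gaussian model; effective range
= a√3. Two degenerate outcomes are flagged rather than reported as
numbers: *pure nugget* (the spatial structure explains <30% of the
count-weighted variance, or the partial sill is <5% of the total) and
*range censored* (fitted a beyond the largest lag — the survey extent
cannot identify it). Buffers are horizontal cylinders: 2D
centroid distance strictly < 1 km, temporal window ±6 h (the window
is a parameter; survey-concurrent matching has no universal
tolerance), arithmetic means per 1-m bin with zeros included.

The vertical model is a Gaussian random-intercept mixed model fitted
by maximum likelihood (not REML) so AIC against the null
`TAD ~ 1 + (1|shark)` is valid; AIC counts fixed effects + group
variance + residual variance. The default response is log(TAD + 1 s)
— TAD is a nonnegative, right-skewed duration — with the raw scale
retained for simulation recovery. Reported r² is the marginal
(fixed-effects) share var(Xβ)/(var(Xβ) + σ_b² + σ_e²); the
random-effect share is σ_b²/(σ_b² + σ_e²). When the group variance
profiles to exactly zero the optimiser can return an infinite
log-likelihood; the fit then falls back to the boundary (OLS)
likelihood with the same parameter count. The horizontal model is an
OLS of pooled 2D-UD cell mass on 10 log₁₀(NASC + 1), pooled across
animals (no grouping survives pooling).

## Synthetic scenes: what they emulate, and what they do not

The generator reproduces the *structure* of a reef-edge study area:
a shelf sloping 10→60 m with gutters/pinnacles (amplitude 4–9 m)
scattered on the 50-m contour, prey patches (default 8, radius 300 m,
peak ~500 ind m⁻³ over a 0.01 background — within the 0.01→10⁵ range
acoustic surveys report for coastal zooplankton) attached to those
features and concentrated near the seabed (weight 0.7, vertical σ
5 m), with an optional 10-m upward night shift emulating diel
vertical migration. Surveys run cross-shelf lines (3.5 km, 1-km
spacing, 10 kn, 0.5-s pings, samples from 5 m); forward Sv is
`10 log₁₀(n σ_bs)` plus Gaussian dB noise (default 3 dB single-ping
variability), a −20 dB seabed echo decaying below, and a −100 dB
detection floor. Sharks dive as a two-state renewal process (surface
phases ~400 s; targets mixed 45/20/35% over <10 m, 10–40 m, 40–60 m
at 0.5 m s⁻¹ vertical speed, capped by the seabed) while walking on
the grid with step probabilities ∝ exp(β_pref · standardised log
column density) — β_pref is the known ground truth the statistics
must recover in sign.

Not emulated: hydrodynamics (eddies, dense-water outflows), prey
advection or avoidance, multi-frequency acoustics, species mixtures,
position error on fixes, tag sensor drift. Passing tests therefore
demonstrate that the *processing chain* is correct and its estimators
recover known truth — not that real sharks behave like the walk, nor
that real prey fields are Gaussian patches.

A deliberate consistency property: with zero noise and the detection
floor disabled, running the acoustics chain on a simulated survey
reproduces the scene's cell-averaged true density to machine
precision, because the ground-truth aggregation shares the cleaning
mask and cell layout with the estimate (same flags, same linear-mean
path). This pins the whole forward/inverse pair to a single
convention and is asserted at <1e-6 relative error.

## Problem sizes and determinism

Default study runs use a 4 × 4 km scene at 50-m resolution, ~5400
pings, six 22-h sharks at 1 Hz, 100-replicate model-recovery
simulations and 20-replicate variogram recovery — sizes chosen so a
full pass (tests plus acceptance script) completes in minutes on one
core while keeping Monte-Carlo assertions comfortably away from their
thresholds. Every random stream derives from a single integer seed
(scene, survey noise and each shark get independent substreams), so
identical configurations are bit-reproducible.

## Known limitations

* The printed-schedule detachment rule can coincidentally flag a few
  genuinely attached fixes whose surfacing gaps land on the schedule;
  the filter is deliberately conservative.
* Variogram ranges beyond the survey extent are reported as censored,
  not as numbers; the synthetic backscatter field has a cross-shelf
  trend (patches hug the reef edge) that routinely censors the range
  at the 3-km max lag.
* The 2D UD on 500-m cells from a few dozen fixes is lumpy; its
  regression against NASC is seed-sensitive at the default six-shark
  scale and is reported descriptively, not as a calibrated estimator.
* Isopleth polygons assume the grid padding keeps contours interior;
  fixed analysis grids that truncate the kernel will underestimate
  the enclosed mass.
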