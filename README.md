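# preyscape

Tools for linking the three-dimensional movements of tagged marine
megafauna to acoustically measured zooplankton prey fields, built for
the situation faced at coral-reef aggregation sites: a filter feeder
(e.g. a whale shark) carries a 1-Hz depth/temperature tag that yields
sparse surface position fixes, while a vessel maps the surrounding prey
field with a 120-kHz echosounder. The package turns those two data
streams into a common currency — volumetric prey density and
utilisation distributions on a shared metric grid — and asks whether
horizontal and vertical space use follows prey density.

Because such field datasets are rarely released, the package ships a
first-class synthetic-data module: reef-edge bathymetry with gutters
and pinnacles near the 50-m contour, prey patches attached to those
features, a forward-modelled echosounder survey, and sharks whose
preference for prey density is a known simulation parameter, so every
stage of the chain is testable against ground truth.

## What it computes

**Acoustics** (`preyscape.acoustics`, `preyscape.dwba`). Per-ping
volume backscattering strength Sv (dB re 1 m⁻¹) is cleaned (seabed
detection, near-surface exclusion, trawl windows), echo-integrated
into 30-s × 1-m MVBS cells — always averaging in the linear domain,
`MVBS = 10 log₁₀(mean 10^(Sv/10))` — and summed into the nautical area
scattering coefficient per 500-m interval,

    NASC = 4π · 1852² · Σ_z s_v Δz   [m² nmi⁻²].

Densities follow from a single-animal target strength, `n =
10^((MVBS − TS)/10)` ind m⁻³, with TS from a distorted-wave Born
approximation (DWBA) for a bent fluid cylinder: material contrasts
γ_κ = (1 − g h²)/(g h²) and γ_ρ = (g − 1)/g, numerical integration
along the discretised body with a Bessel-function aperture term,
averaged over a normal tilt distribution and the measured length
distribution (TS = 10 log₁₀ of the mean cross-section).

**Tags** (`preyscape.tags`). Detachment filtering (a floating tag
transmits on its programmed 30-min schedule), time-at-depth and
time-at-temperature budgets in 1-m/1-°C bins split day/night by solar
elevation, and 1-Hz pseudo-tracks from natural cubic splines through
the fixes.

**Habitat use** (`preyscape.habitat`). Gaussian product-kernel
utilisation distributions in 2D (500-m analysis cells) and 3D
(x, y, depth voxels, seabed-clipped); p% isopleths by
descending-density accumulation (50% "core", 95% "range");
day/night comparison by Wilcoxon rank-sum.

**Matching & models** (`preyscape.matching`, `preyscape.models`). The
matching scale comes from an empirical semivariogram of backscatter
fitted with a Gaussian model γ(h) = c₀ + c(1 − e^(−h²/a²)) (effective
range a√3); prey density is averaged per 1-m depth bin over survey
cells within a 1-km buffer of each time-matched shark position, zeros
included. Two habitat models: pooled 2D-UD cell value on NASC (dB),
and a Gaussian mixed model `TAD ~ density + (1 | shark)` fitted by ML
and compared with its null via Akaike weights.

## Worked example

The numbered drivers under `analysis/` run the whole study on a
synthetic scene (all randomness follows `--seed`) and write tables
under `results/`:

```sh
python analysis/01_simulate.py --seed 1
python analysis/05_habitat.py --seed 1
python analysis/06_models.py  --seed 1
```

prints (seed 1):

```
scene: 80 x 80 cells at 50 m, seabed 10.0-61.2 m
true density: 0.01 to 647 ind m^-3 (background 0.01)
survey: 5440 pings, 62 samples each (5 m to 66 m)
...
2D UD from 289 pooled fixes on 500-m cells:
  core (50%) area  2.25 km^2 in 1 polygon(s)
  range (95%) area 10.00 km^2
  3D 50% volume: day 0.0061 +- 0.0039 km^3, night 0.0072 km^3
day vs night volumes: W = 65, p = 0.71 (exact)
...
TAD ~ density (full column): slope -0.008, r^2 = 0.022, shark random effect = 11% of variance
wAIC: null 0.21 vs density model 0.79 -> prefer 'tad ~ density + (1|shark)'
```

Read: the six simulated sharks concentrate in a 2.25-km² core along
the reef edge; their 3D space use does not differ between day and
night (p = 0.71); vertical time-at-depth is essentially unrelated to
the prey profile (r² = 0.02) even though the horizontal walk prefers
dense columns — the surface-weighted dive cycle dominates depth use.

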