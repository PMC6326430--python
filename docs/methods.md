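# Methods

## Model

`prairieq` implements the habitat-quality formulation popularized by
ecosystem-services toolkits such as InVEST. The pipeline has five stages:

1. **Reclassification.** A land-cover raster (integer class codes with a
   code → name legend) becomes a baseline suitability raster via a table of
   weights *H<sub>j</sub>* ∈ [0, 1]. Class identity is by *name*, so
   synthetic and production legends interchange. Shipped weights follow the
   published grassland-bird parameterization: grassland and conservation
   (CRP) grassland 1.0, hayland 1.0, small grains 0.5, fallow 0.3,
   everything else 0.
2. **Threat layers.** Binary presence rasters: by class membership
   (cropland = row crop, woodland, urban), one-pixel road lines, and energy
   facilities from buffered points (wells 100 m, turbines 30 m — published
   surface-impact radii). A point always marks the pixel containing it, so
   buffer masks are monotone in radius.
3. **Degradation.** The uncapped sum
   D_x = Σ_r Σ_y (w_r/Σw_r) · r_y · max(0, 1 − d_xy/d_max,r) · β_x · S_jr
   over every threat-occupied pixel y within d_max of x, with linear decay
   evaluated at pixel-centre distances and the threat pixel contributing
   i = 1 to itself. The production path convolves each presence raster with
   an exact truncated discrete kernel (direct, non-FFT convolution), so it
   equals the literal double sum to floating-point summation order;
   `degradation_bruteforce` evaluates that double sum and serves as the
   test oracle (guarded to ≤128×128 grids).
4. **Quality.** Q_x = H_x · (1 − D_x^z/(D_x^z + k^z)) with half-saturation
   k = 0.20 (published choice) and exponent z = 2.5 (toolkit convention;
   exposed as a parameter). Q = H where no threat reaches, and exactly H/2
   where D = k, for any z.
5. **Accounting.** Against a threshold of 0.3 — the lowest habitat-class
   weight — a baseline-suitable pixel is *lost* if its impacted value drops
   below 0.3, *degraded* if it drops but stays ≥ 0.3, *retained* otherwise
   (increases count as retained; there is no "improved" category).
   Regional summaries use the baseline suitable area of the same region as
   the percentage denominator throughout. Printed-table style percentages
   use decimal half-up rounding at the requested precision.

### Assumptions and numerical choices

- Distances are Euclidean metres on a projected, north-up 30 m grid; no
  geographic CRS support. Pixel (i, j) centre = origin + ((j+0.5)·cell,
  −(i+0.5)·cell); the raster boundary is the world boundary (no phantom
  threats outside the window, which slightly biases edge pixels low in
  degradation).
- D is deliberately uncapped: a dense threat neighbourhood can push D far
  above 1, and the half-saturation transform, not a cap, bounds Q.
- Threat weights self-normalize by their sum, so with one threat D is
  invariant to rescaling w.
- Polygon rasterization labels a pixel by the polygon containing its
  centre; overlaps resolve to the highest id (documented tie-break).
- Scenario subsets: one uniform permutation of field ids per seed; the
  fraction-f subset is its first round-half-up(f·N) ids, giving nesting by
  construction. Selection is by field *count* (field-by-field producer
  decisions); verification reports the converted share of CRP *area*, so
  the two differ by field-size variation.

## Parameter defaults

| parameter | default | units | why |
|---|---|---|---|
| half-saturation k | 0.20 | – | published model choice |
| exponent z | 2.5 | – | toolkit convention; settable |
| suitability threshold | 0.3 | – | lowest habitat-class weight |
| well buffer | 100 | m | published surface-impact radius |
| turbine buffer | 30 | m | published surface-impact radius |
| stop buffer | 400 | m | assumed bird-detection distance |
| scenario fractions | 10/25/50/75/100 | % | published scenario set |
| cropland d_max | 100 | m | published influence distance |
| woodland/urban/roads/energy d_max | 250/500/250/500 | m | stand-ins, see below |
| threat weights | 1.0/1.0/0.5/0.4/0.7 | – | stand-ins ordered per the published ranking (woodland, urban greatest) |

The full threat-weight and sensitivity tables of the original analysis are
not reproduced in public sources; the shipped `threats.csv` and
`habitat_sensitivity.csv` are clearly-labelled representative stand-ins
that preserve the published ordering (woodland and urban most destructive;
habitat classes sensitive in proportion to their suitability). Influence
distances for the stand-in threats were fixed at the same order of
magnitude as the one published distance (cropland, 0.1 km): under the
uncapped summed degradation, kilometre-scale distances would let large
threat blocks drive D ≫ k across whole landscapes and convert nearly all
habitat to "lost", which contradicts the regional pattern the model is
meant to reproduce (loss < 1 %, degradation 13–31 %). All of these load
from one YAML config and can be overridden per run.

### Count model

Counts are modelled as NB2: mean μ = exp(β0 + β1·x), variance μ + μ²/θ
(equivalently μ + α·μ² with α = 1/θ — stated once to avoid the
two-parameterization trap). The dispersion is estimated by maximum
likelihood jointly with the coefficients (statsmodels). K therefore counts
the dispersion parameter: intercept-only K = 2, one-covariate K = 3. Some
published tables count one parameter more (K = 3/4); `aicc()` takes K
explicitly so either convention is reproducible. Confidence intervals are
two-sided Wald at a settable level (default 95 %). Pseudo-R² defaults to
Nagelkerke (a [0, 1]-normalized likelihood-ratio statistic), with McFadden
reported alongside; the published analysis does not name its family.

## Synthetic data

The generator emulates the statistical structure the analysis assumes on a
northern-prairie agricultural mosaic:

- **Field mosaic** by recursive rectangle splitting with cell-aligned cuts
  (default sides 300–1200 m), classes drawn independently per field from
  configured proportions (row crop 45 %, native prairie 20 %, CRP 10 %,
  small grains 10 %, woodland 5 %, urban 4 %, fallow 3 %, water 3 % —
  a row-crop-dominated composition typical of the region).
- **Roads** as section-line-style one-pixel lines every 1600 m.
- **Wells** from a Thomas (parent–offspring) cluster process
  (0.08 parents/km², mean 6 wells per cluster, 300 m spread), mimicking
  the tight clustering of producing basins; **turbines** on a 2400 m grid
  with 200 m jitter.
- **Stops** uniform with a minimum spacing (default 800 m; placement by
  bounded rejection sampling), and **counts** NB2 with defaults β0 = 1,
  β1 = 1.76 (the published slope magnitude), θ = 1.5.

All randomness derives from one seed through named substreams
(landscape/wells/turbines/stops/counts), so stages regenerate
independently and outputs are bit-reproducible.

What the generator does *not* emulate: wetland mosaics and hydrology,
spatial autocorrelation of counts beyond what quality induces, species
detection processes, year effects, real CDL class granularity, and real
field-shape irregularity (fields are rectangles). Passing tests therefore
demonstrate internal correctness and qualitative behaviour (direction and
rough magnitude of degradation, slope recovery, threshold contrast), not
quantitative agreement with any real landscape.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen as the package's
standard study conditions: 200 × 200 cells (6 × 6 km) for end-to-end runs,
≤ 64 × 64 landscapes (100 random draws) for the brute-force oracle
comparison, 2 000 stops × 100 replicates for the Monte-Carlo slope-recovery
study, and 250 stops for the end-to-end validation. The published
regional tables are used as shipped numeric inputs for
arithmetic-consistency checks; the continental analysis behind them
(multi-state 30 m rasters, millions of fields) is out of scope.

## Known limitations

- No exponential decay option, accessibility rasters (β ≠ 1) or habitat
  rarity weighting; linear decay only, as in the analysis modelled.
- Whether the original tool version normalized degradation by threat-pixel
  count is not documented; the literal summed form is implemented, and the
  stand-in influence distances compensate (see above). Comparisons of D
  across parameterizations with very different threat densities should be
  made with care.
- One published regional table mixes percentage denominators across rows;
  `prairieq` uses a single convention (baseline suitable area of the same
  region) rather than imitating the inconsistency, so row-level
  percentages of that table are not reproduced — the region-wide figures
  are.
- GeoTIFF metadata is carried in a private tag (JSON in ImageDescription),
  not full GeoTIFF georeferencing tags; use the `.asc` format for
  interchange with GIS software that needs georeferencing.
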