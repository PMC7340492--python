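# Methods

`phenotrial` re-implements, as a tested and reusable pipeline, a plot-level
remote-sensing phenotyping workflow for maize field trials that contrast
conservation agriculture (CA: no-till with the soil covered by crop-residue
stover) against conventional ploughing (CP: bare-soil background), crossed
with planting density and hybrid. The pipeline has three computational
stages — colour/vegetation index extraction from plot images, auxiliary
trait computation, and trait-versus-grain-yield statistics — plus a
synthetic trial generator that makes every stage verifiable without any
field data.

## 1. RGB colour indexes

Plot images are 8-bit sRGB. Channels are divided by 255 and converted along
a fixed pipeline (sRGB gamma → linear RGB → XYZ with D65 white point and 2°
observer → CIELab and CIELuv). No camera-specific calibration is applied —
these are consumer-camera images and the indexes are used comparatively.
The white point is defined as the row sums of the sRGB→XYZ matrix so that
sRGB white maps exactly to L\* = 100, a\* = b\* = u\* = v\* = 0.

Per-pixel hue is the HSV hexagonal hue in degrees; saturation is
(max−min)/max; intensity defaults to mean(R,G,B) (the HSB "value"
max(R,G,B) is available as an option, since index software differs on this
point and the convention is rarely documented).

Plot-level statistics:

* intensity, saturation, L\*, a\*, b\*, u\*, v\*: arithmetic means over all
  pixels;
* hue: *circular* mean over chromatic pixels (hue is an angle; an
  arithmetic mean would be wrong across the 0/360 wrap);
* **GA** (green area): fraction of all pixels with hue in [60°, 180°);
* **GGA** (greener area): fraction with hue in [80°, 180°), excluding
  yellowish greens;
* **CSI** (crop senescence index): (GA − GGA)/GA × 100, in percent; missing
  when GA = 0 (no division error).

Conventions the source material leaves open, fixed here: hue intervals are
half-open (a wrap-around partition of the hue circle needs one open end);
achromatic pixels (r = g = b, hue undefined) count in the GA/GGA
denominators but never in the numerators, and are excluded from the
circular hue mean. When a plot has several photographs, indexes are
computed per image and then averaged arithmetically — the averaging order
matters for CSI (CSI of means ≠ mean of CSIs) and is asserted in tests.

## 2. Multispectral indexes and the NDVI soil mask

Reflectance cubes carry 11 bands centred at 450, 550, 570, 670, 700, 720,
780, 840, 860, 900 and 950 nm (one widely used multispectral array camera's
filter set), already calibrated to reflectance in [0, 1]; values up to 1.2
are tolerated on read (calibration overshoot), anything beyond raises.

Thirteen indexes are computed (NDVI, SAVI with L = 0.5, OSAVI with
c = 0.16, RDVI, EVI, PRI, MCARI, CCI, TCARI, TCARI/OSAVI, ARI2, CRI2, WBI).
The canonical published formulas are used. Printed secondary sources of
these formulas frequently contain typos; the ones handled explicitly here,
switchable back to "as printed" via `MSIndexParams(as_printed=True)` for
sensitivity checks:

* RDVI — printed forms often duplicate NDVI; the canonical √ denominator
  (B840−B670)/√(B840+B670) is used;
* PRI — printed denominators sometimes equal the numerator (identically 1);
  the canonical sum denominator (B550−B570)/(B550+B570) is used. 550 nm
  substitutes the original 531 nm band, which this filter set lacks;
* SAVI — the (1+L) scaling is included;
* MCARI/TCARI — garbled printed variants are not implementable; the
  canonical bracketed forms are always used (the `as_printed` switch leaves
  them unchanged);
* WBI — uses the 950/900 nm ratio (no 970 nm filter in this set).

Aggregation is **mean reflectance first, then index**: per-band means over
the selected pixels are computed and the index formulas applied to the mean
spectrum. For ratio indexes this differs from averaging per-pixel index
values; a `per_pixel` aggregation option exists for sensitivity analysis.
Two modes: `plot` (all pixels) and `vegetation` (only pixels whose NDVI
lies in [0.4, 1.0], the soil/residue mask). Vegetation cover (percent) is
the complement of the mask. Division by zero yields missing values (empty
CSV cells), never exceptions; an empty mask yields all-missing
vegetation-mode indexes with a logged warning.

## 3. Auxiliary traits

* Isotope composition: δ = (R_sample/R_standard − 1) × 1000 (per mil), with
  the VPDB ¹³C/¹²C and atmospheric-N₂ ¹⁵N/¹⁴N reference ratios shipped as
  constants.
* Thermal: raw counts convert as °C = raw/scale − 273.15. The nominal
  "Kelvin × 10,000" 16-bit encoding overflows 16-bit integers at ambient
  temperature, so the scale is a parameter (default 10,000) and rasters
  already in °C are accepted directly. Plot temperature is the arithmetic
  mean over the whole plot ROI — deliberately unmasked, since the
  background-vs-canopy temperature split is itself informative and
  canopy-only thermal segmentation is out of scope.
* C/N ratio = %C / %N, missing when %N = 0.

## 4. Trial statistics

* **Factorial ANOVA**: two-way fixed-effects (tillage × density) with
  interaction, Type-II sums of squares via explicit model comparison
  (RSS drops between nested least-squares fits), F against the full-model
  residual mean square. Implemented directly on design matrices for speed
  (the calibration tests fit thousands of models); `statsmodels.anova_lm`
  is the independent oracle in the test suite, never the implementation.
  Cells must be non-empty with ≥ 2 replicates; violations raise with the
  offending cell named. Significance stars at 0.05/0.01/0.001.
* **Yield correlations**: Pearson r of each trait against grain yield,
  pairwise-complete, within the whole trial, each tillage arm, each density
  level and the four combinations. No multiple-testing correction by
  default (matching the conventional presentation of trial correlation
  tables); Benjamini–Hochberg is available as an option.
* **Stepwise yield model**: forward selection from the intercept-only
  model; at each step the candidate minimizing residual SS enters if its
  partial-F p-value < 0.05, stopping at four predictors. The cap and the
  partial-F entry rule are assumptions (the source workflow states
  "forward stepwise" without thresholds; its published models all use four
  or fewer predictors). Listwise deletion; raw-scale coefficients; each
  predictor's variance portion is its incremental R² at entry, so portions
  sum exactly to the final R². Candidates that would make the design
  matrix rank-deficient or ill-conditioned (condition number > 1e8 on the
  standardized augmented matrix) are skipped with a warning.

## 5. The synthetic trial generator

The generator emulates the trial the analysis assumes: 2 tillage × 2
density × 8 hybrids × 3 replicates = 96 plots, hybrids randomized within
each (tillage, density, replicate) block. Hidden per-plot ground truth:
canopy fraction, senescent fraction of canopy, residue fraction of
background (0 for CP; uniform on [0.3, 0.9] for CA — at least 30% residue
cover is the defining criterion of conservation agriculture), a background
brightness multiplier, yield, and canopy temperature.

Yield model:

    GY = baseline + tillage_effect·[CA] + hybrid_effect
         + slope·(canopy_fraction − its per-tillage mean) + ε,

truncated at 0 (truncations logged; none occur at defaults). The canopy
term is centred within tillage arm so `tillage_yield_effect` *is* the total
CA−CP contrast even though canopy fractions differ by arm. Defaults:
baseline 2.42 Mg ha⁻¹ (a realistic smallholder maize mean), tillage effect
+0.57 Mg ha⁻¹, hybrid SD 0.25, slope 4.0 Mg ha⁻¹ per unit canopy fraction,
residual SD 0.30, canopy fraction 0.55 (CP) / 0.66 (CA) with SD 0.12.
These variance components are not published anywhere; they were chosen once
so that (a) the CA−CP direction and approximate magnitude match a typical
long-term tillage contrast, and (b) within-arm correlations between
greenness and yield land near 0.8 under CP, the range such trials report.

Scene rendering: each plot image partitions its pixels among four classes —
green canopy (hue ≈ 127°), senescent canopy (hue ≈ 66°: inside GA, outside
GGA), soil (hue ≈ 25°) and residue straw (hue ≈ 47°, pale) — by *random*
labelling with exact integer counts (largest-remainder rounding keeps every
realized fraction within one pixel of the request). There is no spatial
texture: every downstream index is order-invariant over pixels, so texture
would add cost without adding test power. The multispectral spectra give
green canopy NDVI 0.82, senescent canopy 0.56, soil 0.16 and residue 0.15 —
both canopy classes clear the 0.4 mask threshold and both backgrounds fall
below it with margin ≥ 0.15, so the mask separates classes by construction
and still does so comfortably at the default reflectance noise (SD 0.01).
RGB and multispectral renderings of one plot share class fractions but not
pixel positions (the cameras were never co-registered). Thermal rasters put
canopy at the plot's canopy temperature and background 5 °C warmer.

The CA noise channel: the background brightness multiplier (applied to
soil and residue in both RGB and reflectance renderings) has SD 0.20 under
CA versus 0.06 under CP, emulating the heterogeneous brightness of
weathered, partially shadowed stover against uniform ploughed soil.
Brightness scaling preserves band ratios, so it barely moves arm means but
injects yield-independent variance into whole-plot reflectance indexes —
this is what makes plot-mode index–yield correlations weaker under CA than
CP, and what the NDVI mask then removes. Hue is invariant to brightness
scaling, so the RGB hue-based indexes (GA/GGA) stay robust under CA, which
is exactly the behaviour that motivates RGB indexes for residue-covered
systems.

What a green test establishes — and what it does not: the generator has no
spatial structure, no mixed pixels at canopy edges, no specular highlights
or shadows, no atmospheric or illumination drift, and its class spectra are
fixed points rather than distributions. Green tests therefore establish
that the *computational* chain (conversion, masking, aggregation,
statistics) is correct and that the pipeline detects the planted
statistical structure; they say nothing about segmentation quality on real
imagery. Known limitation: in real trials vegetation cover can be *lower*
under CA while NDVI is higher (canopy quality and cover dissociate); the
generator drives both through one canopy-fraction lever, so its cover
direction follows canopy.

## 6. Numerical and design choices

* Coordinates are 0-based, row-major, origin top-left; ROIs are half-open
  `(row0, col0, row1, col1)` rectangles — half-open slicing avoids
  off-by-one area errors and composes cleanly.
* Bands are identified by TIFF page order (ascending wavelength), not
  metadata — robust across writers.
* Determinism: every generator consumes a `numpy` `default_rng` seeded from
  the run seed plus fixed per-stage/per-plot offsets, so toggling one stage
  never perturbs another; two runs with the same config produce
  byte-identical CSVs.
* The acceptance/test suites render reduced-size scenes (e.g. 60×88 RGB,
  40×58 multispectral) instead of the full 825×1210 default: class-count
  exactness is resolution-independent, and only rounding granularity
  (< 1 pixel) changes with size.
* Reflectance validation range [0, 1.2]: small overshoots above 1 are
  routine after empirical reflectance calibration; beyond that the file is
  treated as mis-scaled.
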