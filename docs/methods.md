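# Methods

This note documents the models implemented in `esbalance`, the defaults and
their rationale, the numerical choices, and what the synthetic tests do and
do not establish about real data.

## Supply: equivalent-factor valuation

Supply is valued as *ESV = Σₖ Aₖ·VCₖₛ* over six primary land-use classes
(cultivated land, woodland, grassland, water, construction land, unused
land) and nine services. The packaged coefficient table is the published
equivalent-factor set for a large subtropical river-basin region;
construction land is valued at zero by construction. Users substitute their
own calibration by passing a CSV with the same `land_class, service,
coefficient` schema — the package performs no regional re-calibration of
equivalent factors.

The unit chain is fixed: areas in km² (cell count × nominal cell area,
default 1 km² — raster-native accounting; a boundary cell belongs wholly to
the zone of its center), ×100 to hm², × coefficient in yuan hm⁻² a⁻¹,
reported in 10⁸ yuan. All arithmetic is done at full precision; rounding
(half away from zero, two decimals — table convention, not banker's
rounding) happens only at reporting. Change percentages are Δ/start × 100;
a zero start with a nonzero end is reported as Δ with an undefined-percent
flag rather than an infinity.

Reproduction tolerance against printed reference tables is ±0.02 × 10⁸
yuan, the propagation of areas printed to whole km². A handful of printed
cells (the unused-land levels for 2010/2015/2020 and the totals they feed)
are not derivable from the printed inputs at any tolerance — the source
tables disagree with each other there — and the package reports the
computed values.

## Demand: land use × population × nightlights

Per zone, *X = D · log(P) · log(c·NLCI)* with

- *D* — built-up (construction-land) percentage of zone area;
- *P* — zone population total divided by zone area. For equal-area cells
  this equals the zone-mean density, so the distinction between "mean
  density" and "total over area" is immaterial on regular grids; the
  total-over-area definition is the one implemented;
- *NLCI = P₁·I + P₂·S*, weights 0.8/0.2. *I* is Σ DNⱼNⱼ / (N_t·63) over lit
  pixels (1 ≤ DN ≤ 63) and *S = N_t/N*. With no lit pixels the 0/0 ratio is
  defined as *I = 0*: a dark zone has zero light intensity, matching the
  behaviour of composite-index studies in data-gap areas.

Three numerical choices make the product well defined, all exposed as
configuration and recorded in run metadata:

- **log base** — base 10 (`log_base`). The index is relative, so the base
  only rescales it; it must simply be fixed for reproducibility.
- **NLCI scaling** — *NLCI* ∈ [0, 1] has a negative log, so the light term
  uses *c·NLCI* with *c* = 100 (`nlci_scale`), i.e. the log of a percent
  index.
- **floors** — both log arguments are floored at 1 (`pop_floor`,
  `nlci_floor`), so empty or unlit zones contribute zero, not negative,
  demand, and *X* is monotone non-decreasing in each of *D*, *P*, *NLCI*
  and identically zero when *D* = 0.

DN rasters must be integers in [0, 63] (the DMSP-OLS gray-level range);
out-of-range input raises an error that points at un-rescaled VIIRS
radiance, and `rescale_to_dn` clips at a saturation percentile (default
99th) and rescales linearly onto [0, 63]. No cross-sensor intercalibration
beyond this rescaling is attempted.

## Balance index and natural-breaks typologies

*BI = supply − demand* per zone-year. Monetary supply and the dimensionless
demand index are incommensurate, so the default `normalized` mode min–max
scales both sides within each year before subtracting (*BI* ∈ [−1, 1],
antisymmetric under swapping supply and demand); `raw` mode subtracts
literally for users who pre-scale their own inputs. A constant side
normalises to all-zeros (no information, no spurious ordering).

Classification uses the Fisher–Jenks optimal partition: an exact O(k·n²)
dynamic programme over prefix sums minimising total within-class SSD of the
sorted sample, deterministic with earliest-split tie-breaking, and verified
in the tests against exhaustive enumeration of all contiguous partitions.
Supply and demand are graded on k = 5 levels (low, lower, general, higher,
high); BI on a k = 7 typology. The seven classes are Jenks classes on BI
with the class containing zero (or the terminal class nearest zero) named
"balance", those above it general/higher/high **surplus** and below it
general/higher/high **deficit** — a published seven-name typology gives the
names but no cut rule, and Jenks-plus-zero-anchoring is the documented
default here. Ties at a break value fall in the lower class; values outside
the fitted range go to the nearest terminal class with a logged warning;
samples with fewer distinct values than classes collapse to that many
classes (all-equal BI yields the single class "balance"). Breaks are refit
per year by default (year-by-year maps); a pooled fit across years is
available for temporal comparability.

## Quantile regression of the balance index

*Q_θ(Y|X) = X′β(θ)* with Y the balance index and X an intercept plus
land-use proportions. β(θ) minimises the check loss Σ ρ_θ(u),
ρ_θ(u) = u(θ − 1{u<0}), solved as the exact primal LP (positive/negative
residual split) with the HiGHS solver: the contract is objective-value
optimality, verified in the tests against the basic-solution vertex
enumeration for small problems and against an independent IRLS
implementation. OLS is fitted alongside for the mean effect. Standard
errors are x–y pair bootstrap (seeded, default 1000 resamples; 200 in the
demo config to keep it quick), with normal-approximation p-values and stars
at the 10/5/1% two-sided levels. Quantile crossings are not corrected, only
counted in diagnostics.

Compositional covariates summing to one are collinear with the intercept,
so proportions always enter as a sub-composition: the synthetic regression
dataset draws an 11-category Dirichlet and keeps ten named classes, and the
pipeline stage drops the largest-share primary class as the reference
category. Rank deficiency is detected up front and the offending columns
named. The pipeline pools all years into one regression (zone-years as
observations) — the multi-year pooled design maximises n at county scale;
per-year fits are available by filtering the input.

## Synthetic landscapes

The generator emulates the data model of a kilometre-grid regional study:

- **Land use** — an initial multinomial draw at configured class
  proportions (defaults ≈ 0.31 cultivated / 0.46 woodland / 0.17 grassland
  / 0.03 water / 0.02 construction / 0.01 unused, the composition of a
  large mixed river-basin region), then per-interval independent cell-level
  Markov transitions. Default rates encode the observed qualitative
  dynamic: construction expanding mainly from cultivated land (0.02 per
  5-year interval) and grassland, slight water growth. Class shares
  therefore follow the closed-form chain *p₀Tⁿ* in expectation, which the
  tests check at 3 binomial standard deviations.
- **Zones** — Voronoi cells of seeded k-means centroids on cell
  coordinates: contiguous, space-filling, county-like units, relabelled
  deterministically by centroid position.
- **Population** — base density × class multiplier × lognormal noise,
  static at the first-year cover; construction cells carry the largest
  multiplier (40×) so demand hot-spots co-locate with built-up land.
- **Nightlight** — per year, DN ~ Normal(class mean + 4·log₁₀(1+pop), sd 3),
  rounded and clipped to [0, 63]; construction ≈ DN 45, dark natural
  classes ≈ DN 0–2.

What it does **not** emulate: spatial autocorrelation of land cover within
classes, realistic terrain or climate gradients, sensor artefacts (blooming,
saturation, the DMSP→VIIRS transition), migration, or any feedback of
demand on land conversion. Passing tests therefore establish the internal
correctness of the accounting, indexing, classification and estimation
chain — not the ecological validity of the coefficients or the demand proxy
on any real landscape.

Problem sizes used in the shipped configurations — a 48×48 demo grid with
12 zones and 5 dates, 500-zone regression datasets, 200–300 bootstrap
resamples in tests — are chosen to exercise every code path at desk scale;
all sizes are plain configuration and scale up unchanged.

## Known limitations

- The equivalent-factor method inherits the published coefficients; no
  actual-vs-potential supply distinction, no demand-side preference
  modelling, no ecosystem-service flows between zones.
- The demand index is ordinal in spirit; its magnitude depends on the
  documented base/scale/floor conventions, so only comparisons under one
  configuration are meaningful.
- Jenks classes are refit per year by default, so class labels are not
  directly comparable across years unless the pooled-breaks option is used.
- The raster I/O is plain multi-band TIFF plus a YAML sidecar; coordinate
  reference systems are out of scope, and zone geometry is carried as a
  label raster rather than vector polygons.
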