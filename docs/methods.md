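# Methods

## Accounting model

The package implements plot-based, design-stratified stock accounting for
aboveground woody carbon and nitrogen. The estimand per LULC class ℓ is the
mean element density (Mg/ha) over the class's area, estimated as the
arithmetic mean of per-plot densities with standard error SD/√n_ℓ, and the
class total as density × mapped class area. The assumptions are the usual
ones of this design: plots are a random (here: area-proportional) sample of
each class, classes are disjoint strata sampled independently (hence the
quadrature rule for the SE of sums over classes), and within a class the plot
densities are exchangeable. Uncertainty from the allometric models and from
the trait fractions is *not* propagated into the stock SEs — the reported ε
is sampling error between plots only.

Because all plots within a class share one size, averaging per-plot
*densities* equals averaging per-plot stocks and dividing by the plot area;
the density form is implemented so that registers with mixed plot sizes
remain unit-coherent.

Treeless plots are legitimate zero observations and stay in the estimate;
dropping them would bias sparse classes (grassland, cropland) upward — their
published minimum densities near 0.03 Mg/ha imply near-empty plots exist.

## Trait fractions

Fractions are proportions of oven-dry matter, stored in (0, 1); percent
appears only in CSVs mirroring printed tables. Per species the summary is
mean, SE (= sample SD with n−1 denominator over √n; 0 with a warning for
n = 1), min and max, for carbon, nitrogen, and the per-sample C/N ratio.

The overall mean used as the fallback for unsampled species is, by default,
the **unweighted mean of species means** (`weighting="species"`), which is
the convention under which the packaged 18-species table yields 47.01 % C and
0.229 % N; `weighting="samples"` gives the sample-count-weighted alternative
(47.00 % / 0.2255 %). Species matching is case-insensitive and
whitespace-collapsed; open nomenclature ("Ficus sp") matches literally.

## Allometry

Three functional forms are supported — `power_product`
B = a·(ρD²H)^b, `power_dbh` B = a·D^b, and `linear_combination`
B = a + b·D + c·D² for palms, which do not follow D²H scaling. Models are
configuration (YAML), routed species-specific → LULC-specific → default;
the shipped default is the generic pantropical power-product
B = 0.0673·(ρD²H)^0.976. DBH outside a model's fitted range extrapolates
with a warning rather than failing, because census DBH ranges routinely
exceed fitting ranges and a hard failure would silently truncate stocks.
Units are fixed: kg per tree, Mg (10³ kg) from plot level up.

## Importance Value Index

Curtis–McIntosh convention: relative density (share of stems), relative
frequency (share of plot occurrences), relative dominance (share of basal
area, π(DBH/200)² m²), each in percent; IVI is their sum, so components each
sum to 100 and IVI to 300. Output is sorted by IVI descending with
alphabetical tie-break.

## Tier-1 coefficient analysis

A fixed biomass→carbon coefficient c applied to a class whose effective
(biomass-weighted, ΣC/ΣB) carbon fraction is f errs by
error(c) = 100·(c/f − 1). The biomass-weighted fraction, not the
tree-averaged one, is the right comparator because mean carbon density is a
biomass-weighted quantity. Two published error percentages for the same
class (at 0.5 and 0.47) are algebraically linked —
error(0.47) = 100·(0.94·(1 + error(0.5)/100) − 1) — so the audit routine
recomputes one from the other and flags pairs that violate the identity
beyond ±0.02 percentage points (the slack two-decimal rounding can
introduce). In the reference pair set, exactly one class (Shrub Savannah,
6.41 → 0.54; implied 0.03) fails the check and is flagged rather than
silently accepted.

## Synthetic-data generator

The generator defines the package's study conditions; every statistical test
runs against it.

**Traits.** Per species, carbon and nitrogen fractions are drawn from a
normal truncated to the published [min, max], with location the published
mean and scale SD = SE·√n — the simplest model consistent with all four
printed statistics. Sample counts are the published n (277 total across 18
species). Note the generating *truth* for a sample mean is the truncated
normal's expectation, which truncation can shift off the nominal location;
recovery tests compare against that expectation.

**Stands.** The plot design is the reference design verbatim: 250 plots over
8 classes (30 × 30 m in forest, grassland and cropland; 100 × 100 m in
settlements; 10 × 20 m in agroforestry and plantations; 27.26 ha sampled in
total). Stem counts per plot are negative-binomial (dispersion k = 5,
moderately overdispersed — published per-class min/max density ranges imply
strong between-plot variability) with mean stems/ha × plot area; the two
published class densities are used directly (1397/ha riparian, 300/ha cashew
agroforestry) and the remaining rates are set to values realistic for the
vegetation type (800 woodland, 600 shrub savannah, 30 grassland, 25
cropland, 60 settlements, 1100 plantation). DBH is log-normal truncated to
[5 cm, class max]; height follows H = h₀·D^h₁·exp(ε) (h₀ = 2.5, h₁ = 0.55,
σ_ε = 0.25); wood density is normal around a per-species mean (σ = 0.05
g/cm³, clipped to [0.1, 1.5]). Species mixes per class are fixed plausible
compositions over the 18-species table (e.g. cashew monoculture in
agroforestry, neem-dominated settlements, shea/néré parkland in cropland).

**Calibration.** Each class carries a target mean carbon density — the
published class means (21.35 Mg/ha for Savannah Woodland, where the printed
table and text disagree at 21.25/21.35, the text value; the plantation class
uses the area-weighted mean of its published species-level figures,
≈ 89.9 Mg/ha). The generator hits its target in expectation by scaling the
class's allometric coefficient a_ℓ so that stems/ha × E[f_C·(ρD²H)^0.976] ×
a_ℓ / 1000 equals the target. The expectation is computed by Monte-Carlo
over the tree-mark distribution with a *fixed internal seed* and 5·10⁵
draws, so calibration is deterministic and independent of the user's seed
(relative MC error ≲ 0.3 %, negligible against between-plot SEs of 5–10 %).
The calibrated registry is part of the generated study and must be used when
running the pipeline on the synthetic census.

**Class map.** A categorical raster stand-in for a classified satellite map:
each class receives round(area / cell area) cells — within half a cell of
the area table — laid out contiguously along a boustrophedon scan
(consecutive scan cells are 4-adjacent, so every class is a connected
region), with class order a seeded permutation. Stock maps assign each cell
its class's mean density (class-constant surfaces, not per-pixel biomass)
and are written as ESRI ASCII grids, a plain-text raster format any desktop
GIS reads.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spatial autocorrelation between neighbouring
plots, within-plot size structure (no stem coordinates, no multi-stemmed
individuals), species–size interactions (DBH is drawn independently of
species within a class), measurement error in DBH/height/density, and any
allometric model error (the pipeline evaluates the same family the generator
used). Tests therefore validate the accounting arithmetic, the estimators'
sampling properties and the plumbing, not allometric adequacy for a real
forest.

## Numerical and design choices

- SE of a mean is sample SD (n−1) over √n throughout; n = 1 yields SE 0 with
  a warning rather than NaN, keeping summaries total.
- Ties in IVI sorting break alphabetically; fraction comparisons use exact
  float arithmetic (no rounding until I/O, where printed tables get
  2-decimal display columns plus full-precision companions).
- The landscape grand-total SE is the quadrature combination of class SEs.
  Published total-stock SEs in the reference tables cannot be reproduced by
  this (or the density×area) rule, so no test or target chases them.
- Problem sizes: the default synthetic study is the full 250-plot design
  (~7,300 stems); the recovery study uses its two contrasting strata
  (80 cropland + 27 woodland plots) over 200 replicates, sizes at which the
  3-SE coverage criterion is comfortably normal-theory valid.

## Known limitations

- No uncertainty propagation from allometry or trait SEs; no belowground,
  soil, deadwood or litter pools; single epoch (no change estimation).
- The fallback fraction is a single overall mean; a phylogenetic or
  trait-imputation fallback would be better for floristically distinct
  censuses.
- The palm default equation is a placeholder family; users with palms should
  supply locally fitted coefficients via the registry YAML.
- ESRI ASCII grids carry no CRS; georeferencing is limited to corner/cell
  size copied from the input.
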