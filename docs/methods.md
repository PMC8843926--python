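# Methods

## The retrieval problem

Chlorophyll-a in inland waters spans four to five orders of magnitude, and
the optical signal changes character across that range.  In clear water the
blue/green reflectance ratio that neural-network inversions such as C2RCC
exploit is informative, but in dense blooms the water-leaving signal is
dominated by the red/NIR fluorescence-and-scattering peak near 700 nm.  The
package therefore treats the two retrievals as complementary instruments
and merges them per pixel.  C2RCC itself is *not* implemented here: its
chl-a output and validity flag are opaque inputs.

## MPH index

For a pixel's bottom-of-Rayleigh reflectance (BRR — Rayleigh-corrected but
not aerosol-corrected reflectance) at the nominal bands 664, 681, 709, 753
and 885 nm, the Maximum Peak Height is the height of the largest of the
three candidate peak bands (681, 709, 753 nm) above the straight baseline
drawn from 664 to 885 nm:

    MPH = BRR_max − BRR_664 − (BRR_885 − BRR_664)·(λ_max − λ_664)/(λ_885 − λ_664)

evaluated with the sensor's actual band-center wavelengths.  The nominal →
actual mapping is configuration, not code: MERIS centers equal the nominal
labels; the OLCI defaults (665, 681.25, 708.75, 753.75, 885 nm) may be
overridden per spectrum.  Two properties make the index robust and are
enforced by property tests: adding a constant to all bands leaves it
unchanged (it is a difference of baseline-corrected terms), and scaling all
bands scales it linearly.

Chl-a follows from the single recalibration cubic

    chl-a = 848468·MPH³ − 72058·MPH² + 5515.7·MPH   [µg L⁻¹]

whose derivative has negative discriminant (minimum slope ≈ 3475.8 per unit
MPH), so it is strictly increasing over the reals and invertible — the
synthetic forward model relies on this.  Negative MPH yields negative
chl-a; by default that is clamped to the invalid marker (NaN), switchable
with `clamp_negative=False`.  Peak-band ties break toward the shorter
wavelength; with degenerate near-ties (differences at the 1e-15 level) the
winner is decided by floating-point comparison, which is why the invariance
tests require a well-separated peak.

## Merge rule

For thresholds (x, y) = (C2RCC max, MPH min), a pixel's merged value is

1. the MPH(P) chl-a, if valid and strictly **>** y (tag `MPH`);
2. else the C2RCC chl-a, if valid and strictly **<** x (tag `C2RCC`);
3. else invalid (tag `NONE`).

Values exactly at a threshold fall through to the next branch.  An invalid
MPH value routes to the C2RCC test rather than discarding the pixel.  The
output is always one of the two inputs or NaN — never a blend.  Presets
C_15-M_10 (error-optimal), C_50-M_10 and C_50-M_15 ship built in.

## Validation metrics

Because retrieval error is roughly proportional to concentration, errors
are scored multiplicatively in log10 space:

    MAE_mult  = 10^(mean |log10 M_i − log10 O_i|)    (≥ 1, 1 = perfect)
    bias_mult = 10^(mean (log10 M_i − log10 O_i))    (<1 under-, >1 over-estimation)

Non-positive values are a hard error naming the offending record; exclusion
of non-positive chl-a happens upstream in the match-up builder where it is
tallied, never silently inside the metrics.  `|1 − bias_mult|` is available
as a presentation transform only.

## Threshold grid search

`grid_search` scores every (MPH-min, C2RCC-max) pair — default 1–50 µg L⁻¹
in 1 µg L⁻¹ steps on both axes, covering all shipped presets — by applying
the merge per record, dropping discarded records, and computing MAE_mult
over the survivors.  Survivorship is recomputed per cell, matching the
merge semantics.  Cells retaining fewer than `min_n` records (default 10)
are excluded from the argmin: tiny survivor sets make MAE_mult
incomparable.  Ties break deterministically: larger n, then smaller
MPH-min, then smaller C2RCC-max.

### Identifiability of the threshold pair

A subtlety documented here because it shaped the synthetic study design: a
*survivor-only* error statistic rewards any configuration that simply
discards an above-average-noise subpopulation, so for many plausible error
structures the MAE surface has exact plateaus (threshold moves that change
no record's routing) or is minimized by degenerate corners ("use only the
cleanest algorithm's cleanest range").  Under such structures the
generative crossover pair is not identifiable by *any* estimator of this
form.  The strong-contrast generator (`synthetic.recovery_matchups`) is
therefore constructed so that every unit threshold move changes the
survivor set in a direction with a strict, sign-known effect:

- **Graded MPH low-range bias** `(t/τ_M)^4` keeps MPH outputs continuous
  through the crossover, so lowering the MPH minimum below τ_M always
  admits records with strictly positive bias (no plateau from output gaps).
- **High-biomass observation error** (log10 SD 0.25 above τ_C, emulating
  the unrepresentativeness of point samples in patchy blooms) attaches to
  records rather than branches.  No threshold choice can shed it, so the
  baseline MAE stays above the low/mid-range C2RCC noise and cutting
  accurate C2RCC records below τ_C always raises the mean.
- **C2RCC saturation to a low background** (τ_C/3, log10 SD 0.3) above its
  crossover: configurations that route high-biomass records into the C2RCC
  branch admit them as strongly erroneous survivors, so "discard the MPH
  branch" cells lose.
- **Low-signal MPH invalidity** (15 % below τ_C) populates the C2RCC branch
  with accurate mid-range values up to τ_C, and a slight mid-range C2RCC
  degradation (0.95 bias between the crossovers) penalizes routing the
  both-good overlap band away from MPH while keeping good C2RCC outputs
  below τ_C, so the windows just above τ_C are empty and the deterministic
  tie-break settles at the crossover.

With n = 2000 records per replicate and `min_n = 50` (excluding degenerate
sub-3 % survivor corners), the search recovers the generative pair within
one grid step in ≥ 95 % of replicates (119/120 across six independent
20-seed blocks at design time; the modal optimum is the exact pair).

## Match-up quality assurance

The builder consumes WQP-style record tables (configurable column map) and
scene stacks, and applies, in order, with a conserved per-rule tally at
every stage (input = retained + Σ rejected):

1. **Deduplication** of identical rows (pseudo-replicated submissions).
2. **Pigment**: the characteristic must normalize into an editable
   chlorophyll-a synonym list; chlorophyll-b/-c and phaeophytin are
   rejected (broadband sensors cannot separate accessory pigments).
3. **Value**: finite and > 0.  Values above 50 000 µg L⁻¹ (beyond
   wind-concentrated surface scums) are flagged `implausible` but retained
   — in practice the spatial filters remove them.
4. **Depth**: ≤ 2 m or the literal label "surface" (the label wins);
   records with no depth information are rejected.
5. **Time**: records without a clock time are imputed at 12:00 local; the
   local→UTC offset comes from a `timezone_offset_h` column or, failing
   that, `round(longitude/15)`.  Records without a date are rejected.
6. **Temporal pairing**: nearest-in-time scene with |Δt| ≤ 6 h (ties to the
   earlier overpass); one match-up per record, avoiding pseudo-replication
   when several overpasses qualify.
7. **Pixel extraction**: the containing pixel under a half-open 300-m grid
   convention (boundary points belong to the higher-index pixel,
   deterministic in projected meters); the pixel and all 8 neighbors must
   be pure water — not land, not within 2 pixels (600 m) of land, not
   cloud/snow-ice flagged.  Border pixels fail (incomplete neighborhood).

Multiple surviving records in one pixel of one scene are kept as separate
match-ups by default; `average_per_pixel=True` collapses them to a mean.

## Raster operators

- **Shoreline erosion**: land dilated n times (default 2) with the
  8-connected structuring element, matching the 8-neighbor purity rule;
  off-grid is treated as land.  Equivalent to flagging water pixels whose
  Chebyshev distance to land is ≤ n (checked against a brute-force oracle).
- **Resolvable lakes**: ≥ 3 pure pixels after erosion.
- **Composites**: per-pixel mean/SD/count over dates, excluding flagged
  (cloud, mixed, snow-ice), non-finite and non-water observations; months
  are calendar months in scene-local civil time.  SD is the population
  estimator by default (a descriptive spread, ±1 SD), switchable to the
  sample estimator.
- **Buffer averaging**: pixels whose *centers* lie within the radius
  (default 300 m) of the point — a deterministic convention; partial-pixel
  weighting is deliberately not attempted at 300-m resolution.
- **Trophic classes** (NLA): oligotrophic ≤ 2 < mesotrophic ≤ 7 <
  eutrophic ≤ 30 < hypereutrophic (µg L⁻¹), upper bounds inclusive; the
  classes partition (0, ∞) and non-positive input is invalid.
- **Lake summaries**: means over pure-water valid pixels only (shoreline
  pixels are the most contaminated; a `pure_mask=None` call uses all valid
  pixels), deterministic ranking with lake-id tie-break, and per-period
  trophic-state fractions.

## Synthetic data

The generator produces every input the pipeline needs, deterministically
from an explicit `numpy.random.Generator` (no global state):

- **Scenes**: elliptical lakes on a land grid (degenerate axes are a hard
  error), constant / gradient / smoothed log-normal truth fields, and
  spatially coherent cloud and snow-ice flag masks hitting a prescribed
  areal fraction.  Default truth fields span roughly 0.1–872 µg L⁻¹, the
  range a national-scale in situ match-up set plausibly covers.
- **BRR forward model**: a flat baseline (0.02) plus a 709-nm peak whose
  height is the cubic's unique root for the target chl-a (80 bisection
  steps on a bracket guaranteed by the minimum slope).  With a flat
  baseline the MPH baseline term vanishes, so retrieval inverts the
  forward model exactly; round-trip agreement is ≤ 1e-6 relative over
  0.1–300 µg L⁻¹.
- **Error model** (`ErrorModel`): multiplicative log-normal noise (errors
  proportional to concentration) with regime structure — MPH
  underestimation below its crossover (graded exponent and/or constant
  factor), C2RCC overestimation at low/mid range (default factor 1.16), an
  optional high-range degradation, a saturation ceiling (default
  100 µg L⁻¹) and per-algorithm invalidity probabilities.
- **In situ tables**: records placed at interior pure pixels of a scene,
  timestamped inside the overpass window, with disjoint record subsets
  assigned exactly one violation each (wrong pigment, 5-m depth, off-window
  time, shoreline placement, missing clock time) so QA survivor counts are
  exact by construction.  Missing-time records stay compliant because the
  bundled scenes place the overpass within 6 h of local noon; the generator
  raises if a recipe violates that assumption rather than silently
  producing an uncountable fixture.

What the synthetic data does *not* emulate: aerosol and adjacency radiative
transfer (BRR is constructed, not simulated), sensor noise and striping,
cloud-shadow geometry, vertically structured blooms, and the spatial
autocorrelation of real in situ sampling programs.  Passing tests therefore
demonstrate the correctness of the *operators* (index arithmetic, merge
logic, filters, audits, search), not the field accuracy of the retrievals.

## Numerical and design choices

- Invalid marker is NaN everywhere; validity flags and NaN are normalized
  to agree at type boundaries.
- Pure-arithmetic oracles (index transliteration, natural-log metric
  re-implementation) agree to 1e-12 relative.
- Raster I/O is NetCDF (classic format via xarray/scipy); tables are UTF-8
  CSV with ISO-8601 dates normalized on read.  GeoTIFF is not supported.
- The CLI is a thin shell over library calls; every run logs the package
  version, a hash of the fully resolved configuration (also written next
  to each output) and the seed.

## Problem sizes

The bundled studies use 40×40-pixel scenes (12 km at 300 m), 100-record
in situ tables, 200-record grid-search fixtures, and 20 × 2000-record
replicates for threshold recovery — sizes chosen so the full suite and the
acceptance script each complete in seconds while every operator still
exercises its edge cases (border pixels, eroded-away lakes, empty windows,
degenerate survivor cells).

## Known limitations

- The C2RCC and IdePix processors are consumed as inputs; their internal
  quality semantics are reduced to a boolean validity here.
- A single projected grid per stack with a local equirectangular
  lon/lat mapping; no reprojection or datum handling.
- The original MPH cyanobacteria/eukaryote branch logic, float/scum
  immersion flags and region-specific recalibrations are out of scope —
  only the single-cubic recalibration is implemented.
- Threshold optimization is a pooled exhaustive grid; no cross-validation
  or regional stratification.
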