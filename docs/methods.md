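# Methods

## Data model

All layers share one regular north-up grid (`GridGeometry`; default 250 m
pixels, i.e. 6.25 ha / 0.0625 km² each). A fire history is a contiguous run
of calendar years with one binary burnt mask per year per season. Seasons
are calendar-defined: months 1–7 are early dry season (EDS), months 8–12
late dry season (LDS); wet-season burns therefore count as EDS. A pixel is
binary within a season — repeated burns of the same pixel in one season are
not resolvable at this mapping scale and collapse to one. Nodata in input
rasters is read as unburnt (it biases frequency conservatively) and logged.

Landscape units (lowland vs upland savanna) are rasterized from polygons by
pixel-centre containment; overlapping polygons resolve last-wins with a
warning. Pixels outside both units are excluded from every unit-normalized
metric.

## Fire-regime metrics

**Seasonal frequency.** For unit *u* and an assessment window of *n* years
(default 5, non-overlapping consecutive windows), the per-year statistic is
the burnt fraction of the unit; the reported frequency is its mean over the
window and the SEM is the sample standard deviation across the *n* yearly
values divided by √n. This is algebraically identical to the mean per-pixel
count of burnt years divided by *n*; the tests verify both routes agree
exactly. The annual mask is the pixelwise EDS ∪ LDS union, so annual
frequency is bounded below by each seasonal frequency and above by their
sum. Empty units yield flagged invalid summaries, never silent NaNs.

**Long-unburnt habitat.** Time since last burnt (TSLB) is whole years; a
pixel burnt in the assessment year has TSLB 0, and a pixel never burnt in
the available record is right-censored at (as_of_year − first_year + 1).
"Unburnt for ≥ N years at the end of year Y" means no burn in years
Y−N+1 … Y inclusive — with histories starting at the first mapped year this
makes the ≥5-year proportion computable at the end of the first 5-year
window, and censoring handles deeper lookbacks naturally. The ≥5 proportion
can never exceed the ≥3 proportion.

**Patch metrics.** A contiguously burnt area (CBA) is a maximal 8-connected
(orthogonal + diagonal) component of a seasonal or annual mask, labeled
with `scipy.ndimage.label` using a 3×3 structuring element; labels follow
row-major order of each patch's first pixel, so ids are deterministic.
Patch statistics (mean size, annual count, each ± SEM over window years)
are site-level; years with zero patches contribute zero to the count series
but are excluded from the size series and flagged. Size-class distributions
assign each CBA to a class by its *total* size — a mega-fire straddling the
unit boundary is one patch, not two — while the area credited to a unit is
only the part inside it, normalized by unit area. Default classes
(0,1], (1,10], (10,100], (100,1000], >1000 km² are the minimal decadal
scheme containing the <1 km² ecological guideline and the 10 and 1000 km²
reporting boundaries. Per year, class proportions sum exactly to the unit's
burnt fraction (a conservation law the tests enforce).

## Threshold assessment

Rules are data (id, metric, unit scope, comparator, threshold, context),
loadable from YAML/JSON; the shipped defaults encode the published
guidelines: annual frequency ≤ 0.3 y⁻¹ (fauna, both units), < 0.2 y⁻¹
(upland obligate seeders), LDS frequency < 0.2 y⁻¹ (*Callitris*; raw LDS
frequency is used — the literature notes an LDS fire is severe with
probability 0.81, recorded in the rule's context rather than deflating the
frequency), unburnt ≥3 y proportion ≥ 0.25 (lowland) / ≥ 0.40 (upland),
mean patch size < 1 km², and the deliberately strict "≪ 10 km²"
small-mammal guideline encoded as < 10 km². Verdicts use point estimates
(means), matching how such comparisons are made narratively; SEMs ride
along for context. A missing metric yields NOT-ASSESSABLE. A fire-free
window has no patches; the pipeline reports its mean patch size as 0, so a
unit with no fires passes every rule.

## Carbon accounting

Accountable emissions are modelled at seasonal-factor level:
`E = f_LDS · (r · A_EDS + A_LDS)` with r = f_EDS/f_LDS defaulting to 0.5
(EDS fire yields ~50% less accountable emissions per hectare). The
fuel-type and fuel-load detail of the accredited regulatory methods is
deliberately collapsed into the configurable `f_LDS`; the package claims
arithmetic fidelity to this model, not regulatory-method fidelity, and
`f_LDS` defaults to a placeholder 1.0 t CO₂-e ha⁻¹ with a logged warning —
relative reductions are factor-free. Abatement credits are mean annual
baseline emissions (nominally 10 pre-project years) minus mean project
emissions, floored at zero; a scenario mode applies a flat reduction
fraction (default 0.38, the documented realized reduction of the first
seven project years in West Arnhem Land) to baseline emissions.
Sequestration methods (woody-fuel and living-tree pools) are area ×
annualized rate, or a stock change annualized over a horizon (default
25 years). The three methods account for disjoint pools and add. Intervals
are a normal approximation, estimate × (1 ± 1.96·CV), CV default 0.16,
floored at zero. Example per-hectare rates can be derived from the
published indicative credit table (credits ÷ area) and are labelled implied
rates; one published row (Kakadu lowland) is internally inconsistent by
4×10³ credits (component sum 890 vs printed total 886, a rounding artefact
in the source) and is excluded from exact cross-checks.

## Synthetic fire-history generator

The generator emulates seasonal burn mosaics with controlled statistics.
Per year and season, the target burnt area is the unit area × target
fraction × seasonal share. Ignition count is Poisson with intensity
rescaled by the configured mean patch size so expected burnt area equals
the target — patchiness (ignition density) and extent are thereby
independent dials. Patch sizes are lognormal (default mean 4 km²,
σ = 1.3, truncated at unit area; a truncated power law is also available).
The heavy tail makes a few large fires dominate burnt area, as observed in
savanna fire mapping; the defaults keep the year-to-year variance small
enough that a 15-year mean on a 500×500 grid recovers the configured burnt
fraction to within ±2 percentage points and the LDS share within ±5.

Patches grow by stochastic frontier growth: from a uniformly chosen
available start pixel, a uniformly random frontier pixel joins the patch
each step under 8-connectivity, stopping at the sampled size or when the
frontier empties. EDS patches are placed first; by default
(`coalescence=False`) LDS fires cannot enter EDS-burnt pixels, so early
burning acts as a fuel break on late fires — the mechanism by which
strategic EDS programs reduce LDS extent. Two implementation details
matter for the statistical contract:

- each season's ignition plan (count, sizes, per-ignition child seeds) is
  drawn from a season-dedicated RNG stream, so at fixed seed the LDS plan
  is independent of EDS parameters and increasing EDS burning cannot
  (statistically) increase LDS extent;
- a patch enclosed by earlier burnt ground realizes fewer pixels than its
  sampled size, which would bias realized area low by ~1 pp at ~35% annual
  extent; per-season top-up ignitions from a dedicated substream replace
  the shortfall until the realized area matches the season's
  compound-Poisson draw.

Saturation (target fraction 1) burns every in-unit pixel, assigning each
pixel's season by a Bernoulli draw on the LDS share. An optional lognormal
year-effect multiplier adds boom-and-bust interannual variability; it is
off by default as no quantitative value is documented. Everything is
deterministic given (grid, units, params, n_years, seed), with no global
RNG state.

**What the generator does not emulate:** physical spread (wind, fuel
moisture, terrain), fuel-age feedbacks between years, the spatial
clustering of ignitions along access routes, sensor artefacts of real
burnt-area classification, and real landscape-unit geometry (the synthetic
stratification is a columnwise split). Passing tests therefore demonstrate
correctness of the metric and accounting computations and the generator's
own calibration — not fidelity of any simulated landscape to a specific
real fire regime beyond its summary statistics.

## Numerical and interface choices

- SEMs use the sample (ddof = 1) standard deviation; single-year windows
  report SEM 0.
- Windowed statistics are exact rational arithmetic in floating point — no
  resampling or smoothing anywhere.
- Raster I/O: single-band TIFF via tifffile with a JSON sidecar carrying
  pixel size/origin/CRS label, or ESRI ASCII grid (self-describing text).
  Inputs must already share one grid; there is no reprojection.
- Problem sizes in the shipped tests: oracle comparisons run on grids up to
  50×50; conservation laws on one hundred 30×30 five-year simulations;
  parameter recovery on the 500×500 × 15-year configuration the recovery
  contract is stated for.
- The pipeline composes the stage functions, writes CSV + a manifest
  (version, seed, config hash, row counts), aborts naming the failing
  stage, removes partial outputs, and is byte-deterministic given config
  and seed.

## Known limitations

- Credit estimates are indicative arithmetic, not an implementation of any
  accredited methodology; absolute numbers require externally supplied
  per-hectare factors.
- Threshold verdicts ignore estimation uncertainty (point comparisons).
- The generator's LDS-independence holds at the plan level; realized areas
  still interact through fuel availability, so monotone fuel-break effects
  are statistical, not per-seed-exact.
- Patch metrics inherit the mapping scale: at 250 m pixels small patchy
  fires are under-resolved, and mean patch sizes are far above the <1 km²
  guideline for any realistic regime at this resolution.
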