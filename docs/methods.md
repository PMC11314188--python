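# Methods

## Scope and model family

`vegrot` simulates the daily fate of water and nitrogen in an intensive
open-field vegetable rotation (cauliflower – amaranth – spinach, North
China Plain conditions) at plot scale, in the tradition of
capacity-based rotation models: a tipping-bucket water balance rather
than Richards flow, first-order N transformation kinetics rather than
microbial pools, and an expolinear crop curve with a critical-N dilution
demand rather than a radiation-driven photosynthesis model. Everything
runs on a daily timestep; the studies this family supports report daily
to seasonal aggregates, and none of the represented processes is
resolved sub-daily.

## Water

**Reference ET.** Daily FAO-56 Penman–Monteith on the grass reference
surface. Net radiation is derived from measured solar radiation with
albedo 0.23 and the FAO-56 clear-sky longwave correction (no radiation
sub-model is assumed in the inputs); soil heat flux is zero at the daily
step; negative combination-equation results clamp to zero. Humidity may
be supplied as mean relative humidity or as actual vapour pressure —
weather sources differ, and the conversion is internal.

**Crop demand.** A four-stage crop coefficient curve (initial plateau,
linear development ramp, mid plateau, late ramp). Potential crop ET is
split into transpiration and soil evaporation by a canopy-cover fraction
`min(1, DM/dm_full_cover)` with `dm_full_cover` = 1.5 t ha⁻¹; bare soil
evaporates at `soil_kc` (default 0.6) × ET₀.

**Runoff.** NRCS curve-number relation with initial abstraction 0.2 S,
applied to rainfall only (default CN 75). Irrigation infiltrates fully:
both furrow and micro-sprinkler application confine water to the plot,
so no irrigation runoff is modelled.

**Redistribution.** The four measured horizons (to 120 cm) are
subdivided into 15 cm computational layers so the 0–15/15–30 cm
reporting split is representable. Water cascades top-down: content above
saturation passes on immediately; a fraction `drain_coeff` (default 0.5
d⁻¹, calibratable) of the water held between field capacity and
saturation drains each day. The bottom outflow of the deepest layer is
column drainage; the ledger reports drainage and leaching at the 90 cm
plane because the balance domain of interest is the 0.9 m profile, while
the state extends to 120 cm to match the measurement depth. Whether the
original field study simulated below 90 cm is unknowable from the
published record; carrying the extra 30 cm of state while reporting at
90 cm is this package's choice.

**Extraction.** Soil evaporation draws on the top layer only, floored at
an air-dry limit (0.5 × θ_wp). Transpiration is allocated over the
rooted layers in proportion to root fraction × plant-available water
(above θ_wp), with a triangular root density (linear decline to zero at
the root front) — the data contain no root distribution, and the
triangular profile is the simplest shape with the right qualitative
behaviour. The allocation solves the capped proportional (water-filling)
problem exactly, so an independent bisection oracle can verify it.

## Nitrogen

Per layer: urea, ammonium, nitrate, and two organic pools — added
organics (manure) and native humus — each mineralising first-order.
Rate modifiers: a Q10 = 2 temperature response referenced to 20 °C and
clipped at 1 (driven by air temperature; no soil-temperature model), and
a piecewise-linear moisture response rising from zero at wilting point
to one at field capacity, declining to 0.5 at saturation.

* **Mineralisation** integrates the decay exactly per day,
  `pool × (1 − exp(−k_eff))`, so cumulative release matches the
  closed-form exponential under constant conditions. Defaults:
  k_humus = 1.5 × 10⁻⁴ d⁻¹ on a humus pool initialised from measured
  total N (1.2 g kg⁻¹ topsoil, declining with depth), k_manure = 0.02
  d⁻¹. Reported "net mineralisation" is humus release minus a configured
  immobilisation fraction (default 0); manure-derived release is
  ledgered separately because the published budgets list manure as its
  own input column.
* **Urea hydrolysis**: first-order at 0.36 d⁻¹ (half-life under two
  days), temperature-modified, surface layer.
* **Volatilisation**: a daily fraction of surface ammonium (default
  0.15) that decays geometrically with days since application (factor
  0.5 d⁻¹), is suppressed to 10 % when ≥ 5 mm of water is applied that
  day (urea is broadcast and watered in immediately), and is reduced to
  20 % for incorporated manure. Manure N enters as 30 % ammoniacal +
  70 % organic, mixed over the 20 cm incorporation depth.
* **Nitrification**: first-order NH₄ → NO₃ (default 0.2 d⁻¹) with both
  rate modifiers.
* **Denitrification**: zero below a water-filled-pore-space threshold of
  0.6; above it, first-order in nitrate (default 0.1 d⁻¹ at saturation)
  scaled by the squared excess WFPS and the temperature factor. Note
  that at field capacity the measured horizons sit at WFPS 0.66–0.81, so
  a wet profile denitrifies chronically; reduced irrigation keeps the
  soil airier and measurably cuts gaseous loss, which is the directional
  behaviour the acceptance checks assert.
* **Transport**: mixing-cell advection using the day's drainage cascade;
  each cell's outflow concentration is mass/(storage + outflow) after
  mixing the inflow from above. Mass is conserved identically.
* **Uptake**: daily crop demand (below) is drawn from an extractable
  fraction (default 0.5) of rooted-layer mineral N, proportionally to
  per-layer availability, split between NH₄ and NO₃ by their share.

The gaseous ledger entry is volatilisation + denitrification; the two
parts are exposed separately, but no published value constrains their
ratio, so the split should be treated as structural rather than
calibrated.

Irrigation water carries nitrate at a configured concentration. The
default, 3.9 mg N L⁻¹, is back-calculated from the published budgets:
every treatment-year's irrigation-N input divided by its irrigation
depth gives 0.039 kg N ha⁻¹ mm⁻¹ (e.g. 19.8 kg N ha⁻¹ over 507.8 mm).

## Crop

Potential growth is expolinear: daily rate `c_m/(1+exp(−r_m(t−t_b)))`,
integrated exactly over each day so the unstressed loop reproduces the
closed form `(c_m/r_m)·log(1+exp(r_m(t−t_b)))`. The realised increment
is potential × min(water stress, N stress) × a temperature ramp from a
4 °C base to an 18 °C optimum — with three short seasons (22–65 days), a
single rate parameter per crop driven by calendar days is identifiable
where thermal-time tables would not be. Water stress is realised/
demanded transpiration; N stress is actual %N over critical %N, clipped
to [0, 1].

N demand targets the luxury ceiling `L × %N_crit(DM_next) × DM_next`,
where `%N_crit = a·DM⁻ᵇ` (percent of dry matter, DM in t ha⁻¹) with a
seedling plateau below 1 t ha⁻¹. Because `a·DM^(1−b)` increases with DM,
plant %N can never exceed `L × %N_crit` at any later point of the
season, which is asserted as an invariant. Fresh yield is
DM × harvest index × fresh:dry ratio.

Transplanted cauliflower starts from 0.05 t ha⁻¹; direct-sown amaranth
and spinach from 0.005 t ha⁻¹. The default growth, dilution and
conversion coefficients are calibratable starting points chosen to give
fresh yields of the right order for these vegetables (≈ 2 × 10⁴ kg ha⁻¹
cauliflower, leafy crops above that per unit water); the field study's
own fitted values were published only in an appendix that is not
available, so no claim is made that the defaults equal them.

## Fertiliser budget

`N_opt = N_upt + N_res + N_loss − N_ini − N_hum − N_root`, with
`N_loss = N_input × 0.019 × weeks`. Negative budgets clamp to zero — a
negative dose is physically meaningless, and well-supplied short seasons
genuinely produce zero-fertiliser recommendations. The reduced-dose
variant multiplies by a per-crop fraction (default 0.8); the source
prose is ambiguous about whether the reduction applied to spinach only
or to all crops, so the fraction is an explicit argument rather than a
hard-coded rule.

## Ledgers and statistics

Seasonal ledgers accumulate between sowing and harvest; annual rows sum
extensive fields and recompute WUE, IWUE, NUE and both balances from the
sums (verified against the published annual rows, which are ratio-of-sums,
not mean-of-ratios). NUE is fresh yield over (uptake + leaching +
gaseous loss) exactly as the source tables define it, dimensional
awkwardness included — no "corrected" definition is substituted.
Undefined ratios (zero denominator) are reported as absent, never as 0.
Report files are written in full precision and in a rounded view
matching the publication formatting (one decimal; yields to the nearest
100 kg ha⁻¹).

RMSE, E and d follow their standard definitions; E errors out on
constant observations and d when every deviation from the observed mean
vanishes, rather than returning a conventional value. The acceptability
rule (E > 0.36 and d > 0.7) uses strict inequalities.

Two cells of the published balance tables are internally inconsistent
with their own component columns by more than rounding (both IWUE cells;
one a digit transposition). They are kept verbatim in
`vegrot.study_tables` but flagged `SUSPECT_CELLS` and excluded from the
identity regression, which covers every other cell at a 0.15 tolerance
in printed units (absorbing table rounding).

## Calibration

The traditional calibration of this model family is manual trial and
error in a fixed order: soil water first, then N transformation
parameters, then crop parameters. The harness makes that reproducible:
a staged grid search in the same order, each stage evaluating the full
Cartesian product of its parameter grids while other stages stay
frozen. The product search (rather than one-parameter-at-a-time sweeps)
matters because the dilution coefficient and the luxury ceiling have
correlated effects on plant N — coordinate descent can stall on an
off-axis product that matches `a × L`; the joint grid cannot. The
self-consistency exercise simulates a 65-day cauliflower season at known
values (kc_mid 1.15, a 4.4, L 1.25, all off the package defaults but on
the grids), with moderate fertiliser so late-season N limitation
separates a (visible in stressed growth) from L (visible in early
uptake), and recovers all three exactly at zero noise and within one
grid step (≤ 10 %) at observation noise of 0.02 cm³ cm⁻³ on water
content and 5 kg N ha⁻¹ on plant N.

## Synthetic study conditions

The published record contains seasonal totals, a crop calendar, the soil
table and climate normals — not the daily weather or per-event
schedules. The generators therefore define the study conditions:

* **Weather**: annual temperature sinusoid (mean 11.5 °C, amplitude
  14.5 °C, warmest mid-July) and radiation sinusoid with daily jitter;
  humidity and wind as jittered baselines, bumped on rain days. Rainfall
  is placed as 5–12 events per growing-season window, amounts quantised
  to 0.1 mm by largest-remainder apportionment with a final
  representation-level nudge so that each window's float sum equals the
  configured total *exactly* (151.0 mm in the 2000 amaranth window,
  69.1 mm in 2001, etc.). Days outside the season windows are dry; the
  generator makes no claim to inter-annual correlation structure.
* **Management**: manure (75 kg N ha⁻¹ in 2000, 120 in 2001, per the
  published budget tables) incorporated at cauliflower planting; urea in
  thirds for cauliflower (basal, end-April, mid-May) and spinach (basal,
  mid-September, early October), all-basal for amaranth; every urea day
  receives same-day irrigation. Irrigation is split into 4–6 events per
  season for furrow (W1) and 8–12 for micro-sprinkler (W2), seasonal
  totals exactly equal to the published treatment totals. A rule-based
  irrigation mode (refill to 80 % of field capacity when the 30 cm
  control zone falls below 50 %) is available for scenario experiments,
  separate from the fixed-total mode used for table-anchored runs.
* **Observations**: simulator truth sampled at the field cadences (water
  every 2 days, nitrate every 7–15 days), Gaussian noise added (defaults
  0.02 cm³ cm⁻³ and 2 mg N L⁻¹), clipped to physical bounds.

What passing tests on these inputs do **not** show: agreement with the
actual 2000–2001 drainage, leaching and ET magnitudes, which depend on
the unpublished weather and event timing. Those appear in the package
only as directional claims checked on fixture scenarios — the monsoon
year drains and leaches more in the amaranth season than the dry year,
reduced fertiliser cuts gaseous N, reduced irrigation cuts leaching —
plus the exact ledger identities on the published component columns.

## Numerical choices

* Closure: every simulated day, the water residual
  (in − runoff − ET − bottom drainage − Δstorage) and the N residual
  (inputs − uptake − gaseous − bottom leaching − Δpools) are recorded;
  the test suite requires ≤ 10⁻⁹ (observed ~10⁻¹²).
* Event order within a day: sowing, manure, urea, irrigation, harvest —
  urea is broadcast before the water that suppresses its volatilisation
  arrives.
* The day's transformation order is hydrolysis → volatilisation →
  mineralisation → nitrification → denitrification → advection →
  uptake, each flux capped by its source pool, so pools cannot go
  negative regardless of event sequence.
* Ties and degenerate inputs: zero-length seasons are forbidden by the
  calendar check; ratios with zero denominators are absent; allocation
  with zero total weight returns zeros.
* Runs are RNG-free given their inputs; identical configurations produce
  byte-identical outputs.

## Known limitations

* No Richards flow, macropores, water table or hysteresis; drainage
  timing is as sharp as a daily bucket cascade allows.
* Air temperature stands in for soil temperature in all rate responses.
* No N₂O/N₂ partitioning, microbial biomass, dissolved organic N or
  ammonium sorption; the volatilisation/denitrification split within
  gaseous loss is structural, not calibrated.
* Crop phenology is a single expolinear curve per crop: no sub-stages,
  vernalisation, or radiation-use modelling; yield quality is out of
  scope, as are significance tests on yields.
* One plot, no spatial variability; observation noise is independent
  Gaussian, unlike real TDR/suction-cup error structure.
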