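# Methods

## The estimation model

`diazoload` estimates the internal nitrogen load of a sea basin — nitrogen
entering via biological N₂ fixation — by multiplying monitored biovolumes
of the three dominant heterocystous cyanobacteria genera with empirical
per-biovolume fixation rates, and aggregating upwards in space and time.

**Per-sample volumetric rate.** For genus *g* with biovolume `B_g`
(mm³ L⁻¹) in a tube sample, the estimated fixation is `r_g × B_g`, where
`r_g` (µmol N mm⁻³ day⁻¹) is the genus rate. Because
1 µmol L⁻¹ = 1 mmol m⁻³, the numeric product is already in
mmol N m⁻³ day⁻¹; no conversion factor appears anywhere in the chain.
Normalising by biovolume rather than cell counts absorbs the large
cell-size variation within and between genera.

**Rates.** The default table (0.66 ± 0.11 for *Aphanizomenon*, 0.68 ± 0.14
for *Nodularia*, 1.20 ± 0.25 µmol N mm⁻³ day⁻¹ for *Dolichospermum*;
1227/1129/1640 cells) represents summer (June–August) means of single-cell
isotope-tracer measurements divided by mean cell volume
(`rates.normalize_cell_rate` implements the normalisation, with SE on an
n−1 denominator). The rates are treated as season-, station- and
depth-invariant constants; published Baltic measurements from independent
campaigns span roughly 0.45–1.3 µmol mm⁻³ day⁻¹, which brackets the
defaults. Alternative rates can be supplied as a four-column CSV.

**Depth handling.** Two conventions interact:

* *Tube correction.* Stations sampled with a 0–20 m integrating tube are
  multiplied by 2 (biovolume and carbon), because the filamentous genera
  are concentrated above ~10 m and the longer tube dilutes them roughly
  two-fold. The correction is a per-station configured multiplier (default
  2 for 0–20 m tubes, 1 for 0–10 m) rather than a hard-coded station list,
  and pre-correction values are retained in the output for audit.
* *Areal integration.* The volumetric rate is assumed constant over the top
  10 m and multiplied by the integration depth (configurable, default
  10 m), yielding mmol N m⁻² day⁻¹. Surface rates exceed 10 m rates in
  reality; using rates that are themselves averages over 0–7 to 0–12 m
  incubations makes the constant-layer assumption a reasonable middle
  ground. No vertical profile model is attempted.

**Aggregation order.** Within a basin-month: genus rates are summed per
sampling event (a distinct station–date pair); events are averaged within
each station-month; station-month means are averaged, unweighted, across
the basin's stations. Stations are the statistical unit of the basin mean,
so a station sampled three times in July does not outweigh one sampled
once. A cast in which no diazotroph was recorded is a genuine zero — the
event set is built from *all* rows of the monitoring table, and such events
enter the mean with areal rate 0. Multiple casts on one day count as one
event.

**Monthly totals and annual sums.** The monthly total is mean daily × 30,
for every calendar month; the annual areal estimate is the sum of the
twelve monthly totals. Months with no sampling anywhere in the basin
contribute zero and emit a logged gap warning (`gap_policy="skip"` merely
drops the zero rows from the output tables; the annual sum is unchanged).
Winter biovolumes of these genera are near zero, so the zero-fill is a
small conservative bias.

**Year pooling.** Basins with sparse sampling pool years into blocks before
the monthly means: `pooled_year_blocks` splits a contiguous span into
near-equal contiguous blocks (target width configurable per basin), placing
the remainder middle-out, so a 19-year span at width 6 gives 6 + 7 + 6
years. Densely sampled basins use annual (width-1) blocks.

**Load conversion.** `load = areal_annual × area × M_N × 10⁻¹²` kt N yr⁻¹,
with area in m² and `M_N = 14.0067 g mol⁻¹` (standard atomic weight). The
across-year (or across-block) mean ± sample standard deviation is the
reported summary; the rate SEs could be propagated linearly instead, but
interannual bloom variability dominates the uncertainty, so the ± in
summaries is the across-year sd.

**Comparisons.** External inputs (rivers + direct sources + atmospheric
deposition) and allowable limits per basin are configuration values
(`data/baltic_defaults.yaml`), each tagged with its reference period; where
two published figures exist for one basin both are retained and the entry
whose period best overlaps the estimate is selected (most overlapping
years, then tightest period). `extrapolate_to_area` scales a load to
another basin's area under the assumption of equal areal rates — an upper
bound style of argument, not a prediction.

## Default Baltic configuration

Eight stations: B1, BY31 (0–20 m tubes, correction 2), BY15, BY5, BY2 in
the Baltic Proper (211 000 km², annual loads); C3 and the B3+B7 pair in the
Bothnian Sea (79 000 km², 6-year pooling); F9/A13 in the Bothnian Bay
(36 800 km², 6-year pooling). The B3+B7 estuary pair is treated as a single
merged series under one station id; treating them as two stations instead
is a matter of relabelling the input rows. Allowable limits: 325 kt yr⁻¹
(Baltic Proper), 79 kt yr⁻¹ (Bothnian Sea). The Gulf of Finland area
(29 600 km²) is included for extrapolation only.

## The synthetic-data generator

`synthetic_data.generate` emulates the statistical features of Baltic
monitoring series that the estimator is sensitive to; it is a data model,
not a bloom model.

* **Seasonality** — each (station, taxon) has a Gaussian bump in
  day-of-year (peak day, peak biovolume, width) on a winter baseline that
  is positive only for *Aphanizomenon*; contributions beyond six widths
  from the peak are clamped to exactly zero, so taxa absent in winter are
  truly absent. There is no wrap-around across New Year (all configured
  peaks are mid-summer).
* **Trend** — the whole curve scales by `(1 + trend)^(year − 2008)`; the
  reference year is the campaign midpoint.
* **Patchiness** — each catch multiplies the seasonal mean by
  `LN(0, σ) × Bernoulli(1 − p)`, normalised by its expectation so every
  draw is unbiased for the seasonal mean. The default σ = 1 reproduces the
  two-orders-of-magnitude spread among summer samples seen in bloom
  regions; p = 0.05 adds occasional zero catches. Zero catches are emitted
  as explicit zero-biovolume rows: the cast happened, and dropping it would
  bias monthly means upward.
* **Sampling schedule** — per-station, per-month event counts (summer-
  weighted in the Baltic Proper, ~monthly northwards), with sampling days
  placed deterministically (evenly spaced) within each month. Deterministic
  days make the generator's ground truth an exact expectation rather than
  an average over random schedules.
* **Tube convention** — emitted biovolumes are the *tube* values
  (true 0–10 m mean divided by the station's correction), so the generated
  table exercises the correction step.
* **Carbon background** — spring diatom and summer flagellate groups with
  fixed carbon densities (200/110/180 µg C per mm³ for cyanobacteria,
  diatoms, flagellates) feed the carbon-fraction summaries.

**Ground truth.** Because every pipeline step is linear in biovolume and
the noise is mean-one, the expected pipeline output has a closed form:
`expected_loads` evaluates the seasonal means on the exact sampling days
and mirrors the aggregation order step by step. Noise-free scenarios
(σ = 0, p = 0) must match it to machine precision (observed ~10⁻¹⁶
relative), and the mean over noisy replicates converges to it (observed
|bias| < 1.2 % over 200 replicates of the default campaign).

**Calibration of the default scenario.** Peak biovolumes, widths and trends
were chosen once, analytically (via the Gaussian-integral approximation of
the annual sum), to land in the observed Baltic regime: Bothnian Sea July
areal rates of order 1 mmol N m⁻² day⁻¹ with loads roughly doubling across
1999–2017, Baltic Proper summer rates of 1–2 mmol N m⁻² day⁻¹ and annual
loads of a few hundred kt with a nearly flat trend, Bothnian Bay summer
biovolume below 0.001 mm³ L⁻¹, *Nodularia* strongest in the southern
Baltic Proper and absent in winter, and summer cyanobacterial carbon
fractions of tens of percent.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: spatial correlation between stations,
within-month temporal autocorrelation (bloom rise and crash between
casts), weather-driven gaps and ice seasons, taxonomic reassignments and
detection limits in real exports, and any coupling of biovolume to nutrient
or temperature drivers. Tests establish that the estimator is an unbiased,
exact implementation of its own model, not that the model captures every
property of field data.

## Numerical and design choices

* 30-day months everywhere (so a "year" is 360 daily units); this is part
  of the model definition, not an approximation to be refined.
* Nitrogen molar mass 14.0067 g mol⁻¹.
* Unweighted means at every aggregation level; no weighting by sampling
  effort or station area share.
* Species→genus rollup sums biovolumes (partitions of one sample);
  duplicate rows after rollup are likewise summed. *Anabaena* is treated as
  a synonym of *Dolichospermum*; unrecognised taxa are pooled as `other`
  and contribute only to the carbon background.
* Validation is strict and total: malformed rows (negative biovolume,
  unparseable dates/numbers, inverted depth intervals) abort the read with
  a per-row report rather than being silently dropped.
* Carbon fractions are reported as NaN (with a warning) for station-months
  with zero total carbon.
* Reported problem sizes: the default campaign spans 19 years × 8 stations
  (≈ 11 600 rows, ≈ 2 700 sampling events); recovery statistics use 200
  replicate campaigns; smaller 2-station, 3–6-year scenarios back the
  fast unit and property tests.

## Known limitations

* Constant genus rates ignore documented station-to-station activity
  differences (up to ~8×); the estimator is therefore a basin-scale, not a
  station-scale, instrument.
* The ×2 tube correction is calibrated for surface-concentrated taxa and
  can overestimate deep-dwelling *Aphanizomenon* locally.
* Zero-filled unsampled months bias annual sums low if blooms occur in
  unsampled months; with the default schedules no bloom month is
  unsampled.
* External loads and allowable limits are period aggregates, not annual
  series; comparisons inherit that resolution.
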