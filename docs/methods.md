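# Methods

`anfbudget` implements the quantitative machinery of an associative
nitrogen fixation (ANF) budget for perennial grass systems — switchgrass
under a long-term N-fertilization gradient being the motivating case. Four
calculations are chained: vial-level isotope rates, soil N-transformation
rates, a plot-level N mass balance, and areal/annual scaling; a
model-selection layer describes how each rate responds to N addition, and
a synthetic-study generator makes every stage testable without field data.

## Isotope rate calculus

A sealed 12-mL vial holds 5 g soil (or 1 g excised roots); 4 mL of
headspace is withdrawn and 4.2 mL of 99 atom% ¹⁵N₂ injected. After *t* days
the sample's ¹⁵N enrichment against a paired natural-abundance control
gives the fixation rate by isotope mass balance:

    rate (µg N vial⁻¹ d⁻¹) = (AE_i · TN_i) / (AE_atm · t)

with `AE_i` the sample atom-fraction excess (treatment − control, atom% /
100), `TN_i` the total N in the vial (µg), and `AE_atm` the headspace N₂
atom-fraction excess. `AE_atm` follows from equal-pressure volume
bookkeeping: tracer N₂ over total headspace N₂, the residual air
contributing N₂ at its atmospheric fraction (0.78, configurable). Natural
abundance is 0.3663 atom% (standard air N₂), configurable.

Numerical/convention choices:

* Atom% everywhere at the interface (instrument convention); conversion to
  atom fractions happens inside the rate equation so both excesses share
  units.
* Detection floor: a rate implied by `AE_i` below twice the instrument
  atom%-repeatability (default SD 0.0002 atom%) is floored to 0 and
  flagged; the raw signed value is always retained, so means can be formed
  either way.
* `AE_atm` is **not** corrected for N₂ produced during incubation
  (denitrification); any such production dilutes the tracer, so computed
  rates are conservative.
* Occupied (solid + liquid) volume defaults to dry mass over a packing
  density of 1.9 g cm⁻³ (soil) or 1.0 (roots) when not recorded; with the
  protocol geometry this puts headspace ¹⁵N₂ near 50%.
* The contamination bound assumes every µg of reactive ¹⁵N delivered with
  the tracer is assimilated and read back through the rate equation — a
  deliberate worst case; measured rates at or below it are
  non-attributable. The bound's form is this package's own construction;
  only the hazard (reactive ¹⁵NH₃/¹⁵NOₓ in commercial tracer) is from the
  assay literature.

## Net mineralization and nitrification

28-d aerobic incubations at 60% water-filled pore space, bracketed by KCl
extractions of NO₃⁻ and NH₄⁺. Net mineralization is the change in total
inorganic N over time; net nitrification the change in NO₃⁻ alone.
Negative mineralization (net immobilization) is reported as-is, never
floored. Extraction replicates are averaged before the rate equations (one
rate per core). Relative nitrification is the ratio of the two net rates
×100. The phrase "percent of mineralizable N present as nitrate" admits
two readings; the Δ-based ratio is the default because observed values
near and above 100% (ammonium pool shrinking) are only consistent with
that reading. The end-pool fraction is provided as an alternative
(`relative_nitrification_end_pool`).

Water additions to reach a target WFPS use pore volume = porosity/bulk
density per gram; already-wetter soils return 0 mL with an `over_wet`
flag. Complete KCl extraction is assumed; a helper converts extract mg L⁻¹
to µg per g dry soil.

## Mass-balance ledger

Annual balance = fertilizer + atmospheric deposition − harvest N removal
(− optional leaching/denitrification terms, default 0, keeping the deficit
conservative). Harvest N is yield (Mg ha⁻¹) × tissue %N × 10. Inputs carry
zero variance; the annual SE equals the harvest-output SE, cumulative SEs
combine in quadrature, and SE(mean) = SE(cumulative)/n — matching how the
published table's SE structure is built. Balances are signed (negative =
deficit); deficit properties report magnitudes. Arithmetic is full
precision; rounding to 0.1 kg is a reporting concern. Years missing
deposition may borrow the multi-year mean, flagged. The packaged fixture
transcribes the published MI balance table verbatim; the ledger reproduces
every unfertilized cell exactly and the fertilized cells within ±0.3 kg
(printed-value rounding in the source table; the ledger recomputes from
the input columns rather than copying printed balances).

## Areal and annual scaling

Per-gram rates integrate over a 120-d growing season partitioned
pre-fertilization 20 d / post-fertilization 40 d / peak biomass 60 d. The
post-senescence sampling is excluded by default (the partition ends at
roughly the end of August); an explicit `senescence` entry in
`season_days` extends it. Soil rates are divided by the glucose
stimulation factor 4.8 — the mean factor by which the glucose amendment
used in the soil assay inflates fixation — then multiplied by bulk density
× core depth (areal mass of the sampled 15 cm only; no depth
extrapolation). Root rates are used as measured (no glucose response in
root assays) and multiplied by areal root biomass, assumed depth-invariant
within the rooting zone. Period SEs propagate linearly and combine in
quadrature (periods are separate samplings).

Site defaults where the source tables stop short: bulk density 1.5 g cm⁻³
for the MI-like Alfisol loam and 1.1 g cm⁻³ for the WI-like high-organic
Mollisol silt loam (soil-series-typical surface values), root biomass
600 g m⁻² over 0–25 cm (typical for established switchgrass). With the
default truth curves these place annual soil ANF at ~39–51 (MI) and
~35–41 (WI) kg N ha⁻¹ yr⁻¹ and root ANF near 0.6 kg N ha⁻¹ yr⁻¹.

## Response models and the agronomic optimum

Five families (see `response_models`); weighted least squares; AIC =
n·ln(SSE/n) + 2(k+1) (least-squares AIC, not REML — stated choice).
Selection keeps families whose effect parameter differs from 0 by an
asymptotic t-test (numerical-Jacobian SEs, n−k df) and returns the lowest
AIC; exact ties break by the fixed order linear < log < power <
exponential < plateau. The default candidate menu for rate responses is
the four non-plateau families; the quadratic plateau is reserved for
yields. `x+1` offsets keep the unfertilized treatment defined in the
log/power/exponential forms.

Numerical choices:

* Nonlinear families use a deterministic multi-start: shape parameter `b`
  started on ±{10⁻³…1} (and 0), amplitude profiled in closed form at each
  start; every fit is reproducible with no RNG.
* The plateau is fit by profiling the join point: for fixed x₀ the curve
  is linear in (a, c) under the vertex constraint b = −2cx₀, so the
  profile SSE is exact on a 241-point grid over (0, 2·max x] and polished
  by bounded scalar minimization. Non-concave outcomes (c ≥ 0) fall back
  to a linear fit with optimum 0. The reported optimum is clamped to
  [0, max x] with a boundary flag.
* The optimum's "no effect → 0" decision uses the extra-sum-of-squares
  F-test of the plateau against the constant mean rather than the t-test
  on `b`: the profiled join point adapts to noise near x₀ = 0 where `b` is
  weakly identified, making the t-test anti-conservative there (measured
  ~23% rejection under flat truth vs ~5.6% for the F-test, with full power
  under a genuine plateau at 7% yield CV).
* "Weighted by the inverse of rank order" is implemented as a pluggable
  policy, default: within each N level, replicates ranked by distance from
  the level median and weighted 1, 1/2, 1/3, … . The upstream protocol's
  exact scheme is not specified in the available text; this reading
  down-weights outlying plots, which is the scheme's evident purpose.
* Per-family type-I error measures 4.0–4.4% at α = 0.05 under flat truth;
  the familywise "no model selected" frequency is ~92%, the union of four
  strongly correlated tests.

A known information limit: at the 12-point design (4 blocks × 3 N levels),
two-parameter families nearly interpolate the three level means, so AIC
identification of the *generating* family against near-equivalent shapes
succeeds only ~55–78% of the time depending on signal amplitude, even
though the generating family is essentially always significant and its
amplitude is recovered. Family labels chosen at this design size should be
read as descriptions of curve shape, not mechanistic identifications.

## Synthetic-study generator

The generator is the package's definition of the study conditions: 2 sites
× 4 blocks × 3 treatments (0/56/196 kg N ha⁻¹ yr⁻¹) × 4 periods. Truth
curves default to the published site×period response fits (exponential and
power declines of fixation with N, a post-senescence root-fixation spike
with amplitude 4.75 and decay −0.03 at the MI-like site, mineralization
increasing with N); periods with no published fit get flat curves at
observed magnitudes. Curves are rectified at 0, since fitted linear tails
can cross zero where rates cannot (the published WI-senescence
mineralization line has a negative intercept; the default truth uses the
site's minimum observed rate, 0.002, instead).

Measurements are produced by inverting the analysis equations: the true
rate (curve × lognormal block effect, CV 0.15, mean 1 — rates are positive
and right-skewed) maps to a treatment-vial atom% through the isotope mass
balance; day-28 pools are day-0 pools (drawn around published
treatment-mean concentrations, printed SEs used as block SDs) plus
mineralized N split NO₃⁻/NH₄⁺ by a relative-nitrification fraction
(0.85/0.95/1.0 across treatments, kept ≤1 so inversion is exact); block
yields scatter around a plateau truth (joins at 109 and 90 kg N ha⁻¹
yr⁻¹). Noise defaults: atom% SD 0.0002 (applied to treatment and control
alike), extract CV 0.10, yield CV 0.07. Everything is deterministic given
the seed.

What the generator does **not** emulate: spatial autocorrelation among
plots, weather-driven interannual dynamics, multi-year soil-N feedback,
depth profiles of diazotroph activity, or correlated errors between the
paired T0/T28 extractions. Passing round-trip and recovery tests therefore
demonstrates the correctness and statistical calibration of the
calculations under the stated error model — not that real field data meet
that model.

## Problem sizes

The test suite and the acceptance script run at desk scale by design: full
synthetic studies are 192 vials/96 assays; recovery checks use 100–250
seeded replicates of single-site, single-period studies or 12–32-point
regressions; the ensemble-mean check uses 200 blocks. These sizes were
chosen so every stochastic frequency is estimated to within a few percent
while the whole suite stays fast.

## Known limitations

* The ledger treats fertilizer and deposition as exact; real deposition
  carries measurement error that would propagate into the deficit SE.
* The scaling step inherits the laboratory assay's artifacts; the glucose
  factor 4.8 is a single mean correction, not treatment- or
  season-specific (though it is configurable per treatment).
* Least-squares AIC assumes homoscedastic Gaussian errors; an optional
  per-level variance weighting is available but off by default.
* The contamination bound is a worst case, not an estimate.
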