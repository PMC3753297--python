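# Methods

## Accounting model

The package implements a multilinear bookkeeping model of urban organic
carbon. Each province contributes four pools computed from its statistics:

* **Vegetation** — urban area × green-space fraction × vegetation carbon
  density of green space. Urban forest and grassland are a single pool
  because provincial statistics do not separate them.
* **Soil** — to 100 cm, under the assumption that green space and
  impervious surfaces tile the urban area exactly (the impervious fraction
  is identically 1 − green fraction; no water or bare-ground class is
  carried).
* **Humans** — population × 60 kg average body mass × 0.3 dry-matter
  fraction × 0.5 carbon fraction, i.e. 9 kg C per person.
* **Buildings** — wood only: construction wood at 0.045 (residential) and
  0.055 (commercial) m³ per m² of floor, plus furniture wood at
  `n_set × n_household × 20 pieces × (0.8×0.067 + 0.2×0.026) m³`, both
  converted to carbon through the 0.4 t m⁻³ bulk density and the 0.5
  carbon fraction. Pets, books and food are excluded as negligible.

Commercial floor area is not tabulated directly and is defined as total
minus residential floor area. Furniture wood volume is converted to mass
with the same bulk density as construction wood, the only bulk density the
coefficient set provides. Internally all masses are kept in kg C and
converted once, centrally, to the reporting unit Tg C (10⁹ kg); urban
areas in km², floor areas in 10⁴ m², densities in kg C m⁻². The
green-space share is stored as a fraction in [0, 1]; percentage inputs
must be divided by 100 at ingest.

Degenerate provinces are tolerated: a zero-stock province reports zero
fractions with a `degenerate` flag; zero-area provinces are rejected at
validation (area is a strict denominator for density) and excluded from
the regression.

## Uncertainty propagation

Input uncertainty is propagated per province by Monte Carlo
(10,000 draws by default). Each of the ten province-level inputs is drawn
independently:

* normal with SD = β × mean (β = 0.15) for area, green fraction,
  vegetation density, population, the two floor areas, furniture sets and
  households — β standing in for the unknown dispersion of
  yearbook-derived quantities;
* mean-matched log-normal for the two soil densities, the standard
  distributional model for soil organic carbon. The impervious-surface
  density uses its tabulated absolute SD; the green-space density, lacking
  a measured SD, uses β like the rest.

Mean matching is closed-form: σ² = ln(1 + (sd/mean)²),
μ = ln(mean) − σ²/2, so the arithmetic mean of the log-normal equals the
input value exactly and the soil pool stays unbiased; the additive
log-scale correction k = μ − ln(mean) = −σ²/2 is reported alongside. A
`method="optimize"` mode finds the same parameters by numerical
moment-matching as a cross-check; the closed form is the default because
it is exact, cheaper, and deterministic.

Model constants are held fixed during Monte Carlo: they are shared across
provinces, and sampling them would correlate provinces and invalidate the
index-wise summation used to combine provincial draws (provinces are
treated as independent). The residential and commercial floor areas are
sampled as two independent normals rather than (residential, total): the
pool equations consume exactly that pair, and independent draws of
(residential, total) would violate residential ≤ total in roughly 2.5% of
draws at CV 0.15. Normal draws are clipped at zero — the quantities are
physically non-negative; at CV 0.15 the clip probability is ~10⁻¹¹ per
draw, so the induced bias is far below Monte Carlo noise — and clip events
are logged. The impervious fraction tracks each draw's green fraction as
its complement.

Summaries report the mean of the draws and a 95% half-width of
1.96 × SD(draws) — the spread of the Monte Carlo distribution of the stock
itself, not the standard error of its mean (which at 10,000 draws would be
two orders of magnitude smaller than the intervals such inventories
publish). Per-pool and total intervals come from the same draws, so the
variance of the total equals the variance of the summed pools exactly.
Reproducibility: each province's random substream is keyed on a master
seed plus a hash of the province id, so results are bit-identical under a
fixed seed and unaffected by adding, dropping, or reordering other
provinces.

## Sensitivity analysis

Sensitivity is one-at-a-time on the point-estimate model: one variable is
raised 10% in every province simultaneously (constants globally), the
national total is recomputed, and 100 × (C′ − C)/C is reported. The
registry holds 21 variables: the eleven province-level model inputs and
ten constants. Because every pool is a product of its inputs, a variable
entering only as a linear factor of pools holding a share s of the total
responds with exactly 10s percent, bounding all responses by 10%; this
closed form is the test oracle.

Two registry conventions: the impervious fraction is perturbable
independently of the green fraction (baseline 1 − α, scaled ×1.1 with α
untouched), since inventories report the two covers as separate
sensitivities and negative responses only arise when fractions move
independently or trade off; and perturbing the wood-furniture fraction f7
re-derives the steel fraction as its complement, which flips the response
sign whenever steel furniture uses more wood per piece than wood furniture.
Signs are reported, not targeted.

## Aggregation, regression, extrapolation

Provinces sum to regions and the nation; density is total stock over total
area; pool fractions are pool sums over the total, making the national
shares automatically the total-weighted means of the regional shares.
Aggregation is therefore associative and order-independent. When Monte
Carlo results accompany the point estimates, regional and national
intervals come from summing the provincial draws.

The storage–area relationship is an ordinary least squares fit of
provincial totals (Tg C) on urban area in units of 1,000 km², with
intercept by default; a through-origin option exists because the
"specific storage" reading of the slope is ratio-like and either
convention is defensible. Zero-area provinces are excluded. The slope
(Tg C per 1,000 km²) times an aggregate urban extent gives an
extrapolated stock; context ratios compare the urban stock and area with
national terrestrial totals (defaults 77.4 Pg C and 9.60 × 10⁶ km²,
shipped as cited, overridable constants), and the density ratio equals the
stock share over the area share identically.

## Synthetic data

No machine-readable provincial input table exists publicly, so the
generator emulates one: 31 provinces in the six conventional
macro-regions; log-normal areas rescaled to a 33,697 km² national total
(a few large provinces dominate, spanning ~2 orders of magnitude); green
fractions uniform 0.31 ± 0.14; carbon densities log-normal with ranges
read as central 95% intervals — vegetation 0.4–2.5 kg C m⁻² (the span of
published urban tree/grass figures), soils 5–15 (green) and 4–12
(impervious) kg C m⁻², which keep provincial urban densities inside the
observed ~9–29 kg C m⁻² envelope; population proportional to area through
a log-normal urban population density of 8,000–25,000 km⁻² (≈19,000 km⁻²
back-computes from a 1% human share at 17.1 kg C m⁻²); 35 m² of total
floor space per capita with a 0.5–0.8 residential share; 3 persons per
household; 0.5–2 furniture sets per household; `sd_simp` set to a CV of
0.3 on the impervious soil density. Every generated table passes full
input validation, and the generator keeps its own straight-arithmetic
bookkeeping of the national pools for closed-loop tests.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring provinces, region-level climate gradients in the densities,
any covariance between green fraction and density, or the real provinces'
identities. Passing tests therefore demonstrate that the pipeline's
arithmetic, propagation and aggregation are correct under realistic
magnitudes and covariation with area — not that real provincial stocks are
reproduced.

`calibrate_national` rescales one generated table so the national
point-estimate run hits a target total (default 577.0 Tg C) and pool
partitioning (7.3/56.1/1.0/35.6%) exactly. Each pool has a disjoint set of
multiplicative handles — vegetation density; both soil densities (and
`sd_simp`); population; floor areas plus household counts — and is linear
in them, so one closed-form scale factor per pool suffices, with no
optimization. Areas are untouched, so the national density (17.1 kg C m⁻²)
follows by construction.

## Numerical choices and problem sizes

* Pool additivity and fraction normalization hold to relative 10⁻¹²;
  the one-at-a-time oracle is asserted to 10⁻⁹.
* The furniture-fraction constraint f7 + f9 = 1 is validated to 10⁻⁹;
  β = 0 is admitted as the no-uncertainty limit (all other constants are
  strictly positive).
* Output CSVs are written at 12 significant digits so a write/read round
  trip is lossless at that precision.
* The default Monte Carlo size is 10,000 draws per province. The test
  suite runs most stochastic checks at 2,000–20,000 draws — sizes at which
  the assertions' tolerances (1–8% on means and CVs, ~5% on combined SDs)
  sit several Monte Carlo standard errors wide — and a national-scale
  check at 2,000 draws per province across 31 provinces.

## Known limitations

* Within-province inputs are drawn independently; real statistics
  correlate (larger areas mean more floor space) and the point estimates
  already encode much of that correlation, but no joint covariance is
  modelled, and no Bayesian treatment is attempted.
* The one-at-a-time design ignores interactions by construction; a
  variance-based (Sobol) analysis is out of scope.
* The regression convention (intercept vs through-origin, unweighted vs
  uncertainty-weighted) materially moves the fitted slope on skewed area
  distributions; both intercept conventions are exposed, weighting is not.
* The soil model assumes exactly two cover classes; urban water bodies and
  bare ground are folded into them.
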