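# Methods

## Scope and entities

`marshsim` simulates the viability and dispersal success of a
univoltine grassland insect (parameterised for the large marsh
grasshopper, *Stethophyma grossum*) on a lattice of square 250 m
habitat cells nested inside a lattice of square 12 km climate cells.
The entities are: climate cells (holding daily driver series), habitat
cells (grassland or not), per-cell populations structured into five
life stages (prediapause egg, diapause egg, embryo, larva, imago), and
age-distinguished cohorts within each stage. The reported state
variable is density (eggs or individuals m⁻²); internally every cohort
carries an integer head count — `count = round_half_up(density · 62 500 m²)` —
which is the unit on which all stochastic draws operate. That choice
makes the conservation law (no mortality/fecundity/dispersal ⇒ total
head count constant) hold exactly, with no floating-point drift.

The calendar has 364-day years (52 full weeks) so that weekly mowing
schedules land on fixed days-of-year; a 60-year run is exactly
21 840 daily steps. Leap days in imported data are dropped by the
climate reader with a warning.

## Climate downscaling

Each grassland cell is assigned the up-to-four climate cells whose
centres enclose it, keyed by secondary cardinal direction, with
standard bilinear weights

    w_dir ∝ max(0, 1 − |Δx|/size_clim) · max(0, 1 − |Δy|/size_clim),

renormalised to sum to one over the available centres. This form is a
partition of unity, collapses to weight 1 at a climate-cell centre,
decreases monotonically with the centre's distance components, is
exact for driver fields linear in x and y, and degrades gracefully to
nearest-cell at lattice boundaries. Interpolated values always lie in
the convex hull of the contributing cells' same-day values.

Climate years can be resampled without losing long-term trends by
permuting whole years within disjoint consecutive 20-year blocks
aligned to the series start. One permutation per block is applied
jointly to all cells and all three drivers, so years move as
spatially coherent units and per-block means of every driver are
conserved. Each replicate draws its own permutation from a seed
derived from (master seed, replicate index).

## Life-cycle machine

Each stage carries daily base rates — mortality, development,
transfer (the maturation probability applied once a cohort's
accumulated development fraction reaches 1), fecundity and dispersal
(imago only) — modified multiplicatively by *influences*: piecewise
linear responses of a driver value to a rate multiplier, clamped at
their boundary nodes. An influence may carry a persistence window: it
only applies after its driver has stayed below a threshold for a
minimum number of consecutive days (used for egg drought stress under
sustained dry soil). Mortality and development are clipped to [0, 1]
as daily probabilities; fecundity (eggs per individual per day) is
only clipped to ≥ 0, since clutch laying can exceed one egg per day.

Daily stochasticity: deaths are Binomial(count, mortality) per cohort;
maturation moves Binomial(count, transfer) individuals to the next
stage once development ≥ 1 (binomial thinning on the following days);
oviposition is Poisson(imago count × fecundity) — Poisson rather than
binomial because the per-capita daily egg output may exceed one. The
diapause stage's development is gated by a calendar window (release in
spring, days 61–180 by default), which prevents premature development
during mild winters. All stages are updated against the pre-update
state: oviposition uses the pre-mortality imago count, and transfers
plus new eggs are buffered and appended after all stages are
processed, so no cohort can advance two stages in a day.

### Default parameterisation (`lmg_default`)

The stage table is fully configuration-driven (JSON-loadable with
validated schema); nothing species-specific is hard-coded in the
engine. The shipped default encodes the qualitative phenology of the
large marsh grasshopper on the synthetic climate: eggs laid from
mid-July develop through prediapause (≈ 55 days at reference
temperature) into diapause by late autumn; diapause releases in March;
embryos hatch from late May (temperature-accelerated); larvae mature
over the summer into imagos from mid-July; cold autumn temperatures
remove larvae and imagos, so year-end populations are concentrated
(≳ 95 %) in the diapause stage. Egg stages suffer eight-fold mortality
after ≥ 14 consecutive days of contact water below 1 kg m⁻² (the
generator places the contact-water minimum in late August, so this
stress is exercised annually).

All numerical values in the default table are this package's own
calibration, not field measurements. The calibration targets, chosen
once, were: (i) the stage timing windows above; (ii) a near-neutral,
mildly growing population under the moderate scenario with low-impact
mowing (realised stochastic growth rate λ ≈ 1.05 yr⁻¹ over 60 years);
and (iii) temperature responses flat enough that six decades of
warming shift λ by tens of percent rather than orders of magnitude —
without any density dependence (deliberately out of scope), steeper
responses would make late-century populations explode numerically and
physically implausibly. Within these constraints the species still
benefits from warming: growth is higher under the severe scenario and
lower (often sub-replacement) under the mild one.

## Mowing

A schedule is up to three fixed days-of-year, day = (week − 1) × 7
from the calendar week; the 18 built-in schedules are `M00` (weeks 20
and 44, the low-impact baseline) plus `M22`–`M38` variants. A cut
deterministically scales aboveground stages (larva, imago) by
1 − 0.9 and belowground egg stages by 1 − 0.05 by default; both
fractions are configurable and are this package's own defaults.
Mowing precedes the day's demographic step, so the cut acts on the
standing population and dispersal uses post-mowing imago densities.
The run's source cell is always pinned to `M00` regardless of the
configured schedule, serving as an undisturbed dispersal source.

## Dispersal

Per source cell, targets are all grassland cells within the 1 500 m
radius, plus — in each of the eight cardinal/secondary directions
whose open 45° sector (boundary rays excluded) holds no in-radius
grassland — the nearest grassland cell beyond the radius (LDD;
distance ties break on the lowest cell id). LDD targets run through
the same kernel machinery as regular ones.

The kernel factors are deliberately isolated behind one function each
so alternative forms are drop-in replacements:

* preference: `pref = d^(−pref_near) / Σ d^(−pref_near)` over all
  neighbours jointly (pref_near = 1);
* finding: `p_find = sight + (1 − sight)·cover` (sight = 0.5), with
  `cover` the grassland fraction within the dispersal radius of the
  source centre;
* survival: `p_surv = exp(−0.04 · (d/250 m) · (2 − cover))`, so zero
  cover doubles dispersal mortality relative to full cover.

These forms satisfy the intended monotonicities (closer targets
preferred, more cover ⇒ better finding and survival, longer flights ⇒
lower survival). Emigrants are Binomial(imago count, 0.00595); the
base rate is the one-disperser-in-168 mark–recapture fraction rounded
to three significant figures. Emigrants are allocated in a single
multinomial draw over targets ∪ {death} with probabilities
p_disp ∪ {1 − Σ p_disp}, so individuals are conserved exactly, and are
removed from the source cohorts by a multivariate hypergeometric draw
(for populations beyond the sampler's 10⁹ limit, a multinomial on
cohort shares, indistinguishable at emigrant counts ≪ population).
The budget identity Σ rates + dispersal mortality = base rate holds to
1e-12 for every kernel and is asserted in the test suite.

## Engine

Daily ordering is fixed: mowing → demography (oviposition, deaths,
development, transfers) → dispersal → activation of newly colonised
cells; dispersal flows are buffered and applied synchronously, so
arrivals participate from the next day and within-day chain dispersal
is impossible. Runs start with 0.725 eggs m⁻² in the diapause stage in
the grassland cell nearest the chosen climate cell's centre and stop
at the horizon or at global extinction (absorbing).

Internally the engine keeps every cohort of every inhabited cell in
flat parallel arrays (cell row, stage, count, development, age) and
performs each day's binomial/Poisson/multinomial draws as a handful of
vectorised calls over them; one counter-based (Philox) stream drives a
replicate. The layout is canonical — rows in colonisation order,
cohorts appended chronologically — so results are deterministic under
a fixed master seed and independent of any cell enumeration order.
Because effective rates depend only on the interpolated drivers at a
cell (persistence counters included, which are functions of the driver
series alone), each cell's full-horizon daily rate table is
precomputed once at colonisation. Only inhabited cells consume per-day
work. The per-cell operations in `lifecycle` (`step_stage`,
`step_population`, `reproduce`) define the per-cell contract and are
exercised directly by the unit tests; engine-level moment and
conservation tests pin the vectorised path to the same distributions.

## Synthetic data

The generators emulate the statistical structure the simulator
assumes, for a north-German lowland setting:

* temperature: mean 9 °C, seasonal amplitude 8.5 °C peaking at day 196
  (mid-July), a linear warming trend, a north–south gradient of
  1 °C per 100 km (cooler north), and shared AR(1) noise (σ = 0.5 °C,
  φ = 0.7) so weather fronts are regionally coherent;
* scenario severities FF/MOD/BAU with trends +0.5/+1.5/+3.5 °C per
  60 years — synthetic stand-ins of increasing severity, ordered like
  mitigation/moderate/business-as-usual storylines;
* contact water: seasonal around 3 kg m⁻² with a late-August minimum
  near 1 kg m⁻² (so egg drought stress is exercisable), clipped ≥ 0;
* humidity: seasonal around 80 %, clipped to [0, 100];
* landscapes: a Gaussian random field smoothed with a kernel whose
  width grows with the clustering parameter, thresholded at the cover
  quantile — realised cover matches the target to one cell, and
  clustering monotonically raises same-class adjacency.

What the generators do **not** emulate: real orography or coastlines,
precipitation extremes and multi-year droughts, correlated
temperature–moisture anomalies, land-use change over time, and
observational error. Passing tests therefore demonstrate internal
consistency of the machinery and the qualitative phenology/disturbance
logic on plausible inputs — not calibration to any real region.

## Numerical choices

* Density→count rounding is half-up (0.725 m⁻² ⇒ 45 313 per cell);
  counts of zero prune the cohort.
* Mowing scales counts deterministically (no sampling), rounding
  half-up.
* Bilinear weights renormalise over available centres at boundaries;
  a point outside all centre rectangles falls back to nearest-centre
  weight 1.
* LDD sector boundaries are open; candidate ties break on the lowest
  cell id; distances are planar Euclidean centre-to-centre (the
  lattice is abstract, no geodesy).
* The yearly establishment flag uses a running per-cell maximum of
  daily imago density (threshold 0.002 m⁻², inclusive); no daily
  series are stored. Colonisation provenance (direct LDD from the
  source vs other) is tagged at first arrival and sticky; the
  established-distance maximum drops direct-LDD colonies.
* Year-end snapshots are taken on day 364; population size and density
  are reported over established cells (in eggs, as year-end
  populations sit in diapause).
* Cross-region association uses Spearman rank correlation; undefined
  (zero-variance) cases report NaN.
* Replicate seeds derive from the master seed via `SeedSequence`
  (climate resampling) and a Philox key offset (demography), keeping
  replicates independent and reproducible.

## Problem sizes used in tests and the acceptance script

Property checks that need full 60-year horizons (single-cell
confinement without dispersal, and the M00-versus-M28 mowing-window
comparison) run on a 6×6 all-grassland lattice with the source at the
centre — the smallest landscape whose corner cells (1 768 m) lie
beyond the 1 500 m dispersal radius, so the establishment front can
demonstrably cross it. The mowing-window check uses ten replicate
pairs in the test suite and three in the acceptance script;
conservation runs ten years; kernel and moment checks use 1 000 random
kernels and 500 replicate draws at n = 10⁴.

## Known limitations

* No density dependence, predation or vegetation structure: benign
  conditions give sustained (super-)exponential growth, so very long
  benign runs are climate- and disturbance-limited only.
* The default vital rates are a calibrated, qualitative stand-in; any
  quantitative application requires transcribing measured rates into
  the stage-table configuration.
* Mowing dates are fixed; farmers' climate-responsive scheduling is
  out of scope, as are movement barriers, wind and within-cell habitat
  quality.
* One dispersal kernel per source cell is cached for the run;
  landscapes are static.
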