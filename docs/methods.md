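# Methods

`kinproj` projects the expected kinship network of a female reference
individual ("Focal") from period, age-specific fertility and survival
schedules, using the matrix formulation of kinship demography: each kin type
is a small age-structured population projected with the same survival and
fertility operators as the population at large.

## The kinship model

Time advances in steps equal to the age-class width (5 years by default,
on a 21-class grid 0–4 … 100+). For one sex, the operators are

- `U` — survival matrix, per-step survival probabilities `p[x]` on the
  subdiagonal; the last class is open-ended and absorbs no one (`p[ω−1] = 0`:
  kin die upon leaving the grid);
- `F` — fertility matrix, per-step rates `f[x]` (births per woman per step)
  in the first row; newborns enter class 0 without mortality exposure inside
  their birth interval.

Each of 14 kin types (children a, grandchildren b, great-grandchildren c,
parents d, grandparents g, great-grandparents h, older/younger siblings m/n,
niblings p/q, aunts/uncles r/s, cousins t/v) obeys the same recursion along
Focal's life: counts at Focal age x+1 are the survivors of the counts at age
x plus recruitment `F·source(x)`, where the source is the kin population that
gives birth to the type (Focal herself for children, children for
grandchildren, the mother for younger siblings, grandmothers for younger
aunts/uncles, aunts/uncles for cousins; ancestor types have no recruitment).
The ten reported categories merge the older/younger splits.

Boundary conditions at Focal's birth are anchored in π, the age distribution
of mothers of current newborns, `π[x] ∝ f[x]·w[x]` with `w` the female age
structure. Focal's mother is a π-draw; her older siblings at birth are the
π-mixture of children already borne by a mother of age x; grandparents are
the π-mixture of a parent's parents; and so on recursively. Because the
recruitment graph is acyclic, types are evaluated in dependency order with
memoization; no iteration is needed.

**Time-invariant model.** One fixed rate regime operating indefinitely. π is
taken from the *stable-equivalent* population implied by the regime itself
(dominant eigenvector of `U + F` restricted to the female/newborn-female
part), which is the natural reading of a boundary regime that has been
operating for a long time. This model supplies the initial condition of a
projection at its first year.

**Time-variant model.** Rates change every period; kin arrays are marched
along cohort lines, `K(x+1, t+1) = U_t K(x, t) + F_t src(x, t)`, and the
Focal-age-0 boundary at each new period is rebuilt from that period's own
arrays, with π computed from the *observed* population structure stored in
the rate series. When the series is time-constant and its population equals
the variant-consistent stable structure, the time-variant model reproduces
the time-invariant one exactly (machine precision); this is a regression
test.

**Two-sex androgynous variant.** Kin vectors stack a female and a male block
(length 2ω); survival is sex-specific, `blockdiag(U_f, U_m)`. Male fertility
schedules are rarely available, so male kin reproduce at the female
(androgynous) rates unless a male schedule is supplied; births split between
the sex blocks by the fraction female α (default 100/205, SRB 1.05). The
boundary uses a sex-symmetric allocation: under androgynous fertility the kin
arrays of a male and a female of the same age coincide, so the father block
of `d(0)` is π as well, and every boundary sum that runs through *both*
parents (grandparents, great-grandparents, aunts/uncles, cousins) carries a
factor 2. Siblings are defined through the mother only, and recruitment of
younger siblings / younger aunts-uncles applies fertility to the female block
of the source array (mothers / grandmothers); otherwise each birth would be
counted once per spouse. These conventions yield the structural bounds
parents ≤ 2, grandparents ≤ 4, great-grandparents ≤ 8 at every age and time.

**One-sex variant.** A single female-line block. The fertility schedule is
applied as given (all offspring tracked through female lines), which makes
the closed form for children `a(x) = Σ_{y<x} f[y]·S(y-birth → x)` exact and
gives one parent at birth. A strictly matrilineal daughters-only model is
obtained by pre-scaling `f` by α.

Counts are expectations conditional on Focal being alive at the reported
age; no within-trajectory variance is propagated (uncertainty enters only
through the rate-trajectory ensemble). Focal ages are reported at class
lower bounds ("65" means the class [65, 70)), and a year label means its
5-year interval.

## Rate inputs

Rates are read from a long-format CSV (location, year, age_lower, sex,
variable, value; variable ∈ {asfr, Lx, population}) with eager validation:
missing blocks, duplicates, negative values and irregular age spacing are
errors, never silently repaired. Annualised inputs are converted as
`f[x] = asfr[x]·step` and `p[x] = L[x+1]/L[x]` (period life-table
approximation), clipped to [0, 1]. An optional column mapping adapts other
export formats to the canonical schema.

## Synthetic rate generator

The generator emulates the statistical *structure* of probabilistic national
rate projections, not any particular country's values:

- **Fertility**: a beta density over the reproductive span 10–55 y with the
  requested mean age and width, integrated over age classes and scaled so
  the per-step rates sum exactly to the TFR.
- **Mortality**: Gompertz–Makeham hazard `h(a) = M + c·e^{Ba}` with `c`
  calibrated by bisection so that life expectancy at birth (trapezoid on a
  0.25-y grid) hits the target to well within 0.25 y; male e0 is the female
  target minus a sex gap (default 4 y). Per-step survival comes from the Lx
  ratios of the fine-grained survivorship curve.
- **Trends**: every schedule parameter interpolates logistically in calendar
  time between a start and an end regime (midpoint year, transition speed).
- **Population structures** are the period-stable age-sex composition of
  each year's own rates (λ^{−x}-discounted survivorship, split by α), scaled
  to 100,000 persons — so the constant-rates regression identity holds
  exactly on generated series.
- **Trajectory ensembles**: years after a "present" year (default 2020,
  mirroring the estimates-versus-projections split of rate databases)
  receive seeded random walks on log-TFR and on the log mortality hazard
  level (innovation SD 0.03 per step by default); fertility schedules are
  rescaled, mortality schedules rebuilt from the perturbed hazard. Random
  walks rather than mean-reverting processes: the emulator only needs a
  widening, seedable fan of valid schedules. Trajectories share the median
  path's population structures; the perturbations enter through rates only,
  so the boundary π of a trajectory tracks the median population — a
  second-order approximation that keeps ensemble generation cheap.

The built-in two-country world spans the global contrast: a high-fertility,
high-mortality country with a steep late transition (TFR 6.5 → 1.8,
e0 50 → 78, midpoint 2030) and an aged low-fertility country (TFR 2.3 → 1.4,
e0 66 → 88, midpoint 1990, childbearing postponed to 33 y). What the
generator does **not** emulate: migration, period shocks (wars, epidemics,
baby booms), cohort effects, between-country trajectory correlation, and the
posterior dependence structure of real Bayesian projection models. Tests
passing on synthetic data therefore validate the projection arithmetic and
its contracts, not the realism of any particular country scenario.

## Microsimulation oracle

The expectation kernel is validated against a brute-force genealogical
simulation that knows nothing of the recursions: individuals with recorded
sex, birth/death steps and parent links; Poisson births by the mother's age
class (`f[x]` per step; a deterministic mode uses rounded expectations for
exact small checks); Bernoulli survival by age and sex; fathers sampled from
living males with weights proportional to androgynous fertility at their
age. Founders are drawn from the stable age distribution and a burn-in of
six generations (30 steps) precedes any tally, so great-grandparents and the
lateral branches of sampled Focals are fully inside the recorded pedigree.

Kin of sampled Focals are classified by walking the pedigree with exactly
the kernel's definitions (siblings through the mother, older/younger splits
by birth step with same-interval ties counted as younger — the kernel's
recruitment accounts for same-interval births via the Palm property of the
Poisson process, which excludes Focal herself automatically).

One timing convention must be mirrored for the comparison to be exact at
Monte Carlo precision. The kernel anchors each boundary in π, the mothers
*currently giving birth*, assigned their pre-registration age class with no
mortality exposure; every π-composition up the pedigree repeats this one
generation higher. Relative to the simulation's registration clock (newborns
recorded at the end of their birth interval) each composition places the
counted kin one step earlier, so the tally evaluates each kin type at
`t − depth`, where depth is the type's π-depth: 0 for descendants, 1 for
parents/siblings/niblings, 2 for grandparents/aunts-uncles/cousins, 3 for
great-grandparents. This is a property of the discrete-time model itself
(its Focal-age clock runs half a step ahead of the cohort registration
clock), not of the implementation; without the offsets, ancestor counts
disagree by one survival step per generation of remove.

The headline comparison regime is TFR 4, e0 60 for both sexes, fraction
female 0.5, 2,000 founders: with symmetric sexes the androgynous model's
sex-symmetry assumption holds exactly in the simulated population, so any
discrepancy isolates Monte Carlo noise or an implementation defect.
Agreement is asserted within 3 standard errors across Focals plus a
resolution floor of one observed kin (1/N), which covers expectations far
below what N Focals can resolve (e.g. 10⁻⁶ grandparents at age 65).

## Pipeline and summaries

Per location and trajectory: time-invariant boundary at the first year →
time-variant projection → category totals, total family size (sum of the ten
categories over all kin ages and sexes, Focal excluded) and count-weighted
mean kin ages (class midpoints; an empty kin population raises a signal
rather than returning a number). Ensembles are summarised by the median and
the 10th/90th percentiles (80% projection interval) using linear
interpolation of order statistics (quantile type 7; the rule is recorded in
the output metadata since several conventions exist). Regional aggregates
are, per trajectory, the population-weighted mean over member countries —
weights default to the female population in Focal's age class at that time —
summarised across trajectories afterwards, so the interval reflects
trajectory uncertainty of the weighted mean, not pooled country spread. One
weighting rule is applied across the whole period.

All randomness flows from a single seed; per-location sub-seeds are derived
deterministically, and rerunning a configuration reproduces output files
byte for byte.

## Numerical choices and problem sizes

- Deterministic identities are asserted at 1e-10 absolute; π normalization
  at 1e-12. Exact arithmetic identities typically hold to ~1e-15.
- The stable structure uses a dense eigendecomposition of the ω×ω female
  projection matrix (ω = 21: negligible cost).
- The kernel exploits operator structure (subdiagonal survival, first-row
  fertility) instead of dense matrix products: one trajectory over 31
  periods costs a few tens of milliseconds, so 1,000-trajectory ensembles
  run in well under a minute per country.
- The default test suite simulates up to ~150k individuals (2,000 founders,
  46 steps) and tallies ≤ 600 Focals per age; the full acceptance script
  runs the 1,000-trajectory two-country analysis end to end.

## Known limitations

- Closed to migration; rates are independent within and across generations
  (no parity, union, or socio-economic structure; no mortality clustering in
  families).
- The androgynous approximation slightly overstates male-line ancestors when
  true male fertility schedules are older than female ones.
- Expectations only: the model says nothing about the distribution of kin
  counts within a trajectory (e.g. the probability of having *no* living
  sibling).
- The open-ended age class retains no survivors, which truncates extreme-age
  ancestors (visible only where expectations are already ~10⁻⁶).
- The time-invariant boundary imprints the first period's rates on early
  decades of a projection; its influence dissipates over time.
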