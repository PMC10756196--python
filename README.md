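# kinproj

Matrix kinship projections: the expected number, age and sex of every type
of living relative of a female reference individual ("Focal"), computed from
period age-specific fertility and survival schedules.

Demographers, epidemiologists and social scientists who study informal care,
bereavement, or family support need to know not just how many people will be
alive, but how many *relatives* each person can expect — grandparents of a
newborn, children and siblings of a 35-year-old, grandchildren of a retiree.
`kinproj` answers this with the formal demography of kinship: each kin type
is a small age-structured population projected with a survival matrix `U`
(per-step survival probabilities on the subdiagonal) and a fertility matrix
`F` (age-specific rates in the first row). For example, Focal's
granddaughters obey

```
b(x+1, t+1) = U_t · b(x, t) + F_t · a(x, t)
```

— the survivors of the existing granddaughters plus the newborn daughters of
Focal's daughters `a(x, t)`. Boundary conditions at Focal's birth are
anchored in π, the age distribution of mothers of newborns. The package
provides:

- **`rates`** — validated schedule containers on a 5-year age × time grid,
  `U`/`F` construction, annual→per-step conversion, and long-format CSV I/O;
- **`kernel`** — the kinship engine: 14 kin types, time-invariant
  (fixed-rates boundary) and time-variant (rates change each period) models,
  one-sex and two-sex androgynous variants (male kin reproduce at female
  rates; births split by the fraction female);
- **`synthetic`** — a generator of realistic schedules, secular trends and
  seeded stochastic trajectory ensembles, so everything runs with no
  external data;
- **`microsim`** — a genealogical microsimulation oracle: explicit pedigrees
  under the same rates, tallied kin by pedigree walking, for Monte Carlo
  validation of the kernel;
- **`pipeline`** — total family size, mean kin ages, ensemble medians with
  80% projection intervals, population-weighted regional aggregation, and an
  end-to-end `run_analysis`;
- a thin **CLI** (`kinproj run / validate-rates / make-fixtures /
  oracle-check`) and narrative scripts under `examples/`.

## Worked example

Expected kin of a woman under a fixed high-fertility regime (TFR 4, life
expectancy 60), two-sex androgynous model — `examples/02_kin_network.py`:

```
expected living kin (TFR 4, e0 60 regime held fixed)

kin category                   0        35        65  mean age @35
children                    0.00      3.43      3.54          8.6y
grandchildren               0.00      0.01     11.41          2.7y
great_grandchildren         0.00      0.00      0.49             -
parents                     2.00      1.05      0.01         60.2y
grandparents                3.02      0.13      0.00         74.3y
great_grandparents          1.49      0.00      0.00         82.3y
siblings                    1.38      3.59      1.94         31.3y
niblings                    0.01      8.04     13.28          8.9y
aunts_uncles                7.34      4.77      0.40         52.6y
cousins                     6.69     26.79     17.63         25.8y

total family size at age 0: 21.9 living relatives
total family size at age 35: 47.8 living relatives
total family size at age 65: 48.7 living relatives
```

Reading the table: a newborn has her two parents with certainty, 3.0 of her
4 grandparents alive, and already ~7 aunts/uncles; by 35 she has 3.4 living
children (mean age ~9) and nearly 27 cousins; by 65, grandchildren (11.4)
dominate her network. "Total family size" sums the ten categories over all
kin ages and sexes.

A probabilistic projection on the built-in two-country synthetic world
(`examples/03_projection_ensemble.py`) shows the demographic transition
shrinking families — median and 80% projection interval across a seeded
trajectory ensemble:

```
HighFertility: total family size of a 65-year-old woman (25 trajectories)
  1950: median  89.8  (identical past)
  2050: median  82.6  [ 81.6 to  84.0] 80% interval
  2095: median  51.7  [ 48.4 to  56.9] 80% interval

LowFertility: total family size of a 65-year-old woman (25 trajectories)
  1950: median  17.6  (identical past)
  2095: median  12.6  [ 12.0 to  13.7] 80% interval
```

`examples/04_oracle_check.py` validates the kernel against the explicit
microsimulation (142k simulated individuals; all kin categories agree within
~1.6 Monte Carlo standard errors).

From a shell, the same analysis is:

```sh
kinproj run --synthetic demo --trajectories 100 --seed 7 --out results/
```

which writes tidy `trajectories.csv`, `summary.csv`, `regional.csv`,
`kin_full.csv` tables plus a `metadata.yaml` echo of the configuration.

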