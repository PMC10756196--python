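"""Synthetic demographic rate schedules, trends, and trajectory ensembles.

This module generates structurally realistic inputs for the kinship model
without any external data: smooth unimodal fertility age schedules, Gompertz–
Makeham mortality calibrated to a target life expectancy, secular trends
(logistic transition between a start and an end regime, emulating fertility
decline/postponement and mortality improvement), and seeded stochastic
ensembles of future rate trajectories that fan out around the median path —
the statistical shape, though not the substance, of probabilistic national
projections.

All outputs are the validated containers of :mod:`kinproj.rates`, so
synthetic data exercise exactly the code paths real data would.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .rates import (
    ALPHA_DEFAULT,
    AgeGrid,
    FertilitySchedule,
    MortalitySchedule,
    PopulationStructure,
    RateSeries,
)

__all__ = [
    "ScheduleParams",
    "TrendParams",
    "TrajectoryEnsemble",
    "CalibrationError",
    "make_fertility",
    "make_mortality",
    "make_rate_series",
    "sample_trajectories",
    "two_country_world",
]

# Reproductive age span (years) over which fertility mass is laid down.
_REPRO_LO = 10.0
_REPRO_HI = 55.0


class CalibrationError(RuntimeError):
    """Mortality level could not be calibrated to the requested e0."""


@dataclass(frozen=True)
class ScheduleParams:
    """Parameters of one period's fertility and mortality age schedules.

    tfr:
        births per woman over the reproductive span (Σ per-step rates).
    mean_age_childbearing:
        fertility-weighted mean age of mothers, years.
    fertility_width:
        standard deviation of the fertility age schedule, years.
    life_expectancy_target:
        female life expectancy at birth, years; the Gompertz–Makeham level is
        calibrated to hit it. Male e0 = target − sex_gap_years.
    gompertz_slope:
        senescent mortality slope, per year of age.
    makeham_level:
        age-independent background hazard, per year.
    sex_gap_years:
        female-minus-male gap in life expectancy at birth, years.
    """

    tfr: float
    mean_age_childbearing: float
    fertility_width: float = 6.0
    life_expectancy_target: float = 70.0
    gompertz_slope: float = 0.1
    makeham_level: float = 0.002
    sex_gap_years: float = 4.0

    def __post_init__(self):
        if self.tfr < 0:
            raise ValueError("tfr must be non-negative")
        if not (10.0 < self.mean_age_childbearing < 55.0):
            raise ValueError("mean_age_childbearing must lie in (10, 55)")
        if not (20.0 < self.life_expectancy_target < 110.0):
            raise ValueError("life_expectancy_target must lie in (20, 110)")
        if self.fertility_width <= 0:
            raise ValueError("fertility_width must be positive")


@dataclass(frozen=True)
class TrendParams:
    """A secular trend between two regimes plus a stochastic future fan.

    The median path interpolates every :class:`ScheduleParams` field
    logistically in calendar time (midpoint ``midpoint_year``, steepness set
    by ``transition_speed_years``). Trajectories branch after ``present_year``:
    log-TFR and the log mortality hazard level each follow a seeded random
    walk with innovation standard deviation ``trajectory_noise`` per step.
    """

    start: ScheduleParams
    end: ScheduleParams
    midpoint_year: float = 2000.0
    transition_speed_years: float = 25.0
    trajectory_noise: float = 0.03
    n_trajectories: int = 1000
    seed: int = 0
    present_year: float = 2020.0
    frac_female: float = ALPHA_DEFAULT
    location: str | None = None

    def __post_init__(self):
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be at least 1")
        if self.trajectory_noise < 0:
            raise ValueError("trajectory_noise must be non-negative")


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """A median rate path plus sampled future rate trajectories."""

    median: RateSeries
    trajectories: tuple
    present_year: float
    seed: int

    @property
    def n_trajectories(self) -> int:
        return len(self.trajectories)


# ---------------------------------------------------------------------------
# Age schedules
# ---------------------------------------------------------------------------

def make_fertility(
    p: ScheduleParams, grid: AgeGrid, frac_female: float = ALPHA_DEFAULT
) -> FertilitySchedule:
    """Smooth unimodal fertility schedule with Σ f[x] = tfr.

    The shape is a beta density over the reproductive span (10–55 y) with the
    requested mean and width, integrated over each age class, then scaled so
    the per-step rates sum to the TFR exactly. A zero TFR yields the zero
    schedule.
    """
    n = grid.n_classes
    f = np.zeros(n)
    if p.tfr > 0:
        span = _REPRO_HI - _REPRO_LO
        m = (p.mean_age_childbearing - _REPRO_LO) / span
        v = min((p.fertility_width / span) ** 2, 0.95 * m * (1.0 - m))
        conc = m * (1.0 - m) / v - 1.0
        a, b = m * conc, (1.0 - m) * conc
        lo = np.asarray(grid.lower_bounds, dtype=float)
        hi = lo + grid.step_years
        # mass of the beta density falling in each age class
        cdf = stats.beta.cdf
        mass = cdf((hi - _REPRO_LO) / span, a, b) - cdf((lo - _REPRO_LO) / span, a, b)
        mass[hi <= _REPRO_LO] = 0.0
        mass[lo >= _REPRO_HI] = 0.0
        mass[mass < 1e-12 * mass.max()] = 0.0
        f = p.tfr * mass / mass.sum()
    return FertilitySchedule(f=f, frac_female=frac_female)


def _gm_survival(makeham: float, slope: float, level: float, ages: np.ndarray) -> np.ndarray:
    """Gompertz–Makeham survivorship ℓ(a) for hazard M + level·exp(slope·a)."""
    return np.exp(-makeham * ages - (level / slope) * (np.exp(slope * ages) - 1.0))


def _calibrate_gm_level(
    makeham: float, slope: float, e0_target: float, ages: np.ndarray
) -> float:
    """Bisection on the log hazard level so ∫ℓ matches the target e0."""
    da = ages[1] - ages[0]

    def e0(log_level: float) -> float:
        return float(np.trapezoid(_gm_survival(makeham, slope, np.exp(log_level), ages), dx=da))

    lo, hi = np.log(1e-12), np.log(10.0)
    if not (e0(hi) <= e0_target <= e0(lo)):
        raise CalibrationError(
            f"life expectancy target {e0_target} unattainable with "
            f"makeham={makeham}, slope={slope}"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if e0(mid) > e0_target:
            lo = mid
        else:
            hi = mid
        if abs(e0(mid) - e0_target) < 1e-3:
            break
    return float(np.exp(0.5 * (lo + hi)))


def _fine_ages(grid: AgeGrid) -> np.ndarray:
    top = grid.lower_bounds[-1] + grid.step_years
    return np.arange(0.0, top + 0.25, 0.25)


def _survival_from_ell(
    ell: np.ndarray, ages: np.ndarray, grid: AgeGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Per-step survival p[x] = L[x+1]/L[x] and Lx from a fine ℓ curve."""
    da = ages[1] - ages[0]
    per_class = int(round(grid.step_years / da))
    n = grid.n_classes
    L = np.empty(n)
    for x in range(n):
        sl = ell[x * per_class : x * per_class + per_class + 1]
        L[x] = np.trapezoid(sl, dx=da)
    p = np.zeros(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(L[:-1] > 0.0, L[1:] / np.where(L[:-1] > 0.0, L[:-1], 1.0), 0.0)
    p[:-1] = np.clip(ratio, 0.0, 1.0)
    return p, L


def make_mortality(p: ScheduleParams, grid: AgeGrid, sex: str = "female") -> MortalitySchedule:
    """Gompertz–Makeham survival schedule calibrated to the target e0.

    The hazard is h(a) = makeham_level + c·exp(gompertz_slope·a) with c found
    by bisection so that life expectancy at birth on a fine age grid matches
    ``life_expectancy_target`` (females; males use target − sex_gap_years) to
    well within 0.25 y. Per-step survival probabilities come from the
    life-table Lx ratios.
    """
    target = p.life_expectancy_target - (p.sex_gap_years if sex == "male" else 0.0)
    if not (20.0 < target < 110.0):
        raise CalibrationError(f"implied {sex} e0 target {target} outside (20, 110)")
    ages = _fine_ages(grid)
    level = _calibrate_gm_level(p.makeham_level, p.gompertz_slope, target, ages)
    ell = _gm_survival(p.makeham_level, p.gompertz_slope, level, ages)
    pvec, _ = _survival_from_ell(ell, ages, grid)
    return MortalitySchedule(sex=sex, p=pvec)


# ---------------------------------------------------------------------------
# Trends and ensembles
# ---------------------------------------------------------------------------

def _logistic_mix(tp: TrendParams, year: float) -> ScheduleParams:
    s = 1.0 / (1.0 + np.exp(-(year - tp.midpoint_year) / tp.transition_speed_years))

    def mix(a, b):
        return float(a + (b - a) * s)

    return ScheduleParams(
        tfr=mix(tp.start.tfr, tp.end.tfr),
        mean_age_childbearing=mix(tp.start.mean_age_childbearing, tp.end.mean_age_childbearing),
        fertility_width=mix(tp.start.fertility_width, tp.end.fertility_width),
        life_expectancy_target=mix(
            tp.start.life_expectancy_target, tp.end.life_expectancy_target
        ),
        gompertz_slope=mix(tp.start.gompertz_slope, tp.end.gompertz_slope),
        makeham_level=mix(tp.start.makeham_level, tp.end.makeham_level),
        sex_gap_years=mix(tp.start.sex_gap_years, tp.end.sex_gap_years),
    )


def _stable_population(
    fert: FertilitySchedule,
    mort_f: MortalitySchedule,
    mort_m: MortalitySchedule,
    grid: AgeGrid,
    scale: float = 1e5,
) -> PopulationStructure:
    """Period-stable age-sex structure implied by one year's rates."""
    from .kernel import stable_population_structure  # local import, no cycle at module load
    from .rates import RatePeriod

    per = RatePeriod(
        grid=grid, time=0.0, fertility=fert,
        survival_female=mort_f, survival_male=mort_m,
        population=PopulationStructure(
            female=np.ones(grid.n_classes), male=np.ones(grid.n_classes)
        ),
    )
    _, w = stable_population_structure(per, "two_sex_androgynous")
    return PopulationStructure(female=scale * w.female, male=scale * w.male)


def make_rate_series(tp: TrendParams, grid: AgeGrid, years) -> RateSeries:
    """Median rate path: logistic interpolation between start and end regimes.

    Population structures are set to the period-stable structure of each
    year's own rates, scaled to 100,000 persons.
    """
    years = [float(y) for y in years]
    fert, surv_f, surv_m, pops = [], [], [], []
    for y in years:
        sp = _logistic_mix(tp, y)
        fs = make_fertility(sp, grid, frac_female=tp.frac_female)
        mf = make_mortality(sp, grid, "female")
        mm = make_mortality(sp, grid, "male")
        fert.append(fs)
        surv_f.append(mf)
        surv_m.append(mm)
        pops.append(_stable_population(fs, mf, mm, grid))
    return RateSeries(
        grid=grid, times=tuple(years), fertility=tuple(fert),
        survival_female=tuple(surv_f), survival_male=tuple(surv_m),
        population=tuple(pops), location=tp.location,
    )


def sample_trajectories(
    tp: TrendParams, grid: AgeGrid, years, seed: int | None = None
) -> TrajectoryEnsemble:
    """Seeded ensemble of future rate trajectories around the median path.

    Years up to and including ``present_year`` are identical across
    trajectories. After it, log-TFR and the log mortality hazard level follow
    independent random walks (innovation SD ``trajectory_noise`` per 5-y
    step); fertility schedules are rescaled and mortality schedules rebuilt
    from the perturbed hazard, so every trajectory is a valid
    :class:`~kinproj.rates.RateSeries`. Population structures are shared with
    the median path. With noise = 0 every trajectory equals the median path.
    """
    years = [float(y) for y in years]
    median = make_rate_series(tp, grid, years)
    rng = np.random.default_rng(tp.seed if seed is None else seed)
    future = [i for i, y in enumerate(years) if y > tp.present_year]
    nf = len(future)
    ages = _fine_ages(grid)

    # calibrated hazard parameters of the median path at future years
    gm_params = []
    for i in future:
        sp = _logistic_mix(tp, years[i])
        row = {}
        for sex in ("female", "male"):
            target = sp.life_expectancy_target - (sp.sex_gap_years if sex == "male" else 0.0)
            level = _calibrate_gm_level(sp.makeham_level, sp.gompertz_slope, target, ages)
            row[sex] = (sp.makeham_level, sp.gompertz_slope, level)
        gm_params.append(row)

    trajectories = []
    for _ in range(tp.n_trajectories):
        shocks_tfr = np.cumsum(rng.normal(0.0, tp.trajectory_noise, size=nf))
        shocks_mort = np.cumsum(rng.normal(0.0, tp.trajectory_noise, size=nf))
        fert = list(median.fertility)
        surv_f = list(median.survival_female)
        surv_m = list(median.survival_male)
        for j, i in enumerate(future):
            base = median.fertility[i]
            fert[i] = FertilitySchedule(
                f=base.f * np.exp(shocks_tfr[j]), frac_female=base.frac_female
            )
            hazard_scale = np.exp(shocks_mort[j])
            for sex, store in (("female", surv_f), ("male", surv_m)):
                mk, slope, level = gm_params[j][sex]
                ell = _gm_survival(mk * hazard_scale, slope, level * hazard_scale, ages)
                pvec, _ = _survival_from_ell(ell, ages, grid)
                store[i] = MortalitySchedule(sex=sex, p=pvec)
        trajectories.append(replace(
            median,
            fertility=tuple(fert),
            survival_female=tuple(surv_f),
            survival_male=tuple(surv_m),
        ))
    return TrajectoryEnsemble(
        median=median,
        trajectories=tuple(trajectories),
        present_year=tp.present_year,
        seed=int(tp.seed if seed is None else seed),
    )


def two_country_world(
    n_trajectories: int = 1000, trajectory_noise: float = 0.03, seed: int = 0
) -> dict[str, TrendParams]:
    """A stylised two-country world spanning the global demographic contrast.

    ``HighFertility`` starts from a young, high-fertility, high-mortality
    regime and undergoes a steep late transition; ``LowFertility`` is an
    already-aged low-fertility population converging to very low fertility,
    delayed childbearing and long lives. The pair exercises the projection
    pipeline across the range of regimes the kinship model is meant for.
    """
    return {
        "HighFertility": TrendParams(
            start=ScheduleParams(
                tfr=6.5, mean_age_childbearing=29.0, fertility_width=7.0,
                life_expectancy_target=50.0, sex_gap_years=3.0,
            ),
            end=ScheduleParams(
                tfr=1.8, mean_age_childbearing=31.0, fertility_width=6.0,
                life_expectancy_target=78.0, sex_gap_years=4.0,
            ),
            midpoint_year=2030.0, transition_speed_years=30.0,
            trajectory_noise=trajectory_noise, n_trajectories=n_trajectories,
            seed=seed, location="HighFertility",
        ),
        "LowFertility": TrendParams(
            start=ScheduleParams(
                tfr=2.3, mean_age_childbearing=28.0, fertility_width=5.5,
                life_expectancy_target=66.0, sex_gap_years=4.5,
            ),
            end=ScheduleParams(
                tfr=1.4, mean_age_childbearing=33.0, fertility_width=5.0,
                life_expectancy_target=88.0, sex_gap_years=4.0,
            ),
            midpoint_year=1990.0, transition_speed_years=25.0,
            trajectory_noise=trajectory_noise, n_trajectories=n_trajectories,
            seed=seed + 1, location="LowFertility",
        ),
    }
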