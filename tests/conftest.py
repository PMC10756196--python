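"""Shared fixtures: small hand-checkable regimes and the oracle regime."""

import numpy as np
import pytest

import kinproj as kp


@pytest.fixture(scope="session")
def grid21():
    return kp.AgeGrid.default()


@pytest.fixture(scope="session")
def grid3():
    return kp.AgeGrid(n_classes=3, step_years=5)


def make_period(grid, f, p_f, p_m=None, frac_female=0.5, pop_f=None, pop_m=None,
                time=0.0):
    """Assemble a RatePeriod from bare vectors."""
    n = grid.n_classes
    return kp.RatePeriod(
        grid=grid,
        time=time,
        fertility=kp.FertilitySchedule(f=np.asarray(f, float), frac_female=frac_female),
        survival_female=kp.MortalitySchedule(sex="female", p=np.asarray(p_f, float)),
        survival_male=kp.MortalitySchedule(
            sex="male", p=np.asarray(p_f if p_m is None else p_m, float)
        ),
        population=kp.PopulationStructure(
            female=np.ones(n) if pop_f is None else np.asarray(pop_f, float),
            male=np.ones(n) if pop_m is None else np.asarray(pop_m, float),
        ),
    )


@pytest.fixture(scope="session")
def oracle_regime(grid21):
    """Constant-rate regime for kernel-vs-microsimulation comparisons.

    TFR 4, e0 60, symmetric sexes (equal survival, half of births female) so
    the androgynous two-sex model's sex-symmetry assumption holds exactly in
    the simulated population.
    """
    sp = kp.ScheduleParams(
        tfr=4.0, mean_age_childbearing=28.0,
        life_expectancy_target=60.0, sex_gap_years=0.0,
    )
    fert = kp.make_fertility(sp, grid21, frac_female=0.5)
    mort = kp.make_mortality(sp, grid21, "female")
    return kp.RatePeriod(
        grid=grid21, time=0.0, fertility=fert,
        survival_female=mort,
        survival_male=kp.MortalitySchedule(sex="male", p=mort.p),
        population=kp.PopulationStructure(
            female=np.ones(grid21.n_classes), male=np.ones(grid21.n_classes)
        ),
    )


@pytest.fixture(scope="session")
def constant_series(grid21):
    """A time-constant synthetic series (population = two-sex stable)."""
    tp = kp.TrendParams(
        start=kp.ScheduleParams(tfr=3.0, mean_age_childbearing=28.0,
                                life_expectancy_target=65.0),
        end=kp.ScheduleParams(tfr=3.0, mean_age_childbearing=28.0,
                              life_expectancy_target=65.0),
        n_trajectories=1,
    )
    return kp.make_rate_series(tp, grid21, list(range(1950, 2005, 5)))


@pytest.fixture
def toy_rate_csv(tmp_path):
    """Canonical 2-location, 2-period long-format rate file."""
    lines = ["location,year,age_lower,sex,variable,value"]
    for loc, scale in (("A", 1.0), ("B", 0.5)):
        for year in (1950, 1955):
            for x, a in enumerate((0, 5, 10)):
                asfr = [0.0, 0.04 * scale, 0.0][x]
                lines.append(f"{loc},{year},{a},female,asfr,{asfr}")
            for sex in ("female", "male"):
                for x, a in enumerate((0, 5, 10)):
                    Lx = [5.0, 4.5, 3.0][x]
                    lines.append(f"{loc},{year},{a},{sex},Lx,{Lx}")
                for x, a in enumerate((0, 5, 10)):
                    popv = [100.0, 80.0, 60.0][x]
                    lines.append(f"{loc},{year},{a},{sex},population,{popv}")
    path = tmp_path / "rates.csv"
    path.write_text("\n".join(lines) + "\n")
    return path
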