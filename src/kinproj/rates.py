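"""Demographic rate schedules on a discrete age × time grid.

Everything downstream (the kinship kernel, the microsimulation, the
projection pipeline) consumes the containers defined here: an :class:`AgeGrid`
of equal-width age classes with an open-ended last class, per-period
:class:`FertilitySchedule` / :class:`MortalitySchedule` / :class:`PopulationStructure`
objects, and a :class:`RateSeries` stringing them together over calendar time.
Rates are period rates per projection step (one step = one age class width,
5 years by default) and are treated as piecewise-constant within a step.

Validation is eager: a successfully constructed object is safe to project
with, and the projection code does not re-check.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ALPHA_DEFAULT",
    "AgeGrid",
    "MortalitySchedule",
    "FertilitySchedule",
    "PopulationStructure",
    "RatePeriod",
    "RateSeries",
    "RateValidationError",
    "build_survival_matrix",
    "build_fertility_matrix",
    "annual_to_step_rates",
    "read_rate_series",
    "write_rate_series",
    "validate_rate_table",
]

#: Default proportion of births that are female (sex ratio at birth 105 males
#: per 100 females), used when the data source does not supply one.
ALPHA_DEFAULT = 100.0 / 205.0

#: Canonical long-format columns for rate files.
CANONICAL_COLUMNS = ("location", "year", "age_lower", "sex", "variable", "value")

#: Recognised values of the ``variable`` column.
VARIABLES = ("asfr", "Lx", "population")


class RateValidationError(ValueError):
    """An input rate schedule or rate file violates a structural invariant."""


def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise RateValidationError(f"{name} must be a 1-d vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise RateValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class AgeGrid:
    """Equal-width age classes; the last class is open-ended.

    Parameters
    ----------
    n_classes:
        Number of age classes (ω). Must be ≥ 3.
    step_years:
        Width of each class in years; also the projection time step.
    lower_bounds:
        Lower bound of each class in years: 0, step, 2·step, …
    """

    n_classes: int
    step_years: int
    lower_bounds: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.n_classes < 3:
            raise RateValidationError("AgeGrid needs at least 3 age classes")
        if self.step_years <= 0:
            raise RateValidationError("step_years must be positive")
        lb = self.lower_bounds
        if lb is None:
            lb = tuple(int(self.step_years) * i for i in range(self.n_classes))
        else:
            lb = tuple(float(v) for v in lb)
            if len(lb) != self.n_classes:
                raise RateValidationError("lower_bounds length must equal n_classes")
            diffs = np.diff(lb)
            if not np.all(diffs > 0) or not np.allclose(diffs, self.step_years):
                raise RateValidationError(
                    "lower_bounds must be strictly increasing with constant "
                    f"spacing step_years={self.step_years}"
                )
        object.__setattr__(self, "lower_bounds", lb)

    @classmethod
    def default(cls) -> "AgeGrid":
        """The UNWPP-style grid: 21 five-year classes, 0–4 … 100+."""
        return cls(n_classes=21, step_years=5)

    @property
    def midpoints(self) -> np.ndarray:
        """Class midpoints in years (lower bound + step/2, incl. open class)."""
        return np.asarray(self.lower_bounds, dtype=float) + self.step_years / 2.0

    def class_index(self, age_years: float) -> int:
        """Age class containing ``age_years`` (the open class catches the rest)."""
        if age_years < 0:
            raise ValueError("age must be non-negative")
        return min(int(age_years // self.step_years), self.n_classes - 1)


@dataclass(frozen=True)
class MortalitySchedule:
    """Per-step survival probabilities p[x] from class x to x+1 for one sex.

    The open-ended last class has p = 0: no one survives out of the grid.
    """

    sex: str
    p: np.ndarray

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise RateValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        p = _as_float_vector(self.p, "survival p")
        if np.any(p < 0) or np.any(p > 1):
            raise RateValidationError("survival probabilities must lie in [0, 1]")
        if p[-1] != 0.0:
            raise RateValidationError("survival out of the open-ended class must be 0")
        object.__setattr__(self, "p", p)

    @property
    def n_classes(self) -> int:
        return len(self.p)

    def survivorship(self) -> np.ndarray:
        """s[x] = probability of surviving from class 0 to class x (s[0] = 1)."""
        return np.concatenate([[1.0], np.cumprod(self.p[:-1])])


@dataclass(frozen=True)
class FertilitySchedule:
    """Expected births (both sexes) per woman per projection step, by age class.

    ``frac_female`` (α) is the proportion of births that are female; the
    two-sex model uses it to allocate newborn kin between the sex blocks.
    The support of f must be a contiguous band of age classes.
    """

    f: np.ndarray
    frac_female: float = ALPHA_DEFAULT

    def __post_init__(self):
        f = _as_float_vector(self.f, "fertility f")
        if np.any(f < 0):
            raise RateValidationError("fertility rates must be non-negative")
        nz = np.flatnonzero(f)
        if nz.size and (nz[-1] - nz[0] + 1 != nz.size):
            raise RateValidationError("fertility support must be contiguous")
        if not (0.0 < self.frac_female < 1.0):
            raise RateValidationError("frac_female must lie strictly in (0, 1)")
        object.__setattr__(self, "f", f)

    @property
    def n_classes(self) -> int:
        return len(self.f)

    @property
    def tfr(self) -> float:
        """Total fertility rate: Σ f[x] (births per woman surviving the span)."""
        return float(self.f.sum())

    def mean_age(self, grid: AgeGrid) -> float:
        """Fertility-weighted mean age of childbearing (class midpoints)."""
        if self.tfr == 0:
            raise RateValidationError("mean age undefined for a zero schedule")
        return float(np.average(grid.midpoints, weights=self.f))


@dataclass(frozen=True)
class PopulationStructure:
    """Population counts by age class, per sex, at one point in time."""

    female: np.ndarray
    male: np.ndarray

    def __post_init__(self):
        f = _as_float_vector(self.female, "female population")
        m = _as_float_vector(self.male, "male population")
        if len(f) != len(m):
            raise RateValidationError("female and male population vectors must align")
        if np.any(f < 0) or np.any(m < 0):
            raise RateValidationError("population counts must be non-negative")
        if f.sum() + m.sum() <= 0:
            raise RateValidationError("population must not be all zero")
        object.__setattr__(self, "female", f)
        object.__setattr__(self, "male", m)

    @property
    def n_classes(self) -> int:
        return len(self.female)


@dataclass(frozen=True)
class RatePeriod:
    """One time-slice of a :class:`RateSeries`: a complete rate regime."""

    grid: AgeGrid
    time: float
    fertility: FertilitySchedule
    survival_female: MortalitySchedule
    survival_male: MortalitySchedule
    population: PopulationStructure
    fertility_male: FertilitySchedule | None = None

    def __post_init__(self):
        n = self.grid.n_classes
        parts = [
            ("fertility", self.fertility.n_classes),
            ("survival_female", self.survival_female.n_classes),
            ("survival_male", self.survival_male.n_classes),
            ("population", self.population.n_classes),
        ]
        if self.fertility_male is not None:
            parts.append(("fertility_male", self.fertility_male.n_classes))
        for name, k in parts:
            if k != n:
                raise RateValidationError(
                    f"{name} has {k} classes but the grid has {n}"
                )


@dataclass(frozen=True)
class RateSeries:
    """Time-indexed demographic rates for one location.

    ``times`` are calendar-year labels at ``grid.step_years`` spacing; the
    rates labelled ``t`` govern the projection interval [t, t + step).
    """

    grid: AgeGrid
    times: tuple
    fertility: tuple
    survival_female: tuple
    survival_male: tuple
    population: tuple
    location: str | None = None
    fertility_male: tuple | None = None

    def __post_init__(self):
        times = tuple(float(t) for t in self.times)
        if len(times) < 1:
            raise RateValidationError("RateSeries needs at least one time")
        diffs = np.diff(times)
        if len(times) > 1 and not np.allclose(diffs, self.grid.step_years):
            raise RateValidationError(
                "times spacing must equal grid.step_years "
                f"({self.grid.step_years}); got spacings {sorted(set(diffs))}"
            )
        for name in ("fertility", "survival_female", "survival_male", "population"):
            seq = tuple(getattr(self, name))
            if len(seq) != len(times):
                raise RateValidationError(
                    f"{name} has {len(seq)} entries for {len(times)} times"
                )
            object.__setattr__(self, name, seq)
        if self.fertility_male is not None:
            fm = tuple(self.fertility_male)
            if len(fm) != len(times):
                raise RateValidationError("fertility_male must align with times")
            object.__setattr__(self, "fertility_male", fm)
        object.__setattr__(self, "times", times)
        # every slice must validate against the grid
        for i in range(len(times)):
            self.period_at(i)

    @property
    def n_times(self) -> int:
        return len(self.times)

    def index_of(self, year: float) -> int:
        try:
            return self.times.index(float(year))
        except ValueError:
            raise KeyError(f"year {year} not in series times {self.times}") from None

    def period_at(self, i: int) -> RatePeriod:
        """Rate regime at time index ``i``."""
        return RatePeriod(
            grid=self.grid,
            time=self.times[i],
            fertility=self.fertility[i],
            survival_female=self.survival_female[i],
            survival_male=self.survival_male[i],
            population=self.population[i],
            fertility_male=None if self.fertility_male is None else self.fertility_male[i],
        )

    def period(self, year: float) -> RatePeriod:
        """Rate regime at calendar year label ``year``."""
        return self.period_at(self.index_of(year))


# ---------------------------------------------------------------------------
# Projection matrices
# ---------------------------------------------------------------------------

def build_survival_matrix(m: MortalitySchedule, grid: AgeGrid) -> np.ndarray:
    """Age-transition matrix U with survival probabilities on the subdiagonal.

    U[x+1, x] = p[x]; all other entries zero. Applied to an age vector it ages
    the population one step, killing everyone who leaves the open-ended class.
    """
    if m.n_classes != grid.n_classes:
        raise RateValidationError(
            f"mortality schedule has {m.n_classes} classes, grid has {grid.n_classes}"
        )
    n = grid.n_classes
    U = np.zeros((n, n))
    U[np.arange(1, n), np.arange(n - 1)] = m.p[:-1]
    return U


def build_fertility_matrix(
    fs: FertilitySchedule, grid: AgeGrid, sex_of_offspring: str = "both"
) -> np.ndarray:
    """Fertility matrix F with age-specific rates in the first row.

    F[0, x] is f[x] scaled by the requested offspring sex fraction: α for
    ``"female"``, 1−α for ``"male"``, 1 for ``"both"``. Newborns enter age
    class 0.
    """
    if fs.n_classes != grid.n_classes:
        raise RateValidationError(
            f"fertility schedule has {fs.n_classes} classes, grid has {grid.n_classes}"
        )
    scale = {
        "female": fs.frac_female,
        "male": 1.0 - fs.frac_female,
        "both": 1.0,
    }
    if sex_of_offspring not in scale:
        raise ValueError(f"sex_of_offspring must be one of {sorted(scale)}")
    n = grid.n_classes
    F = np.zeros((n, n))
    F[0, :] = fs.f * scale[sex_of_offspring]
    return F


def annual_to_step_rates(
    asfr_annual,
    survivorship_L,
    grid: AgeGrid,
    *,
    frac_female: float = ALPHA_DEFAULT,
    sex: str = "female",
) -> tuple[FertilitySchedule, MortalitySchedule]:
    """Convert annualised rates to per-step schedules.

    ``asfr_annual`` are annual age-specific fertility rates (births per woman
    per year); the per-step rate is ``asfr × step_years``. ``survivorship_L``
    is the life-table Lx column (person-years lived in each class, radix-free);
    the per-step survival probability is the period approximation
    p[x] = L[x+1] / L[x], clipped to [0, 1], with p = 0 out of the open class.
    """
    asfr = _as_float_vector(asfr_annual, "asfr_annual")
    L = _as_float_vector(survivorship_L, "survivorship_L")
    if len(asfr) != grid.n_classes or len(L) != grid.n_classes:
        raise RateValidationError("asfr and Lx must have one entry per age class")
    if np.any(L < 0):
        raise RateValidationError("Lx must be non-negative")
    bad = (L[:-1] == 0) & (L[1:] > 0)
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise RateValidationError(
            f"invalid life table: L[{idx}] = 0 but L[{idx + 1}] > 0"
        )
    f = asfr * grid.step_years
    p = np.zeros(grid.n_classes)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(L[:-1] > 0, L[1:] / np.where(L[:-1] > 0, L[:-1], 1.0), 0.0)
    p[:-1] = np.clip(ratio, 0.0, 1.0)
    return (
        FertilitySchedule(f=f, frac_female=frac_female),
        MortalitySchedule(sex=sex, p=p),
    )


# ---------------------------------------------------------------------------
# Long-format I/O
# ---------------------------------------------------------------------------

def _apply_format_config(df: pd.DataFrame, format_config: Mapping | None) -> pd.DataFrame:
    """Rename columns per an optional {canonical: actual} mapping."""
    if not format_config:
        return df
    columns = format_config.get("columns", format_config)
    rename = {actual: canonical for canonical, actual in columns.items()}
    return df.rename(columns=rename)


def validate_rate_table(df: pd.DataFrame) -> list[str]:
    """Return a list of human-readable violations in a long-format rate table.

    An empty list means the table is structurally valid. Checks: required
    columns; recognised variables; non-negative values; no duplicate records;
    constant age spacing; and, per location, a complete (year × variable × sex)
    block over all age classes for every year present.
    """
    issues: list[str] = []
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing required columns: {missing}"]

    bad_var = sorted(set(df["variable"]) - set(VARIABLES))
    if bad_var:
        issues.append(f"unknown variables {bad_var}; expected one of {list(VARIABLES)}")
    if (df["value"] < 0).any():
        n_neg = int((df["value"] < 0).sum())
        issues.append(f"{n_neg} negative values")
    key = ["location", "year", "age_lower", "sex", "variable"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].to_dict()
        issues.append(f"{int(dup.sum())} duplicate records, e.g. {first}")

    required = [("asfr", "female"), ("Lx", "female"), ("Lx", "male"),
                ("population", "female"), ("population", "male")]
    for loc, sub in df.groupby("location"):
        ages = np.sort(sub["age_lower"].unique())
        if len(ages) < 3:
            issues.append(f"{loc}: fewer than 3 age classes")
            continue
        spacing = np.diff(ages)
        if not np.all(spacing == spacing[0]):
            issues.append(f"{loc}: non-constant age spacing {sorted(set(spacing))}")
            continue
        years = np.sort(sub["year"].unique())
        have = {
            (y, v, s): grp
            for (y, v, s), grp in sub.groupby(["year", "variable", "sex"])
        }
        for y in years:
            for v, s in required:
                grp = have.get((y, v, s))
                if grp is None:
                    issues.append(f"{loc}: missing {v}/{s} block for year {int(y)}")
                elif len(grp) != len(ages) or set(grp["age_lower"]) != set(ages):
                    issues.append(
                        f"{loc}: incomplete {v}/{s} block for year {int(y)} "
                        f"({len(grp)}/{len(ages)} ages)"
                    )
    return issues


def read_rate_series(
    path, format_config: Mapping | None = None, *, frac_female: float = ALPHA_DEFAULT
) -> dict[str, RateSeries]:
    """Read a long-format delimited rate file into one RateSeries per location.

    The canonical schema has columns (location, year, age_lower, sex, variable,
    value) with variable ∈ {asfr, Lx, population}, on a 5-year (or other
    constant-width) age and period grid. ``format_config`` may carry a
    ``columns`` mapping adapting other column names (e.g. WPP-2022 exports) to
    the canonical schema. Missing blocks are an error, never interpolated.
    """
    df = pd.read_csv(path)
    df = _apply_format_config(df, format_config)
    issues = validate_rate_table(df)
    if issues:
        raise RateValidationError(
            f"invalid rate file {path}: " + "; ".join(issues[:10])
        )

    out: dict[str, RateSeries] = {}
    for loc, sub in df.groupby("location"):
        ages = np.sort(sub["age_lower"].unique())
        step = int(ages[1] - ages[0])
        grid = AgeGrid(n_classes=len(ages), step_years=step, lower_bounds=ages)
        years = np.sort(sub["year"].unique())
        piv = sub.pivot_table(
            index="age_lower", columns=["year", "variable", "sex"],
            values="value", aggfunc="first",
        ).reindex(ages)
        fert, surv_f, surv_m, pops = [], [], [], []
        for y in years:
            asfr = piv[(y, "asfr", "female")].to_numpy()
            Lf = piv[(y, "Lx", "female")].to_numpy()
            Lm = piv[(y, "Lx", "male")].to_numpy()
            fs, mf = annual_to_step_rates(
                asfr, Lf, grid, frac_female=frac_female, sex="female"
            )
            _, mm = annual_to_step_rates(
                asfr, Lm, grid, frac_female=frac_female, sex="male"
            )
            fert.append(fs)
            surv_f.append(mf)
            surv_m.append(mm)
            pops.append(PopulationStructure(
                female=piv[(y, "population", "female")].to_numpy(),
                male=piv[(y, "population", "male")].to_numpy(),
            ))
        out[str(loc)] = RateSeries(
            grid=grid, times=tuple(float(y) for y in years),
            fertility=tuple(fert), survival_female=tuple(surv_f),
            survival_male=tuple(surv_m), population=tuple(pops),
            location=str(loc),
        )
    return out


def write_rate_series(series: RateSeries | Iterable[RateSeries], path) -> None:
    """Write RateSeries back to the canonical long-format CSV.

    The inverse of :func:`read_rate_series` on the annualised scale: f is
    divided by step_years to recover the annual ASFR, and survival
    probabilities are expressed as a synthetic Lx column with radix L[0] = 1
    and L[x+1] = L[x]·p[x] (so a re-read recovers p bit-for-bit where p > 0).
    Values are written at full float precision.
    """
    if isinstance(series, RateSeries):
        series = [series]
    rows = []
    for s in series:
        loc = s.location or "location"
        ages = s.grid.lower_bounds
        for i, year in enumerate(s.times):
            per = s.period_at(i)
            asfr = per.fertility.f / s.grid.step_years
            for x, a in enumerate(ages):
                rows.append((loc, year, a, "female", "asfr", asfr[x]))
            for sex, sched in (("female", per.survival_female), ("male", per.survival_male)):
                L = np.concatenate([[1.0], np.cumprod(sched.p[:-1])])
                for x, a in enumerate(ages):
                    rows.append((loc, year, a, sex, "Lx", L[x]))
            for sex, w in (("female", per.population.female), ("male", per.population.male)):
                for x, a in enumerate(ages):
                    rows.append((loc, year, a, sex, "population", w[x]))
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    df.to_csv(path, index=False, float_format="%.17g")
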