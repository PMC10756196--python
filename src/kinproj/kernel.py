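"""Matrix kinship kernel: expected kin networks of a female Focal.

The model projects, for a female reference individual ("Focal") assumed alive
at every age, the expected number of each type of living relative, classified
by the relative's age class (and sex, in the two-sex variant). Kin of each
type form a small age-structured population that is projected with the same
machinery as the whole population: a survival matrix U (subdiagonal survival
probabilities) ages and kills existing kin, and a fertility matrix F (rates in
the first row) recruits new kin from the kin population that gives birth to
them — e.g. new granddaughters are born to Focal's daughters:

    b(x+1, t+1) = U_t · b(x, t) + F_t · a(x, t)

Fourteen kin types are tracked, keyed by one-letter codes following the
standard formal-kinship nomenclature:

    a  children                     d  parents
    b  grandchildren                g  grandparents
    c  great-grandchildren          h  great-grandparents
    m  older siblings               n  younger siblings
    p  niblings via older sibs      q  niblings via younger sibs
    r  aunts/uncles older than parent   s  aunts/uncles younger than parent
    t  cousins via older aunts/uncles   v  cousins via younger aunts/uncles

The ten reported kin categories merge the older/younger splits (siblings =
m+n, niblings = p+q, aunts/uncles = r+s, cousins = t+v).

Boundary conditions at Focal's birth are anchored in π, the age distribution
of mothers of newborns (fertility-weighted female age structure): Focal's
mother is a random draw from π, so e.g. her older siblings at birth are the
π-mixture of the children a(x) already borne by a mother aged x.

Two variants are provided. ``one_sex`` is the female-line model: a single
ω-vector per kin array, fertility applied as given. ``two_sex_androgynous``
stacks female and male blocks (length 2ω), survives them with sex-specific
schedules, and lets kin of both sexes reproduce at the androgynous rates
(male fertility set equal to female fertility unless a male schedule is
supplied), with births split between the sex blocks by the fraction female α.
Sibling-type kin are defined through the mother, so recruitment of younger
siblings (and of younger aunts/uncles) applies fertility to the female block
of the source array only — otherwise each birth would be counted once per
spouse. Boundary sums that run through *both* of Focal's parents (grand-
parents, great-grandparents, aunts/uncles, cousins) carry a factor 2 under
the sex-symmetric allocation: with androgynous fertility the kin arrays of a
male and a female of the same age coincide, so each parent contributes one
π-mixture of the relevant array.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .rates import (
    AgeGrid,
    FertilitySchedule,
    MortalitySchedule,
    PopulationStructure,
    RatePeriod,
    RateSeries,
    RateValidationError,
    build_fertility_matrix,
    build_survival_matrix,
)

__all__ = [
    "KIN_CODES",
    "KIN_CODE_NAMES",
    "KIN_CATEGORIES",
    "DEPENDENCY_ORDER",
    "VARIANTS",
    "KinArray",
    "KinNetwork",
    "MotherAgeDistribution",
    "mother_age_distribution",
    "stable_population_structure",
    "project_kin_step",
    "time_invariant_kinship",
    "time_variant_kinship",
    "make_androgynous",
]

KIN_CODES = ("a", "b", "c", "d", "g", "h", "m", "n", "p", "q", "r", "s", "t", "v")

KIN_CODE_NAMES = {
    "a": "children",
    "b": "grandchildren",
    "c": "great_grandchildren",
    "d": "parents",
    "g": "grandparents",
    "h": "great_grandparents",
    "m": "older_siblings",
    "n": "younger_siblings",
    "p": "niblings_older_sibs",
    "q": "niblings_younger_sibs",
    "r": "aunts_uncles_older",
    "s": "aunts_uncles_younger",
    "t": "cousins_older_side",
    "v": "cousins_younger_side",
}

#: The ten reported kin categories and the codes they merge.
KIN_CATEGORIES = {
    "children": ("a",),
    "grandchildren": ("b",),
    "great_grandchildren": ("c",),
    "parents": ("d",),
    "grandparents": ("g",),
    "great_grandparents": ("h",),
    "siblings": ("m", "n"),
    "niblings": ("p", "q"),
    "aunts_uncles": ("r", "s"),
    "cousins": ("t", "v"),
}

#: Evaluation order: each type only ever references earlier types (the
#: recruitment/boundary graph is acyclic).
DEPENDENCY_ORDER = ("a", "d", "b", "g", "m", "n", "c", "h", "p", "q", "r", "s", "t", "v")

VARIANTS = ("one_sex", "two_sex_androgynous")

#: Recruitment source per kin type. "focal" = Focal herself (indicator e_x);
#: a ":mother" suffix restricts fertility to the female block of the source
#: (births through mothers only, avoiding one-count-per-spouse duplication).
_RECRUIT = {
    "a": "focal",
    "b": "a",
    "c": "b",
    "d": None,
    "g": None,
    "h": None,
    "m": None,
    "n": "d:mother",
    "p": "m",
    "q": "n",
    "r": None,
    "s": "g:mother",
    "t": "r",
    "v": "s",
}

#: Boundary condition at Focal age 0: (source code, through_both_parents).
#: The init is factor · Σ_x π[x] · source(x); factor is 2 in the two-sex
#: variant when the sum runs through both parents, else 1. "pi" means the
#: parents' own age distribution; None means zero.
_INIT = {
    "a": None,
    "b": None,
    "c": None,
    "d": "pi",
    "g": ("d", True),
    "h": ("g", True),
    "m": ("a", False),
    "n": None,
    "p": ("b", False),
    "q": None,
    "r": ("m", True),
    "s": ("n", True),
    "t": ("p", True),
    "v": ("q", True),
}


class KinshipError(ValueError):
    """Invalid input to the kinship kernel."""


@dataclass(frozen=True)
class MotherAgeDistribution:
    """π: age-class distribution of mothers of offspring born at one time."""

    pi: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if np.any(pi < 0):
            raise KinshipError("π must be non-negative")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise KinshipError(f"π must sum to 1, got {pi.sum()!r}")
        object.__setattr__(self, "pi", pi)


def mother_age_distribution(
    fs: FertilitySchedule, w: PopulationStructure | np.ndarray
) -> MotherAgeDistribution:
    """Age distribution of mothers: π[x] ∝ f[x] · w_female[x].

    ``w`` is the female population structure at the relevant time (a
    :class:`PopulationStructure` or a bare female age vector). A zero total
    birth flow has no valid π and raises.
    """
    wf = w.female if isinstance(w, PopulationStructure) else np.asarray(w, dtype=float)
    if len(wf) != fs.n_classes:
        raise KinshipError("population vector does not match fertility schedule")
    births = fs.f * wf
    total = births.sum()
    if total <= 0:
        raise KinshipError("zero total births: mothers' age distribution undefined")
    return MotherAgeDistribution(pi=births / total)


def stable_population_structure(period: RatePeriod, variant: str = "two_sex_androgynous"):
    """Stable-equivalent population implied by one fixed rate regime.

    Returns ``(growth_rate, PopulationStructure)`` where growth_rate is the
    dominant eigenvalue λ of the female projection matrix per step, and the
    structure is the stable age-sex composition: w_sex[x] ∝ sex-fraction ·
    λ^{−x} · survivorship_sex(x), scaled to a total of 1. In the one-sex
    variant all mass is female and reproduction uses the full schedule.
    """
    _check_variant(variant)
    grid = period.grid
    alpha = period.fertility.frac_female
    female_frac = alpha if variant == "two_sex_androgynous" else 1.0
    A = build_survival_matrix(period.survival_female, grid)
    A[0, :] += period.fertility.f * female_frac
    eigvals, eigvecs = np.linalg.eig(A)
    k = int(np.argmax(eigvals.real))
    lam = float(eigvals[k].real)
    if lam <= 0:
        raise KinshipError("non-positive dominant eigenvalue: degenerate rates")
    n = grid.n_classes
    decay = lam ** (-np.arange(n, dtype=float))
    wf = female_frac * decay * period.survival_female.survivorship()
    if variant == "two_sex_androgynous":
        wm = (1.0 - alpha) * decay * period.survival_male.survivorship()
    else:
        wm = np.zeros(n)
    total = wf.sum() + wm.sum()
    return lam, PopulationStructure(female=wf / total, male=wm / total)


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise KinshipError(f"variant must be one of {VARIANTS}, got {variant!r}")


class _Ops:
    """Structure-exploiting survival/fertility operators for one rate regime.

    Equivalent to multiplying by blockdiag(U_f, U_m) and by the two-sex
    fertility matrix, but in O(ω) per vector instead of O(ω²).
    """

    def __init__(self, period: RatePeriod, variant: str):
        _check_variant(variant)
        self.variant = variant
        self.grid = period.grid
        self.omega = period.grid.n_classes
        self.alpha = period.fertility.frac_female
        self.p_f = period.survival_female.p
        self.p_m = period.survival_male.p
        f_f = period.fertility.f
        if variant == "two_sex_androgynous":
            f_m = (period.fertility_male.f if period.fertility_male is not None else f_f)
            self.L = 2 * self.omega
            self.f_row = np.concatenate([f_f, f_m])
            self.birth_rows = ((0, self.alpha), (self.omega, 1.0 - self.alpha))
        else:
            self.L = self.omega
            self.f_row = f_f.copy()
            self.birth_rows = ((0, 1.0),)
        self.f_focal = f_f  # Focal is female; her own births use female rates

    def survive(self, M: np.ndarray) -> np.ndarray:
        """Apply blockdiag(U_f, U_m) along the last axis of M (shape (..., L))."""
        out = np.zeros_like(M)
        w = self.omega
        out[..., 1:w] = M[..., : w - 1] * self.p_f[:-1]
        if self.L > w:
            out[..., w + 1 :] = M[..., w : -1] * self.p_m[:-1]
        return out

    def births_into(self, out: np.ndarray, src: np.ndarray) -> None:
        """Add F·src to ``out`` in place (both shaped (..., L))."""
        B = src @ self.f_row
        for row, coef in self.birth_rows:
            out[..., row] += coef * B

    def mother_block(self, M: np.ndarray) -> np.ndarray:
        """Zero the male block: births through female kin only."""
        if self.L == self.omega:
            return M
        out = M.copy()
        out[..., self.omega :] = 0.0
        return out


@dataclass(frozen=True)
class KinArray:
    """Expected counts of one kin type at one (Focal age, time) point.

    ``counts`` has length ω (one-sex) or 2ω (two-sex, female block first),
    indexed by the kin's age class.
    """

    kin_type: str
    focal_age: int
    time: float
    counts: np.ndarray
    grid: AgeGrid
    two_sex: bool

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if np.any(~np.isfinite(c)) or np.any(c < -1e-12):
            raise KinshipError("kin counts must be finite and non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def female(self) -> np.ndarray:
        return self.counts[: self.grid.n_classes]

    @property
    def male(self) -> np.ndarray:
        if not self.two_sex:
            return np.zeros(self.grid.n_classes)
        return self.counts[self.grid.n_classes :]

    @property
    def by_age(self) -> np.ndarray:
        """Counts by kin age class, sexes combined."""
        return self.female + self.male


class KinNetwork:
    """The full kin map {(kin type, Focal age, time) → expected counts}.

    Internally each kin type is a dense array of shape
    (n_times, n_focal_ages, L); the network is complete over its declared
    index set by construction.
    """

    def __init__(self, grid: AgeGrid, variant: str, times, arrays: Mapping[str, np.ndarray]):
        _check_variant(variant)
        self.grid = grid
        self.variant = variant
        self.times = tuple(float(t) for t in times)
        missing = set(KIN_CODES) - set(arrays)
        if missing:
            raise KinshipError(f"kin network incomplete: missing types {sorted(missing)}")
        L = 2 * grid.n_classes if variant == "two_sex_androgynous" else grid.n_classes
        shape = (len(self.times), grid.n_classes, L)
        for code in KIN_CODES:
            if arrays[code].shape != shape:
                raise KinshipError(
                    f"kin array {code!r} has shape {arrays[code].shape}, expected {shape}"
                )
        self.arrays = {code: np.asarray(arrays[code], dtype=float) for code in KIN_CODES}

    @property
    def two_sex(self) -> bool:
        return self.variant == "two_sex_androgynous"

    def _time_index(self, time) -> int:
        if time is None:
            if len(self.times) != 1:
                raise KinshipError("time must be given for a multi-period network")
            return 0
        try:
            return self.times.index(float(time))
        except ValueError:
            raise KeyError(f"time {time} not in network times") from None

    def counts(self, kin_type: str, focal_age: int, time=None) -> np.ndarray:
        if kin_type not in KIN_CODES:
            raise KeyError(f"unknown kin type {kin_type!r}")
        return self.arrays[kin_type][self._time_index(time), focal_age]

    def kin(self, kin_type: str, focal_age: int, time=None) -> KinArray:
        ti = self._time_index(time)
        return KinArray(
            kin_type=kin_type,
            focal_age=focal_age,
            time=self.times[ti],
            counts=self.arrays[kin_type][ti, focal_age].copy(),
            grid=self.grid,
            two_sex=self.two_sex,
        )

    def total(self, kin_type: str, focal_age: int, time=None) -> float:
        return float(self.counts(kin_type, focal_age, time).sum())

    def category_counts(self, category: str, focal_age: int, time=None) -> np.ndarray:
        """Summed count vector over the codes of one reported category."""
        codes = KIN_CATEGORIES[category]
        return sum(self.counts(c, focal_age, time) for c in codes)

    def category_total(self, category: str, focal_age: int, time=None) -> float:
        return float(self.category_counts(category, focal_age, time).sum())


def project_kin_step(
    kin: KinArray, source: KinArray | None, U_t: np.ndarray, F_t: np.ndarray
) -> KinArray:
    """One projection step: counts' = U_t·counts + F_t·source_counts.

    Existing kin survive and age through U_t; new kin are recruited from the
    source kin population through F_t (omitted for kin types with no
    recruitment). Focal's age and the time label each advance one step.
    """
    L = len(kin.counts)
    if U_t.shape != (L, L) or F_t.shape != (L, L):
        raise KinshipError(
            f"operator shapes {U_t.shape}/{F_t.shape} do not match kin vector length {L}"
        )
    new = U_t @ kin.counts
    if source is not None:
        if len(source.counts) != L:
            raise KinshipError("source vector length does not match kin vector")
        new = new + F_t @ source.counts
    return KinArray(
        kin_type=kin.kin_type,
        focal_age=kin.focal_age + 1,
        time=kin.time + kin.grid.step_years,
        counts=new,
        grid=kin.grid,
        two_sex=kin.two_sex,
    )


def _boundary(
    code: str,
    ops: _Ops,
    pi: np.ndarray,
    arrays_now: Mapping[str, np.ndarray],
) -> np.ndarray:
    """Kin counts at Focal age 0 for one type, from same-time source arrays.

    ``arrays_now`` maps codes to (n_focal_ages, L) arrays at the boundary's
    own time. ``pi`` is the mothers'-age distribution at that time.
    """
    spec = _INIT[code]
    L = ops.L
    if spec is None:
        return np.zeros(L)
    if spec == "pi":
        init = np.zeros(L)
        init[: ops.omega] = pi
        if ops.L > ops.omega:
            # sex-symmetric allocation: the father's age distribution is π too
            init[ops.omega :] = pi
        return init
    src_code, through_both = spec
    factor = 2.0 if (through_both and ops.L > ops.omega) else 1.0
    return factor * (pi @ arrays_now[src_code])


def time_invariant_kinship(
    period: RatePeriod,
    variant: str = "two_sex_androgynous",
    pi: MotherAgeDistribution | None = None,
) -> KinNetwork:
    """Kin network under one fixed rate regime operating indefinitely.

    This is the boundary model: the kin structure a population would exhibit
    had the given period's rates always applied. π defaults to the fertility-
    weighted *stable-equivalent* female age structure implied by the rates
    themselves (pass ``pi`` to override, e.g. with an observed structure).
    """
    _check_variant(variant)
    ops = _Ops(period, variant)
    if pi is None:
        _, w = stable_population_structure(period, variant)
        pi = mother_age_distribution(period.fertility, w)
    pvec = pi.pi
    n = ops.omega
    arrays: dict[str, np.ndarray] = {}
    for code in DEPENDENCY_ORDER:
        A = np.zeros((n, ops.L))
        A[0] = _boundary(code, ops, pvec, arrays)
        src = _RECRUIT[code]
        for x in range(n - 1):
            A[x + 1] = ops.survive(A[x])
            if src == "focal":
                # F·e_x: Focal (female, alive by conditioning) gives birth
                B = ops.f_focal[x]
                for row, coef in ops.birth_rows:
                    A[x + 1, row] += coef * B
            elif src is not None:
                src_code, _, restrict = src.partition(":")
                v = arrays[src_code][x]
                if restrict == "mother":
                    v = ops.mother_block(v)
                ops.births_into(A[x + 1], v)
        arrays[code] = A
    nets = {c: arrays[c][None, :, :] for c in KIN_CODES}
    return KinNetwork(period.grid, variant, (period.time,), nets)


def time_variant_kinship(
    series: RateSeries,
    initial: KinNetwork | None = None,
    variant: str = "two_sex_androgynous",
) -> KinNetwork:
    """Kin network under rates that change every period.

    The first period's kin structure is the ``initial`` network (by default
    the time-invariant model run on the first time-slice). Each kin array is
    then marched forward along cohort lines, K(x+1, t+1) = U_t·K(x, t) +
    F_t·source(x, t), and the Focal-age-0 boundary at each new period is
    rebuilt from that period's own arrays, with π taken from the *observed*
    population structure of the series at that period.
    """
    _check_variant(variant)
    grid = series.grid
    n = grid.n_classes
    nt = series.n_times
    if initial is None:
        initial = time_invariant_kinship(series.period_at(0), variant)
    if initial.grid != grid:
        raise KinshipError("initial network grid does not match the series grid")
    if initial.variant != variant:
        raise KinshipError("initial network variant does not match")
    if len(initial.times) != 1 or initial.times[0] != series.times[0]:
        raise KinshipError(
            f"initial network must be at the series' first time {series.times[0]}"
        )

    L = 2 * n if variant == "two_sex_androgynous" else n
    K = {code: np.zeros((nt, n, L)) for code in KIN_CODES}
    for code in KIN_CODES:
        K[code][0] = initial.arrays[code][0]

    for ti in range(nt - 1):
        ops = _Ops(series.period_at(ti), variant)
        per_next = series.period_at(ti + 1)
        pi_next = mother_age_distribution(per_next.fertility, per_next.population).pi
        now: dict[str, np.ndarray] = {}
        for code in DEPENDENCY_ORDER:
            cur = K[code][ti]
            nxt = K[code][ti + 1]
            nxt[1:] = ops.survive(cur[:-1])
            src = _RECRUIT[code]
            if src == "focal":
                for row, coef in ops.birth_rows:
                    nxt[1:, row] += coef * ops.f_focal[:-1]
            elif src is not None:
                src_code, _, restrict = src.partition(":")
                v = K[src_code][ti, :-1]
                if restrict == "mother":
                    v = ops.mother_block(v)
                ops.births_into(nxt[1:], v)
            ops_next = _Ops(per_next, variant)
            nxt[0] = _boundary(code, ops_next, pi_next, now)
            now[code] = nxt
    return KinNetwork(grid, variant, series.times, K)


def make_androgynous(series: RateSeries) -> RateSeries:
    """Mark a series as androgynous: male fertility set equal to female.

    The two-sex kernel already applies the female schedule to male kin when no
    male schedule is present; this makes the approximation explicit by
    attaching ``fertility_male`` equal to the female schedules, and overrides
    any sex-specific male schedule the series carried. Survival stays
    sex-specific.
    """
    import dataclasses

    return dataclasses.replace(series, fertility_male=series.fertility)
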