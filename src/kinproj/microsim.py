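"""Genealogical microsimulation: brute-force ground truth for the kernel.

Instead of projecting expectations, this module simulates an explicit
population of individuals under the same per-step rates the kernel consumes —
Poisson births by the mother's age class, Bernoulli survival by age and sex,
fathers sampled from living males in proportion to the androgynous fertility
at their age — and then walks the resulting pedigree to tally living kin of
sampled Focal individuals by type and age. Kernel expectations should agree
with the Monte Carlo tallies within sampling error; the simulation knows
nothing about the kernel's recursions.

Timing convention matches the kernel exactly: individuals alive at step t
give birth during [t, t+1); newborns enter age class 0 at t+1 and are not
exposed to mortality within their birth interval; survival from t to t+1 uses
the survival probability of the age class occupied at t. One step equals one
age class width. Kin classification mirrors the kernel's conventions:
siblings are other children of the mother (split older/younger by birth
step; same-step twins count as younger siblings, which is how the kernel's
recruitment accounts for them), aunts/uncles are siblings of the parents,
cousins their children, and in the one-sex variant all links run through
mothers only.

One subtlety is inherited from the kernel's boundary conditions and must be
mirrored here for the comparison to be exact. The kernel anchors each kin
type's boundary in π, the age distribution of mothers *currently giving
birth*: a newborn Focal's mother is assigned her pre-registration age class
with no mortality exposure yet, and every further π-composition up the
pedigree (parent's parents, parent's siblings, …) repeats that assignment
one generation higher. Relative to the simulation's registration clock
(newborns recorded at the end of their birth interval), each π-composition
therefore places the counted kin one step earlier. The tally reproduces this
exactly by evaluating each kin type at ``t − offset``, where the offset is
the type's π-depth: 0 for descendants (a, b, c), 1 for parents, siblings and
niblings (d, m, n, p, q), 2 for grandparents, aunts/uncles and cousins
(g, r, s, t, v), and 3 for great-grandparents (h).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernel import KIN_CODES, stable_population_structure
from .rates import RatePeriod, RateSeries

__all__ = [
    "Individual",
    "Genealogy",
    "KinTally",
    "simulate_genealogy",
    "tally_kin",
]

_ALIVE = np.iinfo(np.int64).max  # death_step sentinel: never died

#: π-depth of each kin type: evaluation-step offset relative to the Focal's
#: registration clock (see module docstring).
PI_DEPTH = {
    "a": 0, "b": 0, "c": 0,
    "d": 1, "m": 1, "n": 1, "p": 1, "q": 1,
    "g": 2, "r": 2, "s": 2, "t": 2, "v": 2,
    "h": 3,
}


@dataclass(frozen=True)
class Individual:
    """One simulated person (row view of a :class:`Genealogy`)."""

    id: int
    sex: str
    birth_step: int
    death_step: int | None
    mother_id: int | None
    father_id: int | None


class Genealogy:
    """Columnar pedigree: sex, birth/death steps, parent links.

    ``death_step`` is the first step at which the individual is no longer
    alive; an individual is alive at step s iff birth_step ≤ s < death_step.
    Parent ids always precede child ids. Founders have parent id −1.
    """

    def __init__(self, sex, birth_step, death_step, mother, father, *,
                 grid, variant, n_steps, burn_in_steps=0, extinct=False):
        self.sex = np.asarray(sex, dtype=np.int8)            # 0 female, 1 male
        self.birth_step = np.asarray(birth_step, dtype=np.int64)
        self.death_step = np.asarray(death_step, dtype=np.int64)
        self.mother = np.asarray(mother, dtype=np.int64)
        self.father = np.asarray(father, dtype=np.int64)
        self.grid = grid
        self.variant = variant
        self.n_steps = int(n_steps)
        self.burn_in_steps = int(burn_in_steps)
        self.extinct = bool(extinct)
        n = len(self.sex)
        if not all(len(a) == n for a in (self.birth_step, self.death_step,
                                         self.mother, self.father)):
            raise ValueError("genealogy columns must have equal length")
        ids = np.arange(n)
        for parent in (self.mother, self.father):
            has = parent >= 0
            if np.any(parent[has] >= ids[has]):
                raise ValueError("parent ids must precede child ids (acyclic)")
        if np.any(self.death_step < self.birth_step):
            raise ValueError("death_step must be ≥ birth_step")
        self._children_by_parent = None

    def __len__(self) -> int:
        return len(self.sex)

    def individual(self, i: int) -> Individual:
        d = int(self.death_step[i])
        return Individual(
            id=int(i),
            sex="female" if self.sex[i] == 0 else "male",
            birth_step=int(self.birth_step[i]),
            death_step=None if d == _ALIVE else d,
            mother_id=int(self.mother[i]) if self.mother[i] >= 0 else None,
            father_id=int(self.father[i]) if self.father[i] >= 0 else None,
        )

    def alive_at(self, step: int) -> np.ndarray:
        return (self.birth_step <= step) & (step < self.death_step)

    def age_class_at(self, ids, step: int) -> np.ndarray:
        age = step - self.birth_step[ids]
        return np.minimum(age, self.grid.n_classes - 1)

    def children_of(self, i: int) -> list[int]:
        """Children through either parent link (cached index)."""
        if self._children_by_parent is None:
            index: dict[int, list[int]] = {}
            for child in range(len(self)):
                for par in (int(self.mother[child]), int(self.father[child])):
                    if par >= 0:
                        index.setdefault(par, []).append(child)
            self._children_by_parent = index
        return self._children_by_parent.get(int(i), [])

    def export_edge_list(self, path) -> None:
        """Delimited (id, sex, birth, death, mother_id, father_id) for debugging."""
        import pandas as pd

        death = np.where(self.death_step == _ALIVE, -1, self.death_step)
        pd.DataFrame({
            "id": np.arange(len(self)),
            "sex": np.where(self.sex == 0, "female", "male"),
            "birth": self.birth_step,
            "death": death,
            "mother_id": self.mother,
            "father_id": self.father,
        }).to_csv(path, index=False)

    @classmethod
    def from_edge_list(cls, path, *, grid, variant="two_sex_androgynous", n_steps=None):
        import pandas as pd

        df = pd.read_csv(path)
        death = np.where(df["death"].to_numpy() < 0, _ALIVE, df["death"].to_numpy())
        steps = n_steps if n_steps is not None else int(df["birth"].max()) + 1
        return cls(
            sex=(df["sex"] == "male").astype(np.int8).to_numpy(),
            birth_step=df["birth"].to_numpy(),
            death_step=death,
            mother=df["mother_id"].to_numpy(),
            father=df["father_id"].to_numpy(),
            grid=grid, variant=variant, n_steps=steps,
        )


class _Columns:
    """Growable columnar store for the simulation."""

    def __init__(self, capacity: int):
        self.n = 0
        self.sex = np.empty(capacity, dtype=np.int8)
        self.birth = np.empty(capacity, dtype=np.int64)
        self.death = np.empty(capacity, dtype=np.int64)
        self.mother = np.empty(capacity, dtype=np.int64)
        self.father = np.empty(capacity, dtype=np.int64)

    def _grow(self, need: int) -> None:
        cap = len(self.sex)
        if self.n + need <= cap:
            return
        new_cap = max(2 * cap, self.n + need)
        for name in ("sex", "birth", "death", "mother", "father"):
            arr = getattr(self, name)
            grown = np.empty(new_cap, dtype=arr.dtype)
            grown[: self.n] = arr[: self.n]
            setattr(self, name, grown)

    def append(self, sex, birth, death, mother, father) -> np.ndarray:
        k = len(sex)
        self._grow(k)
        sl = slice(self.n, self.n + k)
        self.sex[sl] = sex
        self.birth[sl] = birth
        self.death[sl] = death
        self.mother[sl] = mother
        self.father[sl] = father
        ids = np.arange(self.n, self.n + k)
        self.n += k
        return ids


def simulate_genealogy(
    rates: RatePeriod | RateSeries,
    n_founders: int = 500,
    burn_in_steps: int = 30,
    horizon_steps: int = 15,
    seed: int | None = None,
    variant: str = "two_sex_androgynous",
    births: str = "poisson",
) -> Genealogy:
    """Simulate an explicit genealogy under the given rates.

    ``rates`` may be a single :class:`RatePeriod` (constant regime) or a
    :class:`RateSeries`, whose slices are applied in order over the horizon
    after a burn-in under the first slice. Founders are drawn from the stable
    age distribution of the first regime. ``births="deterministic"`` replaces
    Poisson draws with the rounded expectation (for exact small checks).
    Extinction before the horizon flags the genealogy and returns it partial.
    """
    if variant not in ("one_sex", "two_sex_androgynous"):
        raise ValueError(f"unknown variant {variant!r}")
    if births not in ("poisson", "deterministic"):
        raise ValueError("births must be 'poisson' or 'deterministic'")
    series = rates if isinstance(rates, RateSeries) else None
    first = series.period_at(0) if series is not None else rates
    grid = first.grid
    omega = grid.n_classes
    total_steps = burn_in_steps + horizon_steps
    rng = np.random.default_rng(seed)
    two_sex = variant == "two_sex_androgynous"

    def period_for(step: int) -> RatePeriod:
        if series is None:
            return first
        i = min(max(step - burn_in_steps, 0), series.n_times - 1)
        return series.period_at(i)

    # founders: stable age distribution of the first regime (survivorship
    # shape when no stable structure exists, e.g. zero fertility)
    try:
        _, stable = stable_population_structure(first, variant)
        weights = stable.female + stable.male
    except Exception:
        weights = first.survival_female.survivorship()
    founder_age = rng.choice(omega, size=n_founders, p=weights / weights.sum())
    if two_sex:
        frac_m = stable.male.sum() / weights.sum()
        founder_sex = (rng.random(n_founders) < frac_m).astype(np.int8)
    else:
        founder_sex = np.zeros(n_founders, dtype=np.int8)

    cols = _Columns(capacity=max(4 * n_founders, 1024))
    cols.append(
        sex=founder_sex,
        birth=-founder_age.astype(np.int64),
        death=np.full(n_founders, _ALIVE),
        mother=np.full(n_founders, -1),
        father=np.full(n_founders, -1),
    )
    alive = np.arange(n_founders)
    extinct = False

    for t in range(total_steps):
        per = period_for(t)
        f = per.fertility.f
        alpha = per.fertility.frac_female
        f_male = per.fertility_male.f if per.fertility_male is not None else f
        age = np.minimum(t - cols.birth[alive], omega - 1)

        # births during [t, t+1): mothers are living females
        females = alive[cols.sex[alive] == 0]
        fem_age = np.minimum(t - cols.birth[females], omega - 1)
        lam = f[fem_age]
        if births == "poisson":
            n_off = rng.poisson(lam)
        else:
            n_off = np.round(lam).astype(np.int64)
        mothers = np.repeat(females, n_off)
        k = len(mothers)
        if k:
            if two_sex:
                males = alive[cols.sex[alive] == 1]
                male_w = f_male[np.minimum(t - cols.birth[males], omega - 1)]
                wsum = male_w.sum()
                if len(males) and wsum > 0:
                    fathers = rng.choice(males, size=k, p=male_w / wsum)
                else:
                    fathers = np.full(k, -1)
                child_sex = (rng.random(k) >= alpha).astype(np.int8)
            else:
                fathers = np.full(k, -1)
                child_sex = np.zeros(k, dtype=np.int8)
            newborn = cols.append(
                sex=child_sex,
                birth=np.full(k, t + 1),
                death=np.full(k, _ALIVE),
                mother=mothers,
                father=fathers,
            )
        else:
            newborn = np.empty(0, dtype=np.int64)

        # survival from t to t+1 by age class and sex
        p_f = per.survival_female.p
        p_m = per.survival_male.p
        p = np.where(cols.sex[alive] == 0, p_f[age], p_m[age])
        survives = rng.random(len(alive)) < p
        cols.death[alive[~survives]] = t + 1
        alive = np.concatenate([alive[survives], newborn])
        if len(alive) == 0:
            extinct = True
            break

    return Genealogy(
        sex=cols.sex[: cols.n].copy(),
        birth_step=cols.birth[: cols.n].copy(),
        death_step=cols.death[: cols.n].copy(),
        mother=cols.mother[: cols.n].copy(),
        father=cols.father[: cols.n].copy(),
        grid=grid, variant=variant, n_steps=total_steps,
        burn_in_steps=burn_in_steps, extinct=extinct,
    )


# ---------------------------------------------------------------------------
# Kin tallies
# ---------------------------------------------------------------------------

def _kin_ids(g: Genealogy, focal: int) -> dict[str, set[int]]:
    """Pedigree walk: ids of each kin type of one focal (alive or dead)."""
    two_sex = g.variant == "two_sex_androgynous"
    fb = int(g.birth_step[focal])

    def parents_of(i: int) -> list[int]:
        out = []
        if g.mother[i] >= 0:
            out.append(int(g.mother[i]))
        if two_sex and g.father[i] >= 0:
            out.append(int(g.father[i]))
        return out

    def own_children(i: int) -> list[int]:
        # one-sex: mother links only
        if two_sex:
            return g.children_of(i)
        return [c for c in g.children_of(i) if g.mother[c] == i]

    kin: dict[str, set[int]] = {c: set() for c in KIN_CODES}
    kin["a"] = set(own_children(focal))
    for c in kin["a"]:
        kin["b"].update(own_children(c))
    for c in kin["b"]:
        kin["c"].update(own_children(c))

    pars = parents_of(focal)
    kin["d"] = set(pars)
    for p_ in pars:
        kin["g"].update(parents_of(p_))
    for gp in kin["g"]:
        kin["h"].update(parents_of(gp))

    mother = int(g.mother[focal]) if g.mother[focal] >= 0 else None
    if mother is not None:
        sibs = [c for c in g.children_of(mother) if g.mother[c] == mother and c != focal]
        for s_ in sibs:
            sb = int(g.birth_step[s_])
            if sb < fb:
                kin["m"].add(s_)
            else:  # same-interval twins count as younger siblings
                kin["n"].add(s_)
    for s_ in kin["m"]:
        kin["p"].update(own_children(s_))
    for s_ in kin["n"]:
        kin["q"].update(own_children(s_))

    # aunts/uncles: siblings of each parent (through that parent's mother)
    for par in pars:
        gm = int(g.mother[par]) if g.mother[par] >= 0 else None
        if gm is None:
            continue
        pb = int(g.birth_step[par])
        for au in g.children_of(gm):
            if g.mother[au] != gm or au == par:
                continue
            ab = int(g.birth_step[au])
            if ab < pb:
                kin["r"].add(au)
            else:  # same-interval ties go with the younger split
                kin["s"].add(au)
    for au in kin["r"]:
        kin["t"].update(own_children(au))
    for au in kin["s"]:
        kin["v"].update(own_children(au))
    return kin


@dataclass
class KinTally:
    """Empirical kin tallies across sampled Focal individuals.

    ``per_focal_totals`` is an (n_focals × 14) matrix of living-kin counts in
    :data:`KIN_CODES` order; ``age_sex_counts`` maps each code to the mean
    count by (kin age class, sex) with sexes stacked female-then-male.
    """

    focal_age: int
    time: int
    n_focals: int
    per_focal_totals: np.ndarray
    age_sex_counts: dict = field(repr=False, default=None)

    def mean(self, code: str) -> float:
        return float(self.per_focal_totals[:, KIN_CODES.index(code)].mean())

    def se(self, code: str) -> float:
        col = self.per_focal_totals[:, KIN_CODES.index(code)]
        return float(col.std(ddof=1) / np.sqrt(len(col))) if len(col) > 1 else 0.0

    def category_mean(self, codes) -> float:
        idx = [KIN_CODES.index(c) for c in codes]
        return float(self.per_focal_totals[:, idx].sum(axis=1).mean())

    def category_se(self, codes) -> float:
        idx = [KIN_CODES.index(c) for c in codes]
        tot = self.per_focal_totals[:, idx].sum(axis=1)
        return float(tot.std(ddof=1) / np.sqrt(len(tot))) if len(tot) > 1 else 0.0

    def mean_by_age(self, code: str) -> np.ndarray:
        """Mean living-kin count by kin age class, sexes combined."""
        m = self.age_sex_counts[code]
        half = m.shape[0] // 2
        return m[:half] + m[half:]


def tally_kin(
    g: Genealogy,
    focal_age: int,
    time: int | None = None,
    *,
    focal_sex: str = "female",
    max_focals: int | None = None,
    min_birth_step: int | None = None,
    seed: int | None = None,
) -> KinTally:
    """Tally living kin of sampled Focals by type and age class.

    Focals are individuals of ``focal_sex`` alive at ``time`` (default: the
    final simulated step) in age class ``focal_age``, born no earlier than
    ``min_birth_step`` (default: after the burn-in, so pedigrees are deep
    enough that founder censoring does not bias ancestor and lateral counts).
    Kin must be alive at ``time`` to be counted. Raises if no Focal is
    eligible.
    """
    t = g.n_steps if time is None else int(time)
    min_birth = g.burn_in_steps if min_birth_step is None else int(min_birth_step)
    want_sex = 0 if focal_sex == "female" else 1
    alive = g.alive_at(t)
    ids = np.flatnonzero(
        alive
        & (g.sex == want_sex)
        & (np.minimum(t - g.birth_step, g.grid.n_classes - 1) == focal_age)
        & (g.birth_step >= min_birth)
    )
    if len(ids) == 0:
        raise ValueError(
            f"no eligible Focal (sex={focal_sex}, age class {focal_age}, "
            f"step {t}, born ≥ {min_birth})"
        )
    if max_focals is not None and len(ids) > max_focals:
        ids = np.random.default_rng(seed).choice(ids, size=max_focals, replace=False)
        ids.sort()

    omega = g.grid.n_classes
    totals = np.zeros((len(ids), len(KIN_CODES)))
    age_sex = {c: np.zeros(2 * omega) for c in KIN_CODES}
    for row, focal in enumerate(ids):
        kin = _kin_ids(g, int(focal))
        for j, code in enumerate(KIN_CODES):
            tc = t - PI_DEPTH[code]  # kernel clock for this kin type
            members = [i for i in kin[code]
                       if g.birth_step[i] <= tc < g.death_step[i]]
            totals[row, j] = len(members)
            if members:
                mem = np.asarray(members)
                age = np.minimum(tc - g.birth_step[mem], omega - 1)
                np.add.at(age_sex[code], age + omega * g.sex[mem], 1.0)
    for c in KIN_CODES:
        age_sex[c] /= len(ids)
    return KinTally(
        focal_age=int(focal_age), time=t, n_focals=len(ids),
        per_focal_totals=totals, age_sex_counts=age_sex,
    )
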