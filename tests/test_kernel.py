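"""Kinship kernel: boundary conditions, recursions, variants, invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kinproj as kp
from kinproj.kernel import (
    KIN_CODES,
    KinshipError,
    mother_age_distribution,
    stable_population_structure,
)

from conftest import make_period


class TestMotherAgeDistribution:
    def test_single_fertile_class(self):
        fs = kp.FertilitySchedule(f=np.array([0, 1.0, 0]))
        pi = mother_age_distribution(fs, np.array([5.0, 3.0, 2.0])).pi
        assert np.array_equal(pi, [0, 1, 0])

    def test_uniform_weights(self):
        fs = kp.FertilitySchedule(f=np.array([0, 1.0, 1.0]))
        pi = mother_age_distribution(fs, np.array([1.0, 1.0, 1.0])).pi
        assert np.allclose(pi, [0, 0.5, 0.5])

    def test_hand_normalization(self):
        fs = kp.FertilitySchedule(f=np.array([0, 0.2, 0.1]))
        pi = mother_age_distribution(fs, np.array([10.0, 5.0, 10.0])).pi
        assert np.allclose(pi, [0, 0.5, 0.5])

    def test_zero_births_is_error_not_nan(self):
        fs = kp.FertilitySchedule(f=np.array([0, 1.0, 0]))
        with pytest.raises(KinshipError, match="zero total births"):
            mother_age_distribution(fs, np.array([5.0, 0.0, 2.0]))

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.01, 2.0), min_size=3, max_size=8),
           st.lists(st.floats(0.1, 10.0), min_size=8, max_size=8))
    def test_pi_normalized(self, f, w):
        f = np.array(f + [0.0] * (8 - len(f)))
        pi = mother_age_distribution(kp.FertilitySchedule(f=f), np.array(w)).pi
        assert abs(pi.sum() - 1.0) <= 1e-12
        assert (pi >= 0).all()


class TestProjectKinStep:
    def test_hand_recruitment(self):
        grid = kp.AgeGrid(n_classes=3, step_years=5)
        # embed the 2-class hand example in the minimal 3-class grid
        U = np.zeros((3, 3))
        U[1, 0] = 0.5
        F = np.zeros((3, 3))
        F[0, 1] = 1.0
        kin = kp.KinArray(kin_type="a", focal_age=0, time=0.0,
                          counts=np.array([0.0, 0.0, 0.0]), grid=grid, two_sex=False)
        src = kp.KinArray(kin_type="d", focal_age=0, time=0.0,
                          counts=np.array([0.0, 1.0, 0.0]), grid=grid, two_sex=False)
        out = kp.project_kin_step(kin, src, U, F)
        assert np.allclose(out.counts, [1.0, 0.0, 0.0])
        assert out.focal_age == 1 and out.time == 5.0

    def test_zero_in_zero_out(self):
        grid = kp.AgeGrid(n_classes=3, step_years=5)
        z = kp.KinArray(kin_type="a", focal_age=0, time=0.0,
                        counts=np.zeros(3), grid=grid, two_sex=False)
        out = kp.project_kin_step(z, z, np.eye(3), np.zeros((3, 3)))
        assert not out.counts.any()

    def test_pure_aging_conserves_mass(self):
        grid = kp.AgeGrid(n_classes=3, step_years=5)
        U = np.zeros((3, 3))
        U[1, 0] = U[2, 1] = 1.0
        kin = kp.KinArray(kin_type="a", focal_age=0, time=0.0,
                          counts=np.array([2.0, 0.0, 0.0]), grid=grid, two_sex=False)
        out = kp.project_kin_step(kin, None, U, np.zeros((3, 3)))
        assert np.allclose(out.counts, [0.0, 2.0, 0.0])

    def test_dimension_mismatch(self):
        grid = kp.AgeGrid(n_classes=3, step_years=5)
        kin = kp.KinArray(kin_type="a", focal_age=0, time=0.0,
                          counts=np.zeros(3), grid=grid, two_sex=False)
        with pytest.raises(KinshipError):
            kp.project_kin_step(kin, None, np.eye(4), np.zeros((4, 4)))


class TestTimeInvariant:
    def test_zero_fertility_errors_on_pi(self, grid3):
        per = make_period(grid3, f=[0, 0, 0], p_f=[0.9, 0.8, 0])
        with pytest.raises(KinshipError):
            kp.time_invariant_kinship(per, "one_sex")

    def test_zero_fertility_with_pi_gives_no_descendants(self, grid3):
        per = make_period(grid3, f=[0, 0, 0], p_f=[0.9, 0.8, 0])
        pi = kp.MotherAgeDistribution(pi=np.array([0.0, 1.0, 0.0]))
        net = kp.time_invariant_kinship(per, "one_sex", pi=pi)
        for code in ("a", "b", "c", "n", "q", "m", "p"):
            # no reproduction: no descendants and no siblings either
            assert net.arrays[code].max() == 0
        assert net.total("d", 0) == pytest.approx(1.0)

    def test_immortal_single_age_fertility(self):
        # fertility phi concentrated in class 1, no mortality inside the grid:
        # children settle at phi once Focal passes the fertile class, and
        # grandchildren reach phi^2 when those children have passed it too
        grid = kp.AgeGrid(n_classes=5, step_years=5)
        phi = 0.8
        per = make_period(grid, f=[0, phi, 0, 0, 0], p_f=[1, 1, 1, 1, 0])
        net = kp.time_invariant_kinship(per, "one_sex")
        assert net.total("a", 2) == pytest.approx(phi)
        assert net.total("a", 3) == pytest.approx(phi)
        assert net.total("b", 4) == pytest.approx(phi**2)

    def test_newborn_has_one_mother_or_two_parents(self, oracle_regime):
        one = kp.time_invariant_kinship(oracle_regime, "one_sex")
        two = kp.time_invariant_kinship(oracle_regime, "two_sex_androgynous")
        assert one.total("d", 0) == pytest.approx(1.0, abs=1e-12)
        assert two.total("d", 0) == pytest.approx(2.0, abs=1e-12)

    def test_closed_form_children(self, oracle_regime):
        f = oracle_regime.fertility.f
        p = oracle_regime.survival_female.p
        s = np.concatenate([[1.0], np.cumprod(p[:-1])])
        net = kp.time_invariant_kinship(oracle_regime, "one_sex")
        for x in range(21):
            expected = sum(f[y] * s[x - 1 - y] for y in range(x))
            assert net.total("a", x) == pytest.approx(expected, abs=1e-10)

    def test_matches_explicit_matrix_recursion(self, oracle_regime):
        """The structure-exploiting kernel equals literal U/F matrix algebra."""
        grid = oracle_regime.grid
        U = kp.build_survival_matrix(oracle_regime.survival_female, grid)
        F = kp.build_fertility_matrix(oracle_regime.fertility, grid, "both")
        net = kp.time_invariant_kinship(oracle_regime, "one_sex")
        a = np.zeros(grid.n_classes)
        for x in range(grid.n_classes - 1):
            e_x = np.zeros(grid.n_classes)
            e_x[x] = 1.0
            a = U @ a + F @ e_x
            assert np.allclose(net.counts("a", x + 1), a, atol=1e-12)

    def test_nonnegative_and_finite(self, oracle_regime):
        for variant in ("one_sex", "two_sex_androgynous"):
            net = kp.time_invariant_kinship(oracle_regime, variant)
            for code in KIN_CODES:
                arr = net.arrays[code]
                assert np.isfinite(arr).all() and (arr >= 0).all()

    def test_ancestor_bounds_two_sex(self, oracle_regime):
        net = kp.time_invariant_kinship(oracle_regime, "two_sex_androgynous")
        for x in range(21):
            assert net.total("d", x) <= 2 + 1e-9
            assert net.total("g", x) <= 4 + 1e-9
            assert net.total("h", x) <= 8 + 1e-9

    def test_younger_siblings_zero_at_birth(self, oracle_regime):
        for variant in ("one_sex", "two_sex_androgynous"):
            net = kp.time_invariant_kinship(oracle_regime, variant)
            assert net.total("n", 0) == 0.0
            assert net.total("m", 0) > 0.0


class TestStablePopulation:
    def test_structure_is_dominant_eigenvector(self, oracle_regime):
        lam, w = stable_population_structure(oracle_regime, "two_sex_androgynous")
        grid = oracle_regime.grid
        A = kp.build_survival_matrix(oracle_regime.survival_female, grid)
        A[0, :] += oracle_regime.fertility.f * oracle_regime.fertility.frac_female
        assert np.allclose(A @ w.female, lam * w.female, atol=1e-10)
        assert lam > 1.0  # TFR 4 regime grows


class TestTimeVariant:
    def test_constant_rates_limit(self, constant_series):
        inv = kp.time_invariant_kinship(constant_series.period_at(0),
                                        "two_sex_androgynous")
        var = kp.time_variant_kinship(constant_series, variant="two_sex_androgynous")
        for code in KIN_CODES:
            diff = np.abs(var.arrays[code] - inv.arrays[code][0]).max()
            assert diff < 1e-10

    def test_two_period_hand_recursion(self, grid3):
        f0 = np.array([0.2, 1.0, 0.0])
        p0 = np.array([0.9, 0.8, 0.0])
        per = make_period(grid3, f=f0, p_f=p0, pop_f=[3.0, 2.0, 1.0])
        series = kp.RateSeries(
            grid=grid3, times=(1950.0, 1955.0),
            fertility=(per.fertility,) * 2,
            survival_female=(per.survival_female,) * 2,
            survival_male=(per.survival_male,) * 2,
            population=(per.population,) * 2,
        )
        net = kp.time_variant_kinship(series, variant="one_sex")
        # children of Focal aged 1 at t=1: recruited at rate f0[0] in the
        # first interval, no survivors of anything older
        assert np.allclose(net.counts("a", 1, 1955.0), [f0[0], 0, 0])
        # children of Focal aged 2 at t=1: U0 . a(1, t0) + F0 e_1 by hand
        a1_t0 = np.array([f0[0], 0, 0])
        expected = np.array([f0[1], p0[0] * f0[0], 0])
        assert np.allclose(net.counts("a", 2, 1955.0),
                           np.array([[0, 0, 0], [p0[0], 0, 0], [0, p0[1], 0]]) @ a1_t0
                           + np.array([f0[1], 0, 0]))
        assert np.allclose(net.counts("a", 2, 1955.0), expected)

    def test_lower_survival_lowers_kin_counts(self, constant_series):
        halved = dataclasses.replace(
            constant_series,
            survival_female=tuple(
                m if i < 2 else kp.MortalitySchedule(sex="female", p=0.5 * m.p)
                for i, m in enumerate(constant_series.survival_female)
            ),
            survival_male=tuple(
                m if i < 2 else kp.MortalitySchedule(sex="male", p=0.5 * m.p)
                for i, m in enumerate(constant_series.survival_male)
            ),
        )
        base = kp.time_variant_kinship(constant_series, variant="two_sex_androgynous")
        low = kp.time_variant_kinship(halved, variant="two_sex_androgynous")
        t_last = constant_series.times[-1]
        for code in KIN_CODES:
            for x in (3, 7, 13):
                b = base.total(code, x, t_last)
                assert low.total(code, x, t_last) <= b + 1e-12
            # strict decrease wherever kin have actually been exposed to
            # mortality (fresh same-interval recruits are exposure-free)
            for x in (7, 13):
                b = base.total(code, x, t_last)
                if b > 1e-8:
                    assert low.total(code, x, t_last) < b

    def test_initial_mismatch_rejected(self, constant_series, oracle_regime):
        wrong = kp.time_invariant_kinship(oracle_regime, "two_sex_androgynous")
        with pytest.raises(KinshipError):
            kp.time_variant_kinship(constant_series, initial=wrong,
                                    variant="two_sex_androgynous")


class TestAndrogynous:
    def test_male_fertility_set_equal(self, constant_series):
        marked = kp.make_androgynous(constant_series)
        for i in range(marked.n_times):
            per = marked.period_at(i)
            assert per.fertility_male is not None
            assert np.array_equal(per.fertility_male.f, per.fertility.f)

    def test_symmetric_survival_doubles_parents(self, oracle_regime):
        # equal male and female survival and a common mothers'-age
        # distribution: two-sex parents are exactly twice the one-sex
        # (single-parent) counts at every Focal age
        _, w = stable_population_structure(oracle_regime, "two_sex_androgynous")
        pi = mother_age_distribution(oracle_regime.fertility, w)
        one = kp.time_invariant_kinship(oracle_regime, "one_sex", pi=pi)
        two = kp.time_invariant_kinship(oracle_regime, "two_sex_androgynous", pi=pi)
        for x in range(21):
            assert two.total("d", x) == pytest.approx(2 * one.total("d", x),
                                                      rel=1e-10, abs=1e-12)

    def test_dead_males_leave_no_fathers(self, grid3):
        p_m = np.array([0.0, 0.0, 0.0])
        per = make_period(grid3, f=[0, 1.0, 0], p_f=[0.9, 0.8, 0], p_m=p_m)
        net = kp.time_invariant_kinship(per, "two_sex_androgynous")
        for x in (1, 2):
            fathers = net.kin("d", x).male.sum()
            assert fathers == 0.0
        # the mother can still be alive
        assert net.kin("d", 1).female.sum() > 0
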