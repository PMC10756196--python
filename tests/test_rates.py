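"""Rate containers, projection matrices, unit conversion, and file I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kinproj as kp
from kinproj.rates import RateValidationError, validate_rate_table


class TestAgeGrid:
    def test_default_is_unwpp_shape(self):
        g = kp.AgeGrid.default()
        assert g.n_classes == 21 and g.step_years == 5
        assert g.lower_bounds[0] == 0 and g.lower_bounds[-1] == 100

    def test_class_index_open_ended(self):
        g = kp.AgeGrid.default()
        assert g.class_index(0) == 0
        assert g.class_index(67) == 13
        assert g.class_index(130) == 20  # open-ended class catches the rest

    @pytest.mark.parametrize("kwargs", [
        dict(n_classes=2, step_years=5),
        dict(n_classes=3, step_years=0),
        dict(n_classes=3, step_years=5, lower_bounds=(0, 5, 11)),
        dict(n_classes=3, step_years=5, lower_bounds=(0, 10, 5)),
    ])
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(RateValidationError):
            kp.AgeGrid(**kwargs)


class TestSchedules:
    def test_survival_bounds_enforced(self):
        with pytest.raises(RateValidationError):
            kp.MortalitySchedule(sex="female", p=np.array([0.9, 1.1, 0.0]))
        with pytest.raises(RateValidationError):
            kp.MortalitySchedule(sex="female", p=np.array([0.9, 0.8, 0.5]))

    def test_fertility_contiguous_support(self):
        with pytest.raises(RateValidationError):
            kp.FertilitySchedule(f=np.array([0.0, 1.0, 0.0, 1.0]))

    def test_frac_female_strict_bounds(self):
        for alpha in (0.0, 1.0):
            with pytest.raises(RateValidationError):
                kp.FertilitySchedule(f=np.array([0.0, 1.0, 0.0]), frac_female=alpha)

    def test_population_not_all_zero(self):
        with pytest.raises(RateValidationError):
            kp.PopulationStructure(female=np.zeros(3), male=np.zeros(3))


class TestSurvivalMatrix:
    def test_direct_placement(self, grid3):
        m = kp.MortalitySchedule(sex="female", p=np.array([0.9, 0.8, 0.0]))
        U = kp.build_survival_matrix(m, grid3)
        assert np.array_equal(U, [[0, 0, 0], [0.9, 0, 0], [0, 0.8, 0]])

    def test_zero_survival_gives_zero_matrix(self, grid3):
        m = kp.MortalitySchedule(sex="female", p=np.zeros(3))
        assert not kp.build_survival_matrix(m, grid3).any()

    def test_pure_aging_moves_cohort(self):
        grid = kp.AgeGrid(n_classes=4, step_years=5)
        m = kp.MortalitySchedule(sex="female", p=np.array([1.0, 1.0, 1.0, 0.0]))
        U = kp.build_survival_matrix(m, grid)
        e0 = np.array([1.0, 0, 0, 0])
        assert np.array_equal(np.linalg.matrix_power(U, 3) @ e0, [0, 0, 0, 1.0])

    def test_dimension_mismatch(self, grid21):
        m = kp.MortalitySchedule(sex="female", p=np.array([0.9, 0.8, 0.0]))
        with pytest.raises(RateValidationError):
            kp.build_survival_matrix(m, grid21)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=3, max_size=12))
    def test_survival_never_creates_mass(self, p):
        p = np.array(p + [0.0])
        grid = kp.AgeGrid(n_classes=len(p), step_years=5)
        U = kp.build_survival_matrix(kp.MortalitySchedule(sex="female", p=p), grid)
        assert (U.sum(axis=0) <= 1 + 1e-12).all()
        assert np.count_nonzero(U) == np.count_nonzero(p[:-1])
        v = np.arange(1.0, len(p) + 1)
        shifted = np.concatenate([[0.0], v[:-1]])
        assert ((U @ v) <= shifted + 1e-12).all()


class TestFertilityMatrix:
    def test_female_offspring_scaled_by_alpha(self, grid3):
        fs = kp.FertilitySchedule(f=np.array([0.0, 1.0, 0.0]), frac_female=0.5)
        F = kp.build_fertility_matrix(fs, grid3, "female")
        assert np.array_equal(F, [[0, 0.5, 0], [0, 0, 0], [0, 0, 0]])

    def test_zero_fertility_recruits_nothing(self, grid3):
        fs = kp.FertilitySchedule(f=np.zeros(3))
        assert not kp.build_fertility_matrix(fs, grid3, "both").any()

    def test_first_row_dot_product(self, grid3):
        fs = kp.FertilitySchedule(f=np.array([0.1, 0.2, 0.3]))
        F = kp.build_fertility_matrix(fs, grid3, "both")
        out = F @ np.array([2.0, 3.0, 4.0])
        assert out[0] == pytest.approx(2.0)
        assert not out[1:].any()


class TestAnnualToStep:
    def test_fertility_scaling(self, grid3):
        fs, _ = kp.annual_to_step_rates([0, 0.04, 0], [5.0, 4.5, 3.0], grid3)
        assert np.allclose(fs.f, [0, 0.2, 0])

    def test_survival_hand_ratio(self, grid3):
        _, m = kp.annual_to_step_rates([0, 0.04, 0], [5.0, 4.5, 3.0], grid3)
        assert np.allclose(m.p, [0.9, 2.0 / 3.0, 0.0])

    def test_constant_lx_gives_full_survival(self, grid3):
        _, m = kp.annual_to_step_rates([0, 0, 0], [2.0, 2.0, 2.0], grid3)
        assert np.array_equal(m.p, [1.0, 1.0, 0.0])

    def test_invalid_life_table(self, grid3):
        with pytest.raises(RateValidationError, match="life table"):
            kp.annual_to_step_rates([0, 0, 0], [5.0, 0.0, 3.0], grid3)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.001, 0.3), min_size=3, max_size=10))
    def test_tfr_recovered(self, asfr):
        grid = kp.AgeGrid(n_classes=len(asfr), step_years=5)
        L = np.linspace(5.0, 1.0, len(asfr))
        fs, _ = kp.annual_to_step_rates(asfr, L, grid)
        assert fs.tfr == pytest.approx(5 * sum(asfr), abs=1e-9)


class TestRateSeries:
    def test_times_spacing_must_match_grid(self, grid3):
        fs = kp.FertilitySchedule(f=np.array([0.0, 1.0, 0.0]))
        m = kp.MortalitySchedule(sex="female", p=np.array([0.9, 0.8, 0.0]))
        mm = kp.MortalitySchedule(sex="male", p=np.array([0.9, 0.8, 0.0]))
        pop = kp.PopulationStructure(female=np.ones(3), male=np.ones(3))
        with pytest.raises(RateValidationError, match="spacing"):
            kp.RateSeries(grid=grid3, times=(1950, 1960), fertility=(fs, fs),
                          survival_female=(m, m), survival_male=(mm, mm),
                          population=(pop, pop))


class TestRateFileIO:
    def test_round_trip_two_locations(self, toy_rate_csv):
        series = kp.read_rate_series(toy_rate_csv)
        assert sorted(series) == ["A", "B"]
        for s in series.values():
            assert s.times == (1950.0, 1955.0)
            assert s.grid.n_classes == 3
        assert series["A"].fertility[0].f[1] == pytest.approx(0.2)
        assert series["B"].fertility[0].f[1] == pytest.approx(0.1)
        assert np.allclose(series["A"].survival_female[0].p, [0.9, 2 / 3, 0.0])

    def test_missing_block_names_location_and_year(self, toy_rate_csv, tmp_path):
        df = pd.read_csv(toy_rate_csv)
        df = df[~((df.location == "B") & (df.year == 1955)
                  & (df.variable == "Lx") & (df.sex == "male"))]
        bad = tmp_path / "bad.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(RateValidationError, match=r"B.*Lx/male.*1955"):
            kp.read_rate_series(bad)

    def test_write_read_round_trip(self, toy_rate_csv, tmp_path):
        series = kp.read_rate_series(toy_rate_csv)
        p1 = tmp_path / "w1.csv"
        p1b = tmp_path / "w1b.csv"
        kp.write_rate_series(list(series.values()), p1)
        kp.write_rate_series(list(series.values()), p1b)
        # serialization is deterministic and bit-identical
        assert p1.read_bytes() == p1b.read_bytes()
        # re-read schedules match to floating-point precision (the Lx <-> p
        # conversion costs at most 1 ulp; full-precision CSV loses nothing)
        again = kp.read_rate_series(p1)
        for loc in series:
            for i in range(2):
                assert np.allclose(series[loc].fertility[i].f,
                                   again[loc].fertility[i].f, rtol=1e-15, atol=0)
                assert np.allclose(series[loc].survival_female[i].p,
                                   again[loc].survival_female[i].p, rtol=1e-15, atol=0)

    def test_column_mapping_config(self, toy_rate_csv, tmp_path):
        df = pd.read_csv(toy_rate_csv).rename(columns={
            "location": "Location", "year": "Time", "age_lower": "AgeGrp"})
        renamed = tmp_path / "wpp_style.csv"
        df.to_csv(renamed, index=False)
        cfg = {"columns": {"location": "Location", "year": "Time",
                           "age_lower": "AgeGrp"}}
        series = kp.read_rate_series(renamed, cfg)
        assert sorted(series) == ["A", "B"]

    def test_validator_lists_all_violations(self, toy_rate_csv):
        df = pd.read_csv(toy_rate_csv)
        df.loc[0, "value"] = -1.0
        df = pd.concat([df, df.iloc[[1]]])  # duplicate record
        issues = validate_rate_table(df)
        assert any("negative" in msg for msg in issues)
        assert any("duplicate" in msg for msg in issues)
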