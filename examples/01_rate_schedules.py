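"""Build synthetic demographic rate schedules and inspect them.

Generates a fertility age schedule (beta-shaped over the reproductive span)
and a Gompertz-Makeham survival schedule calibrated to a target life
expectancy, then prints their summary moments.
"""

import numpy as np

import kinproj as kp

grid = kp.AgeGrid.default()  # 21 five-year classes, 0-4 ... 100+
params = kp.ScheduleParams(
    tfr=2.5,                    # births per woman
    mean_age_childbearing=29.0,  # years
    fertility_width=6.0,         # SD of the fertility schedule, years
    life_expectancy_target=75.0,  # female e0; males get e0 - sex_gap_years
)

fert = kp.make_fertility(params, grid)
mort_f = kp.make_mortality(params, grid, "female")
mort_m = kp.make_mortality(params, grid, "male")

print(f"TFR = {fert.tfr:.3f} births per woman (sum of per-step rates)")
print(f"mean age of childbearing = {fert.mean_age(grid):.1f} y")
print("per-step fertility f[x] on classes 15-49:",
      np.round(fert.f[3:10], 3))
e0f = grid.step_years * mort_f.survivorship().sum()
e0m = grid.step_years * mort_m.survivorship().sum()
print(f"discrete-grid life expectancy: female ~{e0f:.1f} y, male ~{e0m:.1f} y")
print("five-year survival p[x] at ages 60-84:",
      np.round(mort_f.p[12:17], 3))
# The survival matrix U places p[x] on the subdiagonal; the fertility matrix
# F places the rates in the first row (newborns enter age class 0).
U = kp.build_survival_matrix(mort_f, grid)
F = kp.build_fertility_matrix(fert, grid, "female")
print(f"U is {U.shape} with {np.count_nonzero(U)} nonzero survival entries; "
      f"F recruits daughters at rate alpha*f (alpha = {fert.frac_female:.4f})")
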