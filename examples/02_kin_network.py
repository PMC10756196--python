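"""Expected kin of a female Focal under one fixed rate regime.

Runs the time-invariant two-sex kinship model on a single synthetic rate
period and prints the expected number of living relatives by category at
three ages of Focal, plus mean kin ages. Counts are expectations for a
randomly chosen woman alive at that age.
"""

import numpy as np

import kinproj as kp
from kinproj.pipeline import ZeroKinError

grid = kp.AgeGrid.default()
params = kp.ScheduleParams(tfr=4.0, mean_age_childbearing=28.0,
                           life_expectancy_target=60.0, sex_gap_years=3.0)
period = kp.RatePeriod(
    grid=grid, time=1950.0,
    fertility=kp.make_fertility(params, grid),
    survival_female=kp.make_mortality(params, grid, "female"),
    survival_male=kp.make_mortality(params, grid, "male"),
    population=kp.PopulationStructure(female=np.ones(21), male=np.ones(21)),
)

net = kp.time_invariant_kinship(period, "two_sex_androgynous")

print("expected living kin (TFR 4, e0 60 regime held fixed)\n")
header = f"{'kin category':<22}" + "".join(f"{a:>10}" for a in (0, 35, 65))
print(header + f"{'mean age @35':>14}")
for cat in kp.KIN_CATEGORIES:
    row = f"{cat:<22}"
    for age in (0, 35, 65):
        row += f"{net.category_total(cat, grid.class_index(age)):>10.2f}"
    try:
        ma = kp.mean_kin_age(net.category_counts(cat, 7), grid)
        row += f"{ma:>13.1f}y"
    except ZeroKinError:
        row += f"{'-':>14}"
    print(row)
for age in (0, 35, 65):
    x = grid.class_index(age)
    print(f"\ntotal family size at age {age}: "
          f"{kp.total_family_size(net, x):.1f} living relatives")
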