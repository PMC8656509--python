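"""Rank socioeconomic drivers of ESV change by grey relational grade.

Seven driver trajectories (population, urbanization, GDP, industry
proportions, fixed-asset investment, afforestation) are generated inside
their published 2009-2018 ranges; each is scored by how closely its
normalized curve tracks the normalized annual total-ESV curve.  Grades
near 1 mean near-synchronous movement.
"""

import esvgrey as eg

fx = eg.make_study_fixture()
scenario = eg.default_scenario(seed=0, noise_cv=0.01)
areas = eg.generate_land_use_series(scenario)
drivers = eg.generate_driver_series(scenario)
totals = eg.compute_esv(areas, fx.vc).totals

windows = [(2009, 2018), (2009, 2012), (2012, 2015), (2015, 2018)]
for result in eg.rank_drivers(totals, drivers, windows=windows):
    grades = ", ".join(f"{n}={result.grades[n]:.4f}" for n in result.ranking)
    print(f"{result.window[0]}-{result.window[1]}: {grades}")
print()
full = eg.rank_drivers(totals, drivers)[0]
print(
    f"Over the full period the ranking is {' > '.join(full.ranking)}: the "
    "slow monotone series (population, industry proportions) track the slow "
    "ESV decline most closely, while volatile investment series rank last."
)
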