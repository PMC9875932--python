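"""Annual atrophy rates and group effect sizes on a synthetic cohort.

Generates the default 75-patient cohort (9 PPMS, 66 RRMS), measures it
with the DL-like and FS-like channels, fits one thickness-on-age slope
per patient x method x image type (patients need >= 3 time points), and
prints the group summary table.
"""

import dataclasses

from cemorph import compute_atrophy_rates, group_effect_table, simulate_study
from cemorph.synthetic import default_study_config

config, models = default_study_config()
truth, measured = simulate_study(dataclasses.replace(config, seed=1), models)
rates = compute_atrophy_rates(measured, min_timepoints=3)
print(
    f"rated patients: {rates['subject_id'].nunique()} "
    f"(excluded series: {rates.attrs['n_excluded']})\n"
)
table = group_effect_table(rates)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(
    "\nRows PPMS/RRMS hold mean slopes in mm/year for non-enhanced and CE "
    "images (column d: non-enhanced vs CE effect size); the last row per "
    "method is Cohen's d between PPMS and RRMS per image type.  The "
    "progressive group atrophies faster on average, but with only 9 PPMS "
    "patients a single cohort's group means carry a standard error of "
    "~0.01 mm/year."
)
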