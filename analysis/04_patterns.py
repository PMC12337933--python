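"""Drug-utilization patterns (objective 1, secondary outcome).

Classifies continuation / discontinuation / switch / add-on (non-exclusive)
for patients persisting beyond one treatment year, and tabulates switch and
add-on target classes.
"""

from pathlib import Path

import pandas as pd

from rxadherence.cohort import persistent_subcohort
from rxadherence.tables import classify_cohort, pattern_rates, switch_addon_matrices

OUT = Path("results/analysis")


def main() -> None:
    disp = pd.read_csv(OUT / "dispensings.csv", parse_dates=["dispense_date"])
    cohort = pd.read_csv(OUT / "cohort.csv", parse_dates=["index_date"])
    sub = persistent_subcohort(cohort, 1)
    profiles = classify_cohort(sub, disp, study_end="2020-12-31")
    profiles.to_csv(OUT / "patterns.csv", index=False)
    rates = pattern_rates(profiles).round(1)
    rates.to_csv(OUT / "pattern_rates.csv", index=False)
    sw, ad = switch_addon_matrices(profiles)
    sw.to_csv(OUT / "switch_matrix.csv")
    ad.to_csv(OUT / "addon_matrix.csv")
    print(f"patterns among {len(profiles)} patients on monotherapy > 360 days")
    print("(percentages are non-exclusive and can sum past 100%)")
    print(rates.to_string(index=False))
    if not sw.empty:
        print("most common switch target per class:",
              sw.idxmax(axis=1).to_dict())


if __name__ == "__main__":
    main()
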