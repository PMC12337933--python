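"""Build the new-user inception cohort from the simulated dispensing records.

Applies the 730-day washout, the exclusion-drug window (index −730 to +90
days), the adult-age filter, the follow-up end rule and covariate
derivation; prints the patient-selection flow.
"""

from pathlib import Path

import pandas as pd

from rxadherence.cohort import build_cohort

OUT = Path("results/analysis")


def main() -> None:
    disp = pd.read_csv(OUT / "dispensings.csv", parse_dates=["dispense_date"])
    patients = pd.read_csv(OUT / "patients.csv", parse_dates=["birth_date"])
    res = build_cohort(disp, patients, study_end="2020-12-31")
    res.cohort.to_csv(OUT / "cohort.csv", index=False)
    print("patient-selection flow:")
    for step, n in res.flow.items():
        print(f"  {step}: {n}")
    print("censoring reasons:", res.cohort["censor_reason"].value_counts().to_dict())
    print("index classes:", res.cohort["index_class"].value_counts().to_dict())


if __name__ == "__main__":
    main()
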