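"""Risk-factor clustering (objective 2, step 1).

Gower distance over the categorical risk-factor profiles of the
one-year-persistent sub-cohort, PAM clustering, and silhouette-based choice
of the number of clusters.
"""

from pathlib import Path

import pandas as pd

from rxadherence.clustering import gower_matrix, pam, select_k
from rxadherence.cohort import persistent_subcohort
from rxadherence.pipeline import RISK_FACTORS

OUT = Path("results/analysis")
K_RANGE = range(2, 9)
SEED = 7


def main() -> None:
    cohort = pd.read_csv(OUT / "cohort.csv", parse_dates=["index_date"])
    sub = persistent_subcohort(cohort, 1).reset_index(drop=True)
    features = sub[RISK_FACTORS]
    D = gower_matrix(features)
    best_k, profile = select_k(D, K_RANGE, seed=SEED)
    sol = pam(D, best_k, seed=SEED)
    pd.DataFrame(
        {"patient_id": sub["patient_id"], "cluster": sol.assignment}
    ).to_csv(OUT / "cluster_assignments.csv", index=False)
    profile.round(4).to_csv(OUT / "silhouette_by_k.csv", index=False)
    print("average silhouette width by K:")
    print(profile.round(3).to_string(index=False))
    sizes = pd.Series(sol.assignment).value_counts().sort_index().to_dict()
    print(f"selected K = {best_k}; cluster sizes: {sizes}")


if __name__ == "__main__":
    main()
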