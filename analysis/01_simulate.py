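"""Generate the synthetic dispensing database used by the whole analysis.

Writes patients.csv, dispensings.csv and truth.csv (the planted ground
truth) under results/analysis/.  All later numbered scripts read from there.
"""

from pathlib import Path

from rxadherence.simulate import SimulationConfig, simulate_population

OUT = Path("results/analysis")
SEED = 7
N_PATIENTS = 2000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(n_patients=N_PATIENTS, seed=SEED)
    patients, dispensings, truth = simulate_population(cfg)
    patients.to_csv(OUT / "patients.csv", index=False)
    dispensings.to_csv(OUT / "dispensings.csv", index=False)
    truth.to_csv(OUT / "truth.csv", index=False)
    print(f"simulated {len(patients)} patients, {len(dispensings)} dispensings (seed={SEED})")
    print("archetype mix:", truth["archetype"].value_counts(normalize=True).round(3).to_dict())
    print("exposure mix:", truth["exposure_class"].value_counts(normalize=True).round(3).to_dict())


if __name__ == "__main__":
    main()
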