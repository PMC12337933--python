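"""End-to-end pipeline: simulate → cohort → adherence → patterns → cluster →
predict → survive, from one structured config into a reproducible artifact
directory of CSV outputs plus a run manifest.

Every stage reads only the stage outputs before it, so the chain can be run
on synthetic data (built-in generator) or on user-supplied dispensing and
patient CSVs with identical downstream behaviour.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classmap import DEFAULT_CLASS_MAP, ClassMap
from .cohort import build_cohort, long_record_subcohort, persistent_subcohort
from .clustering import gower_matrix, pam, select_k
from .coverage import covered_intervals
from .models import (
    compare_penalties,
    cv_penalized_fit,
    final_logistic_from_lasso,
    make_design,
    plain_logistic_report,
    vif_screen,
)
from .simulate import SimulationConfig, simulate_population
from .survival import (
    cox_fit,
    event_table,
    km_estimate,
    stabilized_ipw,
    survival_metrics,
)
from .tables import (
    _per_patient_dispensings,
    adherence_tables,
    classify_cohort,
    pattern_rates,
    switch_addon_matrices,
)

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "cohort", "adherence", "patterns", "cluster", "predict", "survive")

RISK_FACTORS = [
    "index_class", "sex", "age_band", "diabetes", "ra", "asthma_copd",
    "antiepileptics", "antiparkinson", "psycholeptics", "psychoanaleptics",
    "addictive_disorders", "antineoplastics", "calendar_period",
]


@dataclass
class PipelineConfig:
    out_dir: str = "results/run"
    seed: int = 0
    synthetic: bool = True
    dispensings_csv: str | None = None
    patients_csv: str | None = None
    simulation: dict = field(default_factory=dict)
    class_map_overrides: dict = field(default_factory=dict)
    study_end: str = "2020-12-31"
    policy: str = "carryover"
    stages: dict = field(default_factory=lambda: {s: True for s in ALL_STAGES})
    k_range: tuple[int, int] = (2, 10)
    cluster_adherence: bool = False
    penalties: tuple[str, ...] = ("ridge", "lasso", "elastic_net")
    lambda_rule: str = "min"
    per_cluster_models: bool = True
    cutpoints: tuple[int, ...] = (0, 180, 540, 1080)
    weight_truncation: tuple[float, float] = (0.01, 0.99)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


def _write(df: pd.DataFrame, out: Path, name: str, manifest: dict) -> None:
    path = out / name
    df.to_csv(path, index=False)
    manifest["outputs"][name] = int(len(df))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    class_map = (
        DEFAULT_CLASS_MAP.with_overrides(**config.class_map_overrides)
        if config.class_map_overrides
        else DEFAULT_CLASS_MAP
    )
    manifest: dict = {
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "seed": config.seed,
        "outputs": {},
        "flow": {},
    }

    # ------------------------------------------------------------------ data
    if config.synthetic:
        sim_cfg = SimulationConfig(**{"seed": config.seed, **config.simulation})
        patients, disp, truth = simulate_population(sim_cfg)
        if config.enabled("simulate"):
            _write(patients, out, "patients.csv", manifest)
            _write(disp, out, "dispensings.csv", manifest)
            _write(truth, out, "truth.csv", manifest)
    else:
        if not (config.dispensings_csv and config.patients_csv):
            raise ValueError("non-synthetic mode needs dispensings_csv and patients_csv")
        disp = pd.read_csv(config.dispensings_csv, parse_dates=["dispense_date"])
        patients = pd.read_csv(config.patients_csv, parse_dates=["birth_date"])

    # ---------------------------------------------------------------- cohort
    if not config.enabled("cohort"):
        _finish(out, manifest)
        return out
    res = build_cohort(disp, patients, class_map, study_end=config.study_end)
    cohort = res.cohort
    manifest["flow"].update(res.flow)
    _write(cohort, out, "cohort.csv", manifest)

    per_patient = _per_patient_dispensings(cohort, disp, class_map)
    timelines = {
        pid: covered_intervals(own, config.policy)
        for pid, (own, _, _) in per_patient.items()
    }

    # ------------------------------------------------------------- adherence
    annual = overall = None
    if config.enabled("adherence"):
        annual, overall = adherence_tables(cohort, disp, class_map, config.policy)
        _write(annual, out, "adherence_annual.csv", manifest)
        _write(overall, out, "adherence_overall.csv", manifest)
        rates = (
            annual.groupby("year")
            .agg(n=("pdc", "size"), mean_pdc=("pdc", "mean"),
                 high_rate_pct=("high_adherence", lambda s: 100 * s.mean()))
            .reset_index()
        )
        _write(rates, out, "adherence_rates_by_year.csv", manifest)

    # -------------------------------------------------------------- patterns
    profiles = None
    if config.enabled("patterns"):
        profiles = classify_cohort(
            persistent_subcohort(cohort, 1), disp, class_map,
            study_end=config.study_end, policy=config.policy,
        )
        _write(profiles, out, "patterns.csv", manifest)
        _write(pattern_rates(profiles), out, "pattern_rates.csv", manifest)
        sw, ad = switch_addon_matrices(profiles)
        sw.to_csv(out / "switch_matrix.csv")
        ad.to_csv(out / "addon_matrix.csv")

    # ------------------------------------------------- objective-2 sub-cohort
    needs_obj2 = config.enabled("cluster") or config.enabled("predict")
    features = outcome = None
    if needs_obj2 and annual is not None:
        sub = persistent_subcohort(cohort, 1).reset_index(drop=True)
        y1 = annual[annual["year"] == 1].set_index("patient_id")["high_adherence"]
        sub = sub[sub["patient_id"].isin(y1.index)].reset_index(drop=True)
        features = sub[["patient_id"] + RISK_FACTORS].copy()
        outcome = y1.reindex(sub["patient_id"]).to_numpy(bool)
        manifest["flow"]["objective2_subcohort"] = int(len(sub))

    # ---------------------------------------------------------------- cluster
    assignments = None
    if config.enabled("cluster") and features is not None:
        feat = features.drop(columns=["patient_id"]).copy()
        if config.cluster_adherence:
            feat["adherence"] = np.where(outcome, "high", "low")
        D = gower_matrix(feat)
        lo, hi = config.k_range
        best_k, profile = select_k(D, range(lo, hi + 1), seed=config.seed)
        sol = pam(D, best_k, seed=config.seed)
        assignments = pd.DataFrame(
            {"patient_id": features["patient_id"], "cluster": sol.assignment}
        )
        _write(assignments, out, "cluster_assignments.csv", manifest)
        _write(profile, out, "silhouette_by_k.csv", manifest)
        manifest["selected_k"] = int(best_k)

    # ---------------------------------------------------------------- predict
    if config.enabled("predict") and features is not None:
        design = make_design(features.drop(columns=["patient_id"]))
        _write(vif_screen(design), out, "vif.csv", manifest)
        fits = {
            p: cv_penalized_fit(
                design, outcome.astype(float), p,
                seed=config.seed, lambda_rule=config.lambda_rule,
            )
            for p in config.penalties
        }
        _write(compare_penalties(list(fits.values())), out, "penalty_comparison.csv", manifest)
        lasso = fits.get("lasso") or next(iter(fits.values()))
        report = final_logistic_from_lasso(lasso, design, outcome.astype(float))
        _write(report.coefficients, out, "final_model_coefficients.csv", manifest)
        sens = plain_logistic_report(
            design, outcome.astype(float), lasso.train_idx, lasso.test_idx
        )
        _write(sens.coefficients, out, "sensitivity_model_coefficients.csv", manifest)
        metrics = pd.DataFrame(
            [
                {"model": "lasso", **lasso.metrics, "nagelkerke_r2": np.nan,
                 "hl_stat": np.nan, "hl_p": np.nan},
                {"model": "final_logistic", **report.metrics,
                 "nagelkerke_r2": report.nagelkerke,
                 "hl_stat": report.hosmer_lemeshow[0], "hl_p": report.hosmer_lemeshow[1]},
                {"model": "sensitivity_logistic", **sens.metrics,
                 "nagelkerke_r2": sens.nagelkerke,
                 "hl_stat": sens.hosmer_lemeshow[0], "hl_p": sens.hosmer_lemeshow[1]},
            ]
        )
        _write(metrics, out, "prediction_metrics.csv", manifest)
        manifest["lasso_selected_variables"] = report.selected_variables
        manifest["chosen_lambda"] = {p: f.chosen_lambda for p, f in fits.items()}

        if config.per_cluster_models and assignments is not None:
            rows = []
            for c, grp in assignments.groupby("cluster"):
                mask = features["patient_id"].isin(grp["patient_id"]).to_numpy()
                y_c = outcome[mask].astype(float)
                if len(np.unique(y_c)) < 2 or mask.sum() < 60:
                    continue
                d_c = make_design(
                    features.loc[mask].drop(columns=["patient_id"])
                )
                fit_c = cv_penalized_fit(
                    d_c, y_c, "lasso", seed=config.seed, lambda_rule=config.lambda_rule
                )
                rep_c = final_logistic_from_lasso(fit_c, d_c, y_c)
                tbl = rep_c.coefficients.assign(cluster=c)
                rows.append(tbl)
            if rows:
                _write(pd.concat(rows), out, "per_cluster_coefficients.csv", manifest)

    # ---------------------------------------------------------------- survive
    if config.enabled("survive"):
        sub3 = long_record_subcohort(cohort, disp, 1080).reset_index(drop=True)
        manifest["flow"]["objective3_subcohort"] = int(len(sub3))
        ev = event_table(sub3, timelines)
        ev = ev.rename(columns={"index_class": "exposure"})
        _write(
            ev[["patient_id", "time", "event", "exposure"]],
            out, "event_times.csv", manifest,
        )
        km = km_estimate(ev["time"], ev["event"], ev["exposure"])
        _write(km, out, "km_curves.csv", manifest)
        km_all = km_estimate(ev["time"], ev["event"])
        _write(km_all, out, "km_overall.csv", manifest)

        covars = [c for c in RISK_FACTORS if c != "index_class"]
        w, diag = stabilized_ipw(
            ev[covars], ev["exposure"], truncation=config.weight_truncation
        )
        pd.DataFrame(
            {"smd_before": diag["smd_before"], "smd_after": diag["smd_after"]}
        ).to_csv(out / "weight_balance.csv")
        manifest["ipw"] = {
            "mean_weight": diag["mean_weight"], "n_truncated": diag["n_truncated"]
        }

        hr_rows, metric_rows = [], []
        present = sorted(ev["exposure"].unique())
        reference = "bb" if "bb" in present else present[0]
        for label, weights in (("crude", None), ("ipw", w)):
            for td in (False, True):
                if not ev["event"].any():
                    continue
                rep = cox_fit(
                    ev, exposure_col="exposure", reference=reference,
                    weights=weights, time_dependent=td, cutpoints=config.cutpoints,
                )
                tbl = rep.summary.assign(adjustment=label, time_dependent=td)
                hr_rows.append(tbl)
                m = survival_metrics(rep, ev)
                metric_rows.append({"adjustment": label, "time_dependent": td, **m})
        if hr_rows:
            _write(pd.concat(hr_rows), out, "hazard_ratios.csv", manifest)
            _write(pd.DataFrame(metric_rows), out, "survival_metrics.csv", manifest)

    _finish(out, manifest)
    return out


def _finish(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
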