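"""Time-to-high-adherence survival analysis.

The event is the attainment of high adherence: follow-up is cut into
consecutive 180-day windows from the index date, the window PDC is computed
for each, and the event is placed at the end of the first window with
PDC >= 0.8; patients never reaching it are censored at min(follow-up end,
1080 days).  Kaplan–Meier curves then describe the probability of *remaining
in low adherence* over the first three years, and Cox regression compares the
five monotherapy classes (reference: beta-blockers), crude and reweighted by
stabilized inverse-probability-of-treatment weights from a multinomial
propensity model, with and without piecewise time-dependent exposure effects
(episodes split at 180 and 540 days).  Ties are handled with Efron's method
(the lifelines default) and a robust sandwich variance is used whenever the
fit is weighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.utils import concordance_index
from sklearn.linear_model import LogisticRegression

from .coverage import HIGH_ADHERENCE_THRESHOLD, Interval, covered_days
from .models import DesignMatrix, make_design, nagelkerke_r2

EVENT_WINDOW_DAYS = 180
HORIZON_DAYS = 1080
DEFAULT_CUTPOINTS = (0, 180, 540, 1080)


# ---------------------------------------------------------------------------
# event construction
# ---------------------------------------------------------------------------

def adherence_event_times(
    intervals: list[Interval],
    followup_end_day: int,
    interval_len: int = EVENT_WINDOW_DAYS,
    horizon: int = HORIZON_DAYS,
    threshold: float = HIGH_ADHERENCE_THRESHOLD,
) -> tuple[int, bool]:
    """(time, event) for the transition from low to high adherence.

    Event at the end of the first ``interval_len``-day window with window
    PDC >= ``threshold``; censored at ``min(followup_end_day, horizon)``
    when no complete window qualifies.
    """
    if followup_end_day <= 0:
        raise ValueError("followup_end_day must be positive")
    end = min(int(followup_end_day), horizon)
    w = 1
    while w * interval_len <= end:
        lo, hi = (w - 1) * interval_len, w * interval_len
        pdc = covered_days(intervals, lo, hi) / interval_len
        if pdc >= threshold:
            return w * interval_len, True
        w += 1
    return end, False


def event_table(
    cohort: pd.DataFrame,
    timelines: dict[object, list[Interval]],
    interval_len: int = EVENT_WINDOW_DAYS,
    horizon: int = HORIZON_DAYS,
) -> pd.DataFrame:
    """EventRecord table (patient_id, time, event, exposure + covariates)."""
    rows = []
    for row in cohort.itertuples(index=False):
        t, e = adherence_event_times(
            timelines.get(row.patient_id, []),
            int(row.followup_end_day),
            interval_len,
            horizon,
        )
        rec = row._asdict()
        rec["time"] = t
        rec["event"] = e
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_estimate(
    times, events, groups=None
) -> pd.DataFrame:
    """Product-limit curves of remaining in low adherence, per group.

    Returns tidy step-function points (group, time, survival).
    """
    df = pd.DataFrame(
        {
            "time": np.asarray(times, float),
            "event": np.asarray(events, bool),
            "group": "all" if groups is None else np.asarray(groups),
        }
    )
    out = []
    for g, grp in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], grp["event"])
        sf = kmf.survival_function_
        for t, s in zip(sf.index, sf.iloc[:, 0]):
            out.append({"group": g, "time": float(t), "survival": float(s)})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# stabilized IPW
# ---------------------------------------------------------------------------

def stabilized_ipw(
    covariates: pd.DataFrame,
    exposure: pd.Series,
    truncation: tuple[float, float] = (0.01, 0.99),
) -> tuple[pd.Series, dict]:
    """Stabilized inverse-probability-of-treatment weights.

    A multinomial-logistic propensity model of exposure given the (dummy
    encoded) covariates yields fitted probabilities; the weight is the
    marginal class probability over the fitted conditional one, truncated at
    the stated weight percentiles.  Returns weights plus diagnostics
    (mean weight, truncation count, covariate balance before/after).
    """
    exposure = pd.Series(exposure).astype(str).reset_index(drop=True)
    design = make_design(covariates.reset_index(drop=True))
    model = LogisticRegression(C=1e6, solver="lbfgs", max_iter=5000)
    model.fit(design.X, exposure)
    proba = model.predict_proba(design.X)
    class_idx = pd.Categorical(exposure, categories=list(model.classes_)).codes
    p_cond = proba[np.arange(len(exposure)), class_idx]
    n_nonoverlap = int((p_cond < 1e-6).sum())
    if n_nonoverlap:
        warnings.warn(
            f"{n_nonoverlap} fitted propensities ~0: positivity is doubtful"
        )
    p_marg = exposure.value_counts(normalize=True).reindex(model.classes_).to_numpy()
    w = p_marg[class_idx] / np.clip(p_cond, 1e-12, None)
    lo, hi = np.quantile(w, truncation)
    n_trunc = int(((w < lo) | (w > hi)).sum())
    w = np.clip(w, lo, hi)
    diag = {
        "mean_weight": float(w.mean()),
        "n_truncated": n_trunc,
        "smd_before": standardized_mean_differences(design, exposure),
        "smd_after": standardized_mean_differences(design, exposure, w),
    }
    return pd.Series(w, index=exposure.index, name="ipw"), diag


def standardized_mean_differences(
    design: DesignMatrix | pd.DataFrame,
    groups: pd.Series,
    weights: np.ndarray | None = None,
) -> pd.Series:
    """Max pairwise absolute SMD per design column across exposure groups."""
    X = design.X if isinstance(design, DesignMatrix) else np.asarray(design, float)
    names = design.columns if isinstance(design, DesignMatrix) else list(design.columns)
    groups = pd.Series(groups).reset_index(drop=True)
    w = np.ones(len(groups)) if weights is None else np.asarray(weights, float)
    stats = {}
    uniq = sorted(groups.unique())
    for j, name in enumerate(names):
        col = X[:, j]
        sd = col.std(ddof=1)
        if sd < 1e-12:
            stats[name] = 0.0
            continue
        means = []
        for g in uniq:
            m = (groups == g).to_numpy()
            means.append(np.average(col[m], weights=w[m]))
        diffs = [abs(a - b) for i, a in enumerate(means) for b in means[i + 1:]]
        stats[name] = max(diffs) / sd
    return pd.Series(stats, name="smd")


# ---------------------------------------------------------------------------
# Cox models
# ---------------------------------------------------------------------------

@dataclass
class SurvivalReport:
    summary: pd.DataFrame  # term, coef, hr, ci_low, ci_high, se, p
    log_likelihood: float
    log_likelihood_null: float
    n: int
    n_events: int
    time_dependent: bool
    weighted: bool
    model: object = field(repr=False, default=None)
    linear_predictor: pd.Series | None = field(repr=False, default=None)


def _dummyize(
    df: pd.DataFrame, exposure_col: str, reference: str, covariate_cols: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    out = pd.DataFrame(index=df.index)
    levels = [l for l in sorted(df[exposure_col].astype(str).unique()) if l != reference]
    for lev in levels:
        out[f"{exposure_col}_{lev}"] = (df[exposure_col].astype(str) == lev).astype(float)
    expo_cols = list(out.columns)
    for c in covariate_cols:
        series = df[c]
        if series.dtype == bool:
            out[c] = series.astype(float)
        else:
            vals = series.astype(str)
            ref = vals.value_counts().idxmax()
            for lev in sorted(vals.unique()):
                if lev != ref:
                    out[f"{c}_{lev}"] = (vals == lev).astype(float)
    return out, expo_cols


def _fit_with_fallback(fitter_cls, df, **fit_kwargs):
    """Fit a lifelines Cox model; on a degenerate (singular or separable)
    design, flag it and refit with a small L2 penalizer."""
    try:
        fitter = fitter_cls()
        fitter.fit(df, **fit_kwargs)
        return fitter
    except (np.linalg.LinAlgError, ValueError) as err:
        warnings.warn(
            f"degenerate design for {fitter_cls.__name__} ({err}); "
            "refitting with penalizer=0.05"
        )
        fitter = fitter_cls(penalizer=0.05)
        fitter.fit(df, **fit_kwargs)
        return fitter


def _summary_from(fitter) -> pd.DataFrame:
    s = fitter.summary
    return pd.DataFrame(
        {
            "term": s.index,
            "coef": s["coef"].to_numpy(),
            "hr": s["exp(coef)"].to_numpy(),
            "ci_low": np.exp(s["coef lower 95%"].to_numpy()),
            "ci_high": np.exp(s["coef upper 95%"].to_numpy()),
            "se": s["se(coef)"].to_numpy(),
            "p": s["p"].to_numpy(),
        }
    ).reset_index(drop=True)


def expand_episodes(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    cutpoints: tuple[int, ...] = DEFAULT_CUTPOINTS,
) -> pd.DataFrame:
    """Counting-process episodes split at ``cutpoints`` (id/start/stop/event)."""
    cuts = sorted(set(cutpoints))
    rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = row._asdict()
        t = float(rec[duration_col])
        e = bool(rec[event_col])
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            if t <= lo:
                break
            stop = min(t, hi)
            ep = dict(rec)
            ep.update(
                {
                    "episode_id": i,
                    "start": float(lo),
                    "stop": float(stop),
                    "episode_event": e and (t <= hi),
                    "interval": f"{lo}-{hi}",
                }
            )
            rows.append(ep)
    return pd.DataFrame(rows)


def cox_fit(
    df: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    exposure_col: str = "exposure",
    reference: str = "bb",
    covariate_cols: list[str] | None = None,
    weights: pd.Series | np.ndarray | None = None,
    time_dependent: bool = False,
    cutpoints: tuple[int, ...] = DEFAULT_CUTPOINTS,
) -> SurvivalReport:
    """Cox proportional-hazards fit of time-to-high-adherence.

    Without time-dependent effects: one hazard ratio per exposure class vs
    the reference.  With them: episodes over ``cutpoints`` carry
    interval-specific exposure coefficients.  A robust variance is used
    whenever weights differ from 1.
    """
    covariate_cols = covariate_cols or []
    df = df.reset_index(drop=True)
    if not df[event_col].astype(bool).any():
        raise ValueError("no events observed")
    w = np.ones(len(df)) if weights is None else np.asarray(weights, float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    weighted = weights is not None and not np.allclose(w, 1.0)

    X, expo_cols = _dummyize(df, exposure_col, reference, covariate_cols)

    if not time_dependent:
        data = X.copy()
        data[duration_col] = df[duration_col].astype(float)
        data[event_col] = df[event_col].astype(bool)
        data["wt"] = w
        cph = _fit_with_fallback(
            CoxPHFitter,
            data,
            duration_col=duration_col,
            event_col=event_col,
            weights_col="wt",
            robust=weighted,
        )
        ll = float(cph.log_likelihood_)
        ll_null = ll - float(cph.log_likelihood_ratio_test().test_statistic) / 2.0
        lp = pd.Series(
            np.asarray(X @ cph.params_.reindex(X.columns).to_numpy()), index=df.index
        )
        return SurvivalReport(
            summary=_summary_from(cph),
            log_likelihood=ll,
            log_likelihood_null=ll_null,
            n=len(df),
            n_events=int(df[event_col].sum()),
            time_dependent=False,
            weighted=weighted,
            model=cph,
            linear_predictor=lp,
        )

    base = X.copy()
    base[duration_col] = df[duration_col].astype(float)
    base[event_col] = df[event_col].astype(bool)
    base["wt"] = w
    long = expand_episodes(base, duration_col, event_col, cutpoints)
    cuts = sorted(set(cutpoints))
    intervals = [f"{lo}-{hi}" for lo, hi in zip(cuts[:-1], cuts[1:])]
    cols = []
    for name in intervals:
        ind = (long["interval"] == name).astype(float)
        for ec in expo_cols:
            cn = f"{ec}@{name}"
            long[cn] = long[ec] * ind
            cols.append(cn)
    other_cols = [c for c in X.columns if c not in expo_cols]
    fit_df = long[["episode_id", "start", "stop", "episode_event", "wt"] + cols + other_cols]
    ctv = _fit_with_fallback(
        CoxTimeVaryingFitter,
        fit_df,
        id_col="episode_id",
        event_col="episode_event",
        start_col="start",
        stop_col="stop",
        weights_col="wt",
        # lifelines' time-varying fitter has no sandwich variance; TD CIs are
        # model-based even under weighting (see methods note)
        robust=False,
    )
    ll = float(ctv.log_likelihood_)
    try:
        ll_null = ll - float(ctv.log_likelihood_ratio_test().test_statistic) / 2.0
    except Exception:
        ll_null = np.nan
    # per-subject prognostic score: episode-length-weighted mean linear predictor
    lp_long = np.asarray(fit_df[cols + other_cols] @ ctv.params_.to_numpy())
    length = (fit_df["stop"] - fit_df["start"]).to_numpy()
    agg = pd.DataFrame(
        {"id": long["episode_id"], "lp": lp_long * length, "len": length}
    ).groupby("id").sum()
    lp = pd.Series((agg["lp"] / agg["len"]).to_numpy(), index=df.index)
    return SurvivalReport(
        summary=_summary_from(ctv),
        log_likelihood=ll,
        log_likelihood_null=ll_null,
        n=len(df),
        n_events=int(df[event_col].sum()),
        time_dependent=True,
        weighted=weighted,
        model=ctv,
        linear_predictor=lp,
    )


# ---------------------------------------------------------------------------
# performance metrics
# ---------------------------------------------------------------------------

def survival_metrics(
    report: SurvivalReport,
    df: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    t_eval: float = HORIZON_DAYS,
) -> dict[str, float]:
    """Cumulative/dynamic AUC at ``t_eval``, Youden sensitivity/specificity,
    Nagelkerke R² from the partial likelihood, and Harrell's C-index."""
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    times = df[duration_col].to_numpy(float)
    events = df[event_col].to_numpy(bool)
    risk = report.linear_predictor.to_numpy()

    out: dict[str, float] = {}
    # time-dependent AUC with IPCW; the evaluation time must sit strictly
    # inside the observed follow-up range
    t = min(t_eval, times.max() - 1e-6)
    t = max(t, times.min() + 1e-6)
    # ties between events and censoring resolve censoring-last, so the
    # censoring survival function stays positive at the horizon
    t_adj = times + np.where(events, 0.0, 1e-3)
    y = Surv.from_arrays(events, t_adj)
    try:
        auc, _ = cumulative_dynamic_auc(y, y, risk, [t])
        out["auc"] = float(auc[0])
    except ValueError:
        out["auc"] = np.nan

    known_case = (times <= t_eval) & events
    # still at risk at t_eval: survived beyond it, or censored exactly at it
    known_ctrl = (times >= t_eval) & ~known_case
    mask = known_case | known_ctrl
    if known_case.any() and known_ctrl.any():
        thresholds = np.unique(risk[mask])
        best = (-np.inf, np.nan, np.nan)
        for thr in thresholds:
            sens = float((risk[known_case] >= thr).mean())
            spec = float((risk[known_ctrl] < thr).mean())
            youden = sens + spec - 1
            if youden > best[0]:
                best = (youden, sens, spec)
        out["sensitivity"], out["specificity"] = best[1], best[2]
    else:
        out["sensitivity"] = out["specificity"] = np.nan

    out["nagelkerke_r2"] = (
        nagelkerke_r2(report.log_likelihood_null, report.log_likelihood, report.n)
        if np.isfinite(report.log_likelihood_null)
        else np.nan
    )
    if np.ptp(risk) < 1e-12:
        out["harrell_c"] = 0.5
    else:
        out["harrell_c"] = float(concordance_index(times, -risk, events))
    return out
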