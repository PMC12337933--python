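"""Penalized-regression model selection and final logistic prediction models.

Workflow: categorical risk factors are dummy-encoded against a most-frequent
reference level; pairwise association is screened with Cramér's V and
multicollinearity with variance inflation factors; ridge / LASSO / elastic-net
logistic models are compared on a stratified 7:3 split with the penalty
strength chosen by 10-fold cross-validated binomial deviance; variables with
at least one dummy surviving LASSO selection are refit in an unpenalized
logistic model reported with odds ratios, Wald CIs, AUC / sensitivity /
specificity on the held-out 30%, a 10-group Hosmer–Lemeshow calibration test
and Nagelkerke's R².

Penalty strength is parameterized glmnet-style: the penalized objective is
(1/n)·deviance/2 + λ·[(1−α)/2·‖β‖² + α·‖β‖₁] on internally standardized
columns, mapped onto scikit-learn's ``C = 1/(nλ)``.  Coefficients are
reported on the original indicator scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

PENALTIES = ("ridge", "lasso", "elastic_net")
_L1_RATIO = {"ridge": 0.0, "lasso": 1.0, "elastic_net": 0.5}


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Dummy-encoded categorical design (intercept excluded)."""

    X: np.ndarray
    columns: list[str]
    var_of: dict[str, str]
    reference: dict[str, str]

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for c in self.columns:
            v = self.var_of[c]
            if v not in seen:
                seen.append(v)
        return seen

    def columns_of(self, var: str) -> list[str]:
        return [c for c in self.columns if self.var_of[c] == var]


def make_design(df: pd.DataFrame, variables: list[str] | None = None) -> DesignMatrix:
    """Encode each categorical variable as L−1 indicators.

    The reference level is the most frequent one (ties broken by sorted
    value), and non-reference levels enter in descending frequency order.
    """
    variables = list(variables) if variables is not None else list(df.columns)
    cols, names, var_of, reference = [], [], {}, {}
    for var in variables:
        series = df[var].astype(str)
        freq = series.value_counts()
        levels = sorted(freq.index, key=lambda v: (-freq[v], v))
        reference[var] = levels[0]
        for lev in levels[1:]:
            name = f"{var}_{lev}"
            cols.append((series == lev).to_numpy(float))
            names.append(name)
            var_of[name] = var
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return DesignMatrix(X=X, columns=names, var_of=var_of, reference=reference)


# ---------------------------------------------------------------------------
# screening diagnostics
# ---------------------------------------------------------------------------

def cramers_v(a, b) -> float:
    """Cramér's V from the contingency table of two categorical vectors
    (no bias correction)."""
    a, b = pd.Series(a).astype(str), pd.Series(b).astype(str)
    if len(a) != len(b):
        raise ValueError("vectors must have equal length")
    table = pd.crosstab(a, b)
    r, c = table.shape
    if min(r, c) < 2:
        raise ValueError("both variables need at least two observed levels")
    chi2 = stats.chi2_contingency(table.to_numpy(), correction=False)[0]
    n = table.to_numpy().sum()
    return float(np.sqrt(chi2 / (n * (min(r, c) - 1))))


def vif_screen(design: DesignMatrix, threshold: float = 5.0) -> pd.DataFrame:
    """Variance inflation factor per design column: VIF_j = 1/(1−R²_j)."""
    X = design.X
    out = []
    for j, name in enumerate(design.columns):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(y)), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            vif = np.inf  # constant column
        else:
            r2 = 1 - ss_res / ss_tot
            vif = np.inf if r2 > 1 - 1e-10 else 1.0 / (1.0 - r2)
        out.append({"column": name, "vif": vif, "flag": bool(vif > threshold)})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# penalized fits
# ---------------------------------------------------------------------------

@dataclass
class PenalizedFit:
    penalty: str
    lambda_grid: np.ndarray
    chosen_lambda: float
    coefficients: pd.Series  # original indicator scale, index = design columns
    intercept: float
    train_idx: np.ndarray
    test_idx: np.ndarray
    metrics: dict[str, float]
    cv_table: pd.DataFrame  # lambda, mean_deviance, se_deviance, mean_nonzero
    seed: int
    lambda_rule: str = "min"
    design_columns: list[str] = field(default_factory=list)
    # the parsimony solution (largest lambda within one SE of the CV minimum),
    # kept alongside the primary fit for variable selection
    chosen_lambda_1se: float | None = None
    coefficients_1se: pd.Series | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        lp = self.intercept + X @ self.coefficients.to_numpy()
        return 1.0 / (1.0 + np.exp(-lp))


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _solver_for(penalty: str) -> tuple[str, dict]:
    if penalty == "ridge":
        return "lbfgs", {"l1_ratio": 0.0}
    if penalty == "lasso":
        return "saga", {"l1_ratio": 1.0}
    return "saga", {"l1_ratio": 0.5}


def _fit_path(Xs, y, penalty, lambdas):
    """Fit the penalty path on standardized X with warm starts; returns
    (coefs, intercepts) arrays along the λ grid (descending λ)."""
    n = len(y)
    solver, kw = _solver_for(penalty)
    est = LogisticRegression(
        solver=solver, warm_start=True, max_iter=5000, tol=1e-6,
        random_state=0,  # saga shuffles; never depend on the global RNG
        **kw,
    )
    coefs, icepts = [], []
    for lam in lambdas:
        est.C = 1.0 / (n * lam)
        est.fit(Xs, y)
        beta = est.coef_[0].copy()
        # The intercept is unpenalized: polish it by 1-d Newton at fixed
        # coefficients (saga can return it unconverged when C is tiny).
        a = float(est.intercept_[0])
        eta = Xs @ beta
        for _ in range(25):
            p = 1.0 / (1.0 + np.exp(-(eta + a)))
            g = float(np.sum(y - p))
            h = float(np.sum(p * (1 - p)))
            if h <= 0 or abs(g) < 1e-10 * n:
                break
            a += g / h
        coefs.append(beta)
        icepts.append(a)
    return np.array(coefs), np.array(icepts)


def lambda_grid_for(Xs: np.ndarray, y: np.ndarray, penalty: str,
                    n_lambda: int = 30, min_ratio: float = 1e-4) -> np.ndarray:
    """Descending log-spaced λ grid from λ_max (glmnet convention).

    For ridge, which never zeroes coefficients, λ_max uses the α = 0.001
    surrogate so the grid still spans from heavy to light shrinkage.
    """
    n = len(y)
    r = y - y.mean()
    alpha = max(_L1_RATIO[penalty], 1e-3)
    lam_max = np.abs(Xs.T @ r).max() / (n * alpha)
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * min_ratio), n_lambda)


def cv_penalized_fit(
    design: DesignMatrix,
    y: np.ndarray,
    penalty: str,
    seed: int,
    cv_folds: int = 10,
    test_size: float = 0.3,
    n_lambda: int = 30,
    lambda_rule: str = "min",
    lambda_grid: np.ndarray | None = None,
) -> PenalizedFit:
    """Stratified 7:3 split, 10-fold CV λ selection, held-out evaluation."""
    if penalty not in PENALTIES:
        raise ValueError(f"penalty must be one of {PENALTIES}")
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_size, stratify=y, random_state=seed
    )
    Xtr, ytr = design.X[train_idx], y[train_idx]
    mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Xtr_s = (Xtr - mu) / sd

    lambdas = (
        np.sort(np.asarray(lambda_grid, float))[::-1]
        if lambda_grid is not None
        else lambda_grid_for(Xtr_s, ytr, penalty, n_lambda)
    )

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    dev = np.zeros((cv_folds, len(lambdas)))
    nnz = np.zeros((cv_folds, len(lambdas)))
    for f, (tr, va) in enumerate(skf.split(Xtr_s, ytr)):
        coefs, icepts = _fit_path(Xtr_s[tr], ytr[tr], penalty, lambdas)
        lp = Xtr_s[va] @ coefs.T + icepts
        p = 1.0 / (1.0 + np.exp(-lp))
        for j in range(len(lambdas)):
            dev[f, j] = _binomial_deviance(ytr[va], p[:, j])
        nnz[f] = (np.abs(coefs) > 1e-10).sum(axis=1)
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(cv_folds)

    j_min = int(mean_dev.argmin())
    bound = mean_dev[j_min] + se_dev[j_min]
    j_1se = int(np.flatnonzero(mean_dev <= bound)[0])  # λ descending: largest λ
    if lambda_rule == "min":
        j_star = j_min
    elif lambda_rule == "1se":
        j_star = j_1se
    else:
        raise ValueError("lambda_rule must be 'min' or '1se'")
    chosen = float(lambdas[j_star])

    j_deep = max(j_star, j_1se)
    coefs, icepts = _fit_path(Xtr_s, ytr, penalty, lambdas[: j_deep + 1])

    def _original_scale(j):
        beta = coefs[j] / sd
        return beta, icepts[j] - float((mu / sd) @ coefs[j])

    beta, intercept = _original_scale(j_star)
    beta_1se, _ = _original_scale(j_1se)

    p_test = 1.0 / (1.0 + np.exp(-(design.X[test_idx] @ beta + intercept)))
    y_test = y[test_idx]
    metrics = evaluate_binary(y_test, p_test)

    return PenalizedFit(
        penalty=penalty,
        lambda_grid=lambdas,
        chosen_lambda=chosen,
        coefficients=pd.Series(beta, index=design.columns),
        intercept=intercept,
        train_idx=train_idx,
        test_idx=test_idx,
        metrics=metrics,
        cv_table=pd.DataFrame(
            {
                "lambda": lambdas,
                "mean_deviance": mean_dev,
                "se_deviance": se_dev,
                "mean_nonzero": nnz.mean(axis=0),
            }
        ),
        seed=seed,
        lambda_rule=lambda_rule,
        design_columns=list(design.columns),
        chosen_lambda_1se=float(lambdas[j_1se]),
        coefficients_1se=pd.Series(beta_1se, index=design.columns),
    )


def unpenalized_logistic(X: np.ndarray, y: np.ndarray):
    """Maximum-likelihood logistic fit (statsmodels Newton, BFGS fallback)."""
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    try:
        return model.fit(disp=0, maxiter=200)
    except np.linalg.LinAlgError:
        warnings.warn("Newton step met a singular Hessian; falling back to BFGS")
        return model.fit(disp=0, maxiter=500, method="bfgs")


def evaluate_binary(y: np.ndarray, p: np.ndarray, threshold: float = 0.5) -> dict[str, float]:
    """AUC, sensitivity/specificity at ``threshold``, RMSE and R² on the
    probability scale."""
    y = np.asarray(y, float)
    pred = (p >= threshold).astype(float)
    pos, neg = y == 1, y == 0
    sens = float(pred[pos].mean()) if pos.any() else np.nan
    spec = float(1 - pred[neg].mean()) if neg.any() else np.nan
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - float(((y - p) ** 2).sum()) / ss_tot if ss_tot > 0 else np.nan
    return {
        "auc": float(roc_auc_score(y, p)) if pos.any() and neg.any() else np.nan,
        "sensitivity": sens,
        "specificity": spec,
        "rmse": float(np.sqrt(np.mean((y - p) ** 2))),
        "r_squared": r2,
    }


def compare_penalties(fits: list[PenalizedFit]) -> pd.DataFrame:
    """Rank penalties; the winner has lowest RMSE *and* highest R².

    When the two metrics disagree no winner is flagged and the discordance
    is reported; exact ties are broken by higher AUC.
    """
    rows = [
        {
            "penalty": f.penalty,
            "rmse": f.metrics["rmse"],
            "r_squared": f.metrics["r_squared"],
            "auc": f.metrics["auc"],
            "chosen_lambda": f.chosen_lambda,
        }
        for f in fits
    ]
    table = pd.DataFrame(rows)
    by_rmse = table.sort_values(["rmse", "auc"], ascending=[True, False])
    by_r2 = table.sort_values(["r_squared", "auc"], ascending=[False, False])
    winner_rmse = by_rmse["penalty"].iloc[0]
    winner_r2 = by_r2["penalty"].iloc[0]
    table["winner"] = False
    table["discordant"] = winner_rmse != winner_r2
    if winner_rmse == winner_r2:
        table.loc[table["penalty"] == winner_rmse, "winner"] = True
    return table


# ---------------------------------------------------------------------------
# final model and diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    selected_variables: list[str]
    coefficients: pd.DataFrame  # term, coef, se, or, ci_low, ci_high, p
    metrics: dict[str, float]
    hosmer_lemeshow: tuple[float, float]
    nagelkerke: float
    warnings: list[str] = field(default_factory=list)


def variables_surviving_lasso(
    fit: PenalizedFit, design: DesignMatrix, rule: str = "1se"
) -> list[str]:
    """Group-survival rule: a source variable is retained iff at least one of
    its dummies has a nonzero LASSO coefficient.

    Selection defaults to the parsimonious one-SE solution; ``rule='primary'``
    uses the fit's own lambda instead.
    """
    if rule == "1se" and fit.coefficients_1se is not None:
        coef = fit.coefficients_1se
    else:
        coef = fit.coefficients
    nz = coef.abs() > 1e-10
    return [v for v in design.variables if any(nz[c] for c in design.columns_of(v))]


def final_logistic_from_lasso(
    fit: PenalizedFit,
    design: DesignMatrix,
    y: np.ndarray,
    hl_groups: int = 10,
) -> ModelReport:
    """Unpenalized logistic refit on LASSO-retained variables.

    Trained on the fit's 70% split; AUC / sensitivity / specificity and the
    Hosmer–Lemeshow test are evaluated on the 30% holdout; Nagelkerke's R²
    comes from the training likelihood.
    """
    y = np.asarray(y, float)
    retained = variables_surviving_lasso(fit, design)
    notes: list[str] = []
    cols = [c for v in retained for c in design.columns_of(v)]
    if not retained:
        notes.append("no variable survived LASSO selection; intercept-only model")
        warnings.warn(notes[-1])
    col_idx = [design.columns.index(c) for c in cols]
    Xtr = design.X[fit.train_idx][:, col_idx]
    Xte = design.X[fit.test_idx][:, col_idx]
    ytr, yte = y[fit.train_idx], y[fit.test_idx]

    res = unpenalized_logistic(Xtr, ytr)
    params = np.asarray(res.params)
    ses = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    terms = ["intercept"] + cols
    z = stats.norm.ppf(0.975)
    coef_table = pd.DataFrame(
        {
            "term": terms,
            "coef": params,
            "se": ses,
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(params - z * ses),
            "ci_high": np.exp(params + z * ses),
            "p_value": pvals,
        }
    )

    p_te = res.predict(sm.add_constant(Xte, has_constant="add"))
    metrics = evaluate_binary(yte, np.asarray(p_te))
    hl = hosmer_lemeshow(yte, np.asarray(p_te), groups=hl_groups)
    ll_model = float(res.llf)
    ll_null = float(res.llnull)
    nk = nagelkerke_r2(ll_null, ll_model, len(ytr))
    return ModelReport(
        selected_variables=retained,
        coefficients=coef_table,
        metrics=metrics,
        hosmer_lemeshow=hl,
        nagelkerke=nk,
        warnings=notes,
    )


def plain_logistic_report(
    design: DesignMatrix,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    hl_groups: int = 10,
) -> ModelReport:
    """Unpenalized logistic model on all variables (LASSO-free sensitivity
    mode); variables constant on the training split are dropped."""
    y = np.asarray(y, float)
    keep_vars, notes, cols = [], [], []
    for v in design.variables:
        var_cols = []
        for c in design.columns_of(v):
            j = design.columns.index(c)
            if design.X[train_idx][:, j].std() < 1e-12:
                notes.append(f"column {c} constant on training split; dropped")
                continue
            var_cols.append(c)
        if not var_cols:
            notes.append(f"variable {v} constant on training split; dropped")
            continue
        keep_vars.append(v)
        cols.extend(var_cols)
    col_idx = [design.columns.index(c) for c in cols]
    res = unpenalized_logistic(design.X[train_idx][:, col_idx], y[train_idx])
    p_te = res.predict(sm.add_constant(design.X[test_idx][:, col_idx], has_constant="add"))
    params = np.asarray(res.params)
    ses = np.asarray(res.bse)
    z = stats.norm.ppf(0.975)
    coef_table = pd.DataFrame(
        {
            "term": ["intercept"] + cols,
            "coef": params,
            "se": ses,
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(params - z * ses),
            "ci_high": np.exp(params + z * ses),
            "p_value": np.asarray(res.pvalues),
        }
    )
    return ModelReport(
        selected_variables=keep_vars,
        coefficients=coef_table,
        metrics=evaluate_binary(y[test_idx], np.asarray(p_te)),
        hosmer_lemeshow=hosmer_lemeshow(y[test_idx], np.asarray(p_te), groups=hl_groups),
        nagelkerke=nagelkerke_r2(float(res.llnull), float(res.llf), len(train_idx)),
        warnings=notes,
    )


def hosmer_lemeshow(
    y: np.ndarray, p: np.ndarray, groups: int = 10
) -> tuple[float, float]:
    """Hosmer–Lemeshow statistic over deciles of predicted risk.

    Ties in predicted risk stay in one group; groups with a degenerate
    expected count (0 or n_g) are merged into their neighbour.  The p-value
    uses χ² with (groups used − 2) degrees of freedom.
    """
    y = np.asarray(y, float)
    p = np.asarray(p, float)
    if len(y) < groups:
        raise ValueError("need at least as many observations as groups")
    bins = pd.qcut(p, groups, duplicates="drop")
    table = pd.DataFrame({"y": y, "p": p, "g": bins.codes}).groupby("g").agg(
        n=("y", "size"), O=("y", "sum"), E=("p", "sum")
    )
    # merge degenerate groups (E == 0 or E == n) into the neighbour above
    rows = table.to_dict("records")
    merged: list[dict] = []
    for row in rows:
        if merged and (row["E"] <= 1e-12 or row["n"] - row["E"] <= 1e-12):
            for key in ("n", "O", "E"):
                merged[-1][key] += row[key]
        else:
            merged.append(dict(row))
    if len(merged) >= 2 and (merged[0]["E"] <= 1e-12 or merged[0]["n"] - merged[0]["E"] <= 1e-12):
        for key in ("n", "O", "E"):
            merged[1][key] += merged[0][key]
        merged = merged[1:]
    stat = 0.0
    used = 0
    for row in merged:
        denom = row["E"] * (1 - row["E"] / row["n"])
        if denom <= 1e-12:
            continue
        stat += (row["O"] - row["E"]) ** 2 / denom
        used += 1
    df = max(used - 2, 1)
    return float(stat), float(stats.chi2.sf(stat, df))


def nagelkerke_r2(loglik_null: float, loglik_model: float, n: int) -> float:
    """Nagelkerke's rescaled Cox–Snell pseudo-R² in [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if loglik_model < loglik_null - 1e-8:
        raise ValueError("model log-likelihood below null log-likelihood")
    cs = 1.0 - np.exp(2.0 * (loglik_null - loglik_model) / n)
    max_cs = 1.0 - np.exp(2.0 * loglik_null / n)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cs / max_cs, 0.0, 1.0))
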