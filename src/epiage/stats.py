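"""Marker screening and the linear age-model baseline.

Per-CpG ordinary least squares against chronological age, covariate
association tests on age-residualised methylation, forward stepwise
multiple regression (partial-F entry), a multiple-linear-regression age
predictor, prediction-quality metrics (MAE, error bands, skewness) and
variance inflation factors for collinearity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import beta_columns

__all__ = [
    "screen_markers",
    "covariate_association",
    "stepwise_select",
    "StepwiseResult",
    "LinearAgeModel",
    "fit_linear_age_model",
    "predict_linear",
    "EvaluationReport",
    "evaluate_predictions",
    "vif",
]

VIF_CAP = 1e6


def screen_markers(matrix: pd.DataFrame, age=None, fdr: bool = False) -> pd.DataFrame:
    """Per-CpG linear regression of beta on age.

    Returns one row per CpG: slope (beta-fraction per year), Pearson r, R²,
    two-sided p-value for the slope, observed methylation range (max-min)
    and a ``significant`` flag at raw p < 0.05 (optionally
    Benjamini-Hochberg adjusted with ``fdr=True``). Constant CpGs are
    flagged ``degenerate`` and excluded from significance calls.
    """
    if age is None:
        age = matrix["age"]
    age = np.asarray(age, dtype=float)
    rows = []
    for cpg in beta_columns(matrix):
        beta = matrix[cpg].to_numpy(dtype=float)
        ok = ~np.isnan(beta)
        b, a = beta[ok], age[ok]
        rng_ = float(np.max(b) - np.min(b)) if len(b) else np.nan
        if len(b) < 3 or np.ptp(b) == 0 or np.ptp(a) == 0:
            rows.append(
                dict(cpg=cpg, slope=0.0, r=np.nan, r_squared=np.nan, p_value=np.nan,
                     methylation_range=rng_, degenerate=True)
            )
            continue
        res = sps.linregress(a, b)
        rows.append(
            dict(cpg=cpg, slope=res.slope, r=res.rvalue, r_squared=res.rvalue**2,
                 p_value=res.pvalue, methylation_range=rng_, degenerate=False)
        )
    table = pd.DataFrame(rows).set_index("cpg")
    pvals = table["p_value"]
    if fdr:
        from statsmodels.stats.multitest import multipletests

        ok = pvals.notna()
        adj = pd.Series(np.nan, index=table.index)
        if ok.any():
            adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        table["p_adjusted"] = adj
        pvals = adj
    table["significant"] = (pvals < 0.05).fillna(False) & ~table["degenerate"]
    return table


def covariate_association(
    matrix: pd.DataFrame, covariates=("sex", "dataset")
) -> pd.DataFrame:
    """F-test of categorical covariates on age-residualised methylation.

    For every CpG the age trend is removed by OLS, then the residuals are
    regressed on the covariate factor levels; the returned table has one
    p-value per (CpG, covariate) plus a pooled row per covariate (median p
    across CpGs).
    """
    import statsmodels.api as sm

    age = matrix["age"].to_numpy(dtype=float)
    rows = []
    for cov in covariates:
        levels = pd.unique(matrix[cov])
        if len(levels) < 2:
            raise ValueError(f"covariate {cov!r} has a single level; F-test undefined")
        dummies = pd.get_dummies(matrix[cov], drop_first=True).to_numpy(dtype=float)
        for cpg in beta_columns(matrix):
            beta = matrix[cpg].to_numpy(dtype=float)
            ok = ~np.isnan(beta)
            X_age = sm.add_constant(age[ok])
            resid = beta[ok] - X_age @ np.linalg.lstsq(X_age, beta[ok], rcond=None)[0]
            model = sm.OLS(resid, sm.add_constant(dummies[ok])).fit()
            rows.append(dict(cpg=cpg, covariate=cov,
                             p_value=float(model.f_pvalue), f_stat=float(model.fvalue)))
    table = pd.DataFrame(rows)
    pooled = (
        table.groupby("covariate")["p_value"].median().rename("median_p").reset_index()
    )
    return table.merge(pooled, on="covariate")


@dataclass(frozen=True)
class StepwiseResult:
    selected: tuple[str, ...]
    r_squared_path: tuple[float, ...]
    entry_p_values: tuple[float, ...]
    stop_reason: str


def stepwise_select(
    matrix: pd.DataFrame,
    age=None,
    candidates=None,
    alpha_enter: float = 0.05,
    r2_tol: float = 1e-4,
    max_steps: int | None = None,
) -> StepwiseResult:
    """Forward stepwise multiple regression of age on CpG betas.

    At each step the candidate with the smallest partial-F p-value enters;
    selection stops when there is no statistical improvement: the winning
    p-value — Bonferroni-adjusted for the number of candidates examined at
    that step, since the best of k null candidates is selection-biased —
    reaches ``alpha_enter``, or the R² improvement falls below ``r2_tol``.
    Ties break on candidate id for determinism. Samples with missing betas
    in any candidate are dropped. ``entry_p_values`` records the adjusted
    p-values.
    """
    if age is None:
        age = matrix["age"]
    candidates = sorted(candidates if candidates is not None else beta_columns(matrix))
    sub = matrix[candidates].astype(float)
    keep = ~sub.isna().any(axis=1)
    X_all = sub[keep].to_numpy()
    y = np.asarray(age, dtype=float)[np.asarray(keep)]
    n = len(y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return StepwiseResult((), (), (), "constant response")

    selected: list[str] = []
    sel_idx: list[int] = []
    r2_path: list[float] = []
    entry_p: list[float] = []
    rss_current = ss_tot
    Q = np.ones((n, 1)) / np.sqrt(n)  # orthonormal basis of the current design

    while True:
        if max_steps is not None and len(selected) >= max_steps:
            return StepwiseResult(tuple(selected), tuple(r2_path), tuple(entry_p),
                                  "max steps reached")
        remaining = [j for j in range(len(candidates)) if j not in sel_idx]
        if not remaining:
            return StepwiseResult(tuple(selected), tuple(r2_path), tuple(entry_p),
                                  "candidates exhausted")
        k = Q.shape[1]
        dof = n - k - 1
        if dof <= 0:
            return StepwiseResult(tuple(selected), tuple(r2_path), tuple(entry_p),
                                  "degrees of freedom exhausted")
        y_res = y - Q @ (Q.T @ y)
        best = None  # (p, candidate index, rss_new)
        for j in remaining:
            x = X_all[:, j]
            x_res = x - Q @ (Q.T @ x)
            norm = np.linalg.norm(x_res)
            if norm < 1e-10:  # collinear with current design
                continue
            u = x_res / norm
            gain = float((u @ y_res) ** 2)
            rss_new = rss_current - gain
            if rss_new <= 0:
                p = 0.0
            else:
                f = gain / (rss_new / dof)
                p = float(sps.f.sf(f, 1, dof))
            if best is None or p < best[0] - 1e-300 or (p == best[0] and j < best[1]):
                best = (p, j, rss_new)
        if best is None:
            return StepwiseResult(tuple(selected), tuple(r2_path), tuple(entry_p),
                                  "all remaining candidates collinear")
        p, j, rss_new = best
        p_adj = min(1.0, p * len(remaining))
        delta_r2 = (rss_current - rss_new) / ss_tot
        if p_adj >= alpha_enter:
            return StepwiseResult(tuple(selected), tuple(r2_path), tuple(entry_p),
                                  f"best entry p {p_adj:.3g} >= alpha {alpha_enter}")
        if delta_r2 < r2_tol:
            return StepwiseResult(tuple(selected), tuple(r2_path), tuple(entry_p),
                                  f"R2 improvement {delta_r2:.2e} < tol {r2_tol}")
        x = X_all[:, j]
        x_res = x - Q @ (Q.T @ x)
        Q = np.hstack([Q, (x_res / np.linalg.norm(x_res))[:, None]])
        rss_current = rss_new
        sel_idx.append(j)
        selected.append(candidates[j])
        entry_p.append(p_adj)
        r2_path.append(1.0 - rss_current / ss_tot)


@dataclass(frozen=True)
class LinearAgeModel:
    intercept: float
    coefficients: tuple[float, ...]
    cpgs: tuple[str, ...]
    training_mae: float
    training_sd: float
    training_r_squared: float

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": list(self.coefficients),
            "cpgs": list(self.cpgs),
            "training_mae": self.training_mae,
            "training_sd": self.training_sd,
            "training_r_squared": self.training_r_squared,
        }


def fit_linear_age_model(matrix: pd.DataFrame, age=None, cpgs=None) -> LinearAgeModel:
    """OLS of age on the selected CpG betas; samples with missing betas dropped."""
    if age is None:
        age = matrix["age"]
    cpgs = list(cpgs if cpgs is not None else beta_columns(matrix))
    missing = [c for c in cpgs if c not in matrix.columns]
    if missing:
        raise KeyError(f"CpGs not in matrix: {missing}")
    sub = matrix[cpgs].astype(float)
    keep = ~sub.isna().any(axis=1)
    X = np.column_stack([np.ones(int(keep.sum())), sub[keep].to_numpy()])
    y = np.asarray(age, dtype=float)[np.asarray(keep)]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    err = np.abs(fitted - y)
    r = np.corrcoef(fitted, y)[0, 1] if np.ptp(fitted) > 0 else np.nan
    return LinearAgeModel(
        float(coef[0]), tuple(float(c) for c in coef[1:]), tuple(cpgs),
        float(err.mean()), float(err.std(ddof=1)), float(r**2),
    )


def predict_linear(model: LinearAgeModel, betas: pd.DataFrame) -> np.ndarray:
    missing = [c for c in model.cpgs if c not in betas.columns]
    if missing:
        raise KeyError(f"prediction requires missing CpGs: {missing}")
    X = betas[list(model.cpgs)].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [c for c in model.cpgs if betas[c].isna().any()]
        raise ValueError(f"missing beta values for model CpGs: {bad}")
    return model.intercept + X @ np.asarray(model.coefficients)


@dataclass(frozen=True)
class EvaluationReport:
    n: int
    mae: float
    sd_abs_error: float
    r_squared: float
    within_5yr: float
    within_10yr: float
    skewness: float
    abs_error_p75: float
    residuals: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mae": self.mae,
            "sd_abs_error": self.sd_abs_error,
            "r_squared": self.r_squared,
            "within_5yr": self.within_5yr,
            "within_10yr": self.within_10yr,
            "skewness": self.skewness,
            "abs_error_p75": self.abs_error_p75,
        }


def evaluate_predictions(true_ages, predicted_ages) -> EvaluationReport:
    """MAE, SD of absolute error, R² (squared Pearson of predicted vs true),
    ±5/±10-year band fractions, signed-error skewness and the 75th
    percentile of absolute error, plus a residual-vs-age table."""
    t = np.asarray(true_ages, dtype=float)
    p = np.asarray(predicted_ages, dtype=float)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("true and predicted ages must be equal-length, non-empty")
    signed = p - t
    err = np.abs(signed)
    r2 = float(np.corrcoef(p, t)[0, 1] ** 2) if np.ptp(p) > 0 and np.ptp(t) > 0 else np.nan
    skew = float(sps.skew(signed)) if np.ptp(signed) > 0 else 0.0
    residuals = pd.DataFrame({"age": t, "predicted": p, "signed_error": signed})
    return EvaluationReport(
        n=len(t),
        mae=float(err.mean()),
        sd_abs_error=float(err.std(ddof=1)) if len(t) > 1 else 0.0,
        r_squared=r2,
        within_5yr=float(np.mean(err <= 5.0)),
        within_10yr=float(np.mean(err <= 10.0)),
        skewness=skew,
        abs_error_p75=float(np.percentile(err, 75)),
        residuals=residuals,
    )


def vif(matrix: pd.DataFrame, cpgs=None) -> pd.DataFrame:
    """Variance inflation factor per CpG: 1/(1-R²) of each column regressed
    on the others. Values beyond 1e6 are reported capped with a flag."""
    cpgs = list(cpgs if cpgs is not None else beta_columns(matrix))
    X = matrix[cpgs].to_numpy(dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    rows = []
    for j, cpg in enumerate(cpgs):
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        y = X[:, j]
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            value, capped = np.nan, True
        elif ss_res / ss_tot < 1.0 / VIF_CAP:
            value, capped = VIF_CAP, True
        else:
            value, capped = ss_tot / ss_res, False
        rows.append(dict(cpg=cpg, vif=float(value), capped=capped))
    return pd.DataFrame(rows).set_index("cpg")
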