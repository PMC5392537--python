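"""Generalised regression neural network (GRNN) for age prediction.

A GRNN is Nadaraya-Watson kernel regression dressed as a network: one
pattern unit per training case, a Gaussian radial basis with smoothing
width sigma, and a pair of summation units forming

    y_hat(x) = sum_i y_i exp(-||x - x_i||^2 / (2 sigma^2))
             / sum_i     exp(-||x - x_i||^2 / (2 sigma^2))

on standardized inputs. Predictions are convex combinations of training
ages, hence always inside [min(y), max(y)]. The module also implements the
staged optimisation protocol used to build the published-style model:

* stage 1 — search over train/verify/blind proportions with repeated
  random assignment, scoring mean blind MAE;
* stage 2 — re-sample train/verify splits with the blind set held fixed;
* stage 3 — ten replicate models on re-drawn train/verify splits,
  reporting per-subset error mean ± SD;

plus leave-one-input-out sensitivity ratios and a budgeted input-subset
search (greedy forward growth followed by random neighbourhood moves,
scored by verification MAE).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import beta_columns
from .stats import evaluate_predictions

__all__ = [
    "GRNNModel",
    "SplitSpec",
    "make_split",
    "grnn_predict",
    "fit_grnn",
    "tune_sigma",
    "stage1_split_search",
    "stage2_fixed_blind",
    "stage3_replicates",
    "sensitivity_analysis",
    "input_subset_search",
    "SensitivityReport",
]


@dataclass(frozen=True)
class GRNNModel:
    exemplars: np.ndarray  # n_train × p, raw beta scale
    targets: np.ndarray  # ages, years
    sigma: float | np.ndarray  # standardized units; scalar or per-input vector
    input_cpgs: tuple[str, ...]
    mean: np.ndarray  # per-input standardization over exemplars
    sd: np.ndarray

    @property
    def n_pattern_units(self) -> int:
        return len(self.targets)

    def to_json(self, path) -> None:
        payload = {
            "input_cpgs": list(self.input_cpgs),
            "sigma": np.asarray(self.sigma).tolist(),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "exemplars": self.exemplars.tolist(),
            "targets": self.targets.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GRNNModel":
        with open(path) as fh:
            payload = json.load(fh)
        sigma = payload["sigma"]
        sigma = float(sigma) if np.isscalar(sigma) else np.asarray(sigma, dtype=float)
        return cls(
            exemplars=np.asarray(payload["exemplars"], dtype=float),
            targets=np.asarray(payload["targets"], dtype=float),
            sigma=sigma,
            input_cpgs=tuple(payload["input_cpgs"]),
            mean=np.asarray(payload["mean"], dtype=float),
            sd=np.asarray(payload["sd"], dtype=float),
        )


def fit_grnn(train_betas, train_ages, sigma: float, cpgs=None) -> GRNNModel:
    """Store exemplars with per-input standardization; no iterative training."""
    if isinstance(train_betas, pd.DataFrame):
        cpgs = tuple(cpgs if cpgs is not None else beta_columns(train_betas))
        X = train_betas[list(cpgs)].to_numpy(dtype=float)
    else:
        X = np.asarray(train_betas, dtype=float)
        cpgs = tuple(cpgs if cpgs is not None else (f"x{j}" for j in range(X.shape[1])))
    y = np.asarray(train_ages, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("exemplars and targets must align")
    if np.isscalar(sigma) and sigma <= 0:
        raise ValueError("sigma must be positive")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        warnings.warn("constant input(s) among exemplars; standardization uses SD=1")
        sd = np.where(sd == 0, 1.0, sd)
    return GRNNModel(X, y, sigma, cpgs, mean, sd)


def grnn_predict(model: GRNNModel, queries) -> np.ndarray:
    """Kernel-weighted average of training ages; log-sum-exp stabilised.

    In the sigma→0 limit (all kernel weights underflow) the nearest
    exemplar's age is returned.
    """
    if isinstance(queries, pd.DataFrame):
        missing = [c for c in model.input_cpgs if c not in queries.columns]
        if missing:
            raise KeyError(f"query missing model inputs: {missing}")
        Q = queries[list(model.input_cpgs)].to_numpy(dtype=float)
    else:
        Q = np.atleast_2d(np.asarray(queries, dtype=float))
    if Q.shape[1] != model.exemplars.shape[1]:
        raise ValueError(
            f"query has {Q.shape[1]} inputs, model expects {model.exemplars.shape[1]}"
        )
    if np.isnan(Q).any():
        raise ValueError("query contains missing values")
    Xs = (model.exemplars - model.mean) / model.sd
    Qs = (Q - model.mean) / model.sd
    sigma = np.asarray(model.sigma, dtype=float)
    if sigma.ndim > 0:  # per-input widths: scale coordinates instead
        Xs = Xs / sigma
        Qs = Qs / sigma
        sig2 = 1.0
    else:
        sig2 = float(sigma) ** 2
    d2 = (
        np.sum(Qs**2, axis=1)[:, None]
        - 2.0 * Qs @ Xs.T
        + np.sum(Xs**2, axis=1)[None, :]
    )
    np.maximum(d2, 0.0, out=d2)
    logw = -d2 / (2.0 * sig2)
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return (w @ model.targets) / w.sum(axis=1)


def _mae(model: GRNNModel, X, y) -> float:
    return float(np.mean(np.abs(grnn_predict(model, X) - y)))


def tune_sigma(
    train_X,
    train_y,
    verify_X,
    verify_y,
    cpgs=None,
    bracket: tuple[float, float] = (0.01, 10.0),
    tol: float = 1e-3,
) -> tuple[GRNNModel, float]:
    """Golden-section search (in log sigma) minimising verification MAE.

    Returns the fitted model at the best sigma and its verification MAE.
    A boundary warning is raised when the optimum sits at a bracket edge.
    Degenerate all-identical exemplars make sigma irrelevant; the model is
    returned with a warning.
    """
    base = fit_grnn(train_X, train_y, 1.0, cpgs=cpgs)
    if np.allclose(base.exemplars, base.exemplars[0]):
        warnings.warn("all exemplars identical: prediction is constant, sigma irrelevant")
        return base, _mae(base, _verify_frame(verify_X, base), verify_y)

    lo, hi = np.log(bracket[0]), np.log(bracket[1])
    phi = (np.sqrt(5.0) - 1.0) / 2.0

    def score(logsig):
        return _mae(replace(base, sigma=float(np.exp(logsig))),
                    _verify_frame(verify_X, base), verify_y)

    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc, fd = score(c), score(d)
    while b - a > tol:
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = score(c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = score(d)
    best_log = c if fc <= fd else d
    best = float(np.exp(best_log))
    if best_log - lo < 2 * tol or hi - best_log < 2 * tol:
        warnings.warn(f"tuned sigma {best:.4g} sits at the search boundary {bracket}")
    model = replace(base, sigma=best)
    return model, _mae(model, _verify_frame(verify_X, base), verify_y)


def _verify_frame(X, model: GRNNModel):
    if isinstance(X, pd.DataFrame):
        return X
    return np.asarray(X, dtype=float)


@dataclass(frozen=True)
class SplitSpec:
    """Train/verify/blind proportions with the published rounding rule:
    n_train = round(p_train*n), n_verify = round(p_verify*n), blind takes
    the remainder (60:20:20 of 1156 gives 694/231/231)."""

    p_train: float
    p_verify: float
    p_blind: float
    seed: int = 0
    fixed_blind_ids: tuple | None = None

    def __post_init__(self):
        total = self.p_train + self.p_verify + self.p_blind
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {total}")
        if not 0.5 <= self.p_train <= 0.7:
            raise ValueError(
                f"training proportion must lie in [0.5, 0.7], got {self.p_train}"
            )

    def sizes(self, n: int) -> tuple[int, int, int]:
        n_train = round(self.p_train * n)
        n_verify = round(self.p_verify * n)
        return n_train, n_verify, n - n_train - n_verify


def make_split(index, spec: SplitSpec, rng=None):
    """Random partition of sample ids into (train, verify, blind) id arrays.

    With ``fixed_blind_ids`` only train/verify are re-randomised.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    index = np.asarray(index)
    n = len(index)
    n_train, n_verify, n_blind = spec.sizes(n)
    if spec.fixed_blind_ids is not None:
        blind = np.asarray(spec.fixed_blind_ids)
        rest = index[~np.isin(index, blind)]
        if len(rest) != n_train + n_verify:
            raise ValueError("fixed blind ids inconsistent with proportions")
        perm = rng.permutation(rest)
        return perm[:n_train], perm[n_train:], blind
    perm = rng.permutation(index)
    return perm[:n_train], perm[n_train : n_train + n_verify], perm[n_train + n_verify :]


def _split_frames(matrix, cpgs, ids):
    sub = matrix.loc[list(ids)]
    return sub[list(cpgs)], sub["age"].to_numpy(dtype=float)


@dataclass
class StageResult:
    spec: SplitSpec
    model: GRNNModel
    blind_mae: float
    detail: pd.DataFrame


def stage1_split_search(
    matrix: pd.DataFrame,
    cpgs=None,
    proportions=(0.5, 0.55, 0.6, 0.65, 0.7),
    repeats: int = 3,
    seed: int = 0,
) -> StageResult:
    """Stage 1: choose train/verify/blind proportions by mean blind MAE.

    The remainder after training is split equally between verification and
    blind testing. Each proportion is tried ``repeats`` times with fresh
    random assignment; sigma is tuned on the verification set each time.
    """
    cpgs = tuple(cpgs if cpgs is not None else beta_columns(matrix))
    rng = np.random.default_rng(seed)
    rows = []
    best = None
    for p_train in proportions:
        p_rest = (1.0 - p_train) / 2.0
        for rep in range(repeats):
            spec = SplitSpec(p_train, p_rest, p_rest,
                             seed=int(rng.integers(0, 2**31 - 1)))
            tr, ve, bl = make_split(matrix.index, spec)
            model, _ = tune_sigma(*_split_frames(matrix, cpgs, tr),
                                  *_split_frames(matrix, cpgs, ve), cpgs=cpgs)
            bX, by = _split_frames(matrix, cpgs, bl)
            mae = _mae(model, bX, by)
            rows.append(dict(p_train=p_train, repeat=rep, blind_mae=mae,
                             seed=spec.seed))
            if best is None or mae < best[0]:
                best = (mae, spec, model)
    detail = pd.DataFrame(rows)
    mean_by_p = detail.groupby("p_train")["blind_mae"].mean()
    best_p = float(mean_by_p.idxmin())
    # winning proportion by mean blind MAE; best model among its repeats
    cand = detail[detail["p_train"] == best_p].sort_values("blind_mae").iloc[0]
    spec = SplitSpec(best_p, (1 - best_p) / 2, (1 - best_p) / 2, seed=int(cand["seed"]))
    tr, ve, bl = make_split(matrix.index, spec)
    model, _ = tune_sigma(*_split_frames(matrix, cpgs, tr),
                          *_split_frames(matrix, cpgs, ve), cpgs=cpgs)
    return StageResult(spec, model, float(cand["blind_mae"]), detail)


def stage2_fixed_blind(
    matrix: pd.DataFrame,
    spec: SplitSpec,
    cpgs=None,
    resamples: int = 5,
    seed: int = 1,
) -> StageResult:
    """Stage 2: hold the blind set fixed, re-randomise train/verify."""
    cpgs = tuple(cpgs if cpgs is not None else beta_columns(matrix))
    _, _, blind_ids = make_split(matrix.index, spec)
    fixed = replace(spec, fixed_blind_ids=tuple(blind_ids))
    rng = np.random.default_rng(seed)
    rows, best = [], None
    for rep in range(resamples):
        tr, ve, bl = make_split(matrix.index, fixed, rng=rng)
        model, _ = tune_sigma(*_split_frames(matrix, cpgs, tr),
                              *_split_frames(matrix, cpgs, ve), cpgs=cpgs)
        bX, by = _split_frames(matrix, cpgs, bl)
        mae = _mae(model, bX, by)
        rows.append(dict(resample=rep, blind_mae=mae))
        if best is None or mae < best[0]:
            best = (mae, model, (tr, ve, bl))
    return StageResult(fixed, best[1], best[0], pd.DataFrame(rows))


def stage3_replicates(
    matrix: pd.DataFrame,
    spec: SplitSpec,
    cpgs=None,
    k: int = 10,
    seed: int = 2,
):
    """Stage 3: k replicate models with the blind set fixed; per-subset
    error mean ± SD quantifies replicate variability.

    Returns (list of (model, split) replicates, variability table).
    """
    cpgs = tuple(cpgs if cpgs is not None else beta_columns(matrix))
    if k == 1:
        warnings.warn("k=1 replicate: SD reported as 0")
    _, _, blind_ids = make_split(matrix.index, spec)
    fixed = replace(spec, fixed_blind_ids=tuple(blind_ids))
    rng = np.random.default_rng(seed)
    replicates, rows = [], []
    for rep in range(k):
        tr, ve, bl = make_split(matrix.index, fixed, rng=rng)
        model, _ = tune_sigma(*_split_frames(matrix, cpgs, tr),
                              *_split_frames(matrix, cpgs, ve), cpgs=cpgs)
        replicates.append((model, (tr, ve, bl)))
        for subset, ids in (("train", tr), ("verify", ve), ("blind", bl)):
            X, y = _split_frames(matrix, cpgs, ids)
            err = np.abs(grnn_predict(model, X) - y)
            rows.append(dict(replicate=rep, subset=subset,
                             mae=float(err.mean()), sd=float(err.std(ddof=1))))
    detail = pd.DataFrame(rows)
    summary = (
        detail.groupby("subset")["mae"]
        .agg(mean_mae="mean", sd_mae=lambda s: 0.0 if len(s) == 1 else s.std(ddof=1))
        .reindex(["train", "verify", "blind"])
    )
    return replicates, summary, detail


@dataclass(frozen=True)
class SensitivityReport:
    table: pd.DataFrame  # per input: mean/median ratio, quartiles, rank
    per_replicate: pd.DataFrame

    def ranked_inputs(self) -> list[str]:
        return list(self.table.sort_values("rank").index)


def _drop_input(model: GRNNModel, j: int) -> GRNNModel:
    """Remove one input and re-standardise over the remaining exemplars."""
    X = np.delete(model.exemplars, j, axis=1)
    cpgs = tuple(c for i, c in enumerate(model.input_cpgs) if i != j)
    sigma = model.sigma
    if not np.isscalar(sigma):
        sigma = np.delete(np.asarray(sigma), j)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return GRNNModel(X, model.targets, sigma, cpgs, mean, sd)


def sensitivity_analysis(replicates, blind_X: pd.DataFrame, blind_y) -> SensitivityReport:
    """Leave-one-input-out error ratios across replicate models.

    ratio = blind MAE with the input removed / blind MAE with all inputs;
    values above 1 mean the input contributes to accuracy. Inputs are
    ranked by mean ratio across replicates (1 = most depended upon).
    """
    blind_y = np.asarray(blind_y, dtype=float)
    if not isinstance(replicates, (list, tuple)):
        replicates = [replicates]
    models = [r[0] if isinstance(r, tuple) else r for r in replicates]
    cpgs = models[0].input_cpgs
    rows = []
    for rep, model in enumerate(models):
        full_mae = _mae(model, blind_X, blind_y)
        for j, cpg in enumerate(cpgs):
            reduced = _drop_input(model, j)
            sub = blind_X[list(reduced.input_cpgs)]
            ratio = _mae(reduced, sub, blind_y) / full_mae if full_mae > 0 else np.inf
            rows.append(dict(replicate=rep, cpg=cpg, error_ratio=float(ratio)))
    per_rep = pd.DataFrame(rows)
    table = (
        per_rep.groupby("cpg")["error_ratio"]
        .agg(
            mean_ratio="mean",
            median_ratio="median",
            q25=lambda s: float(np.percentile(s, 25)),
            q75=lambda s: float(np.percentile(s, 75)),
        )
        .reindex(list(cpgs))
    )
    table["rank"] = table["mean_ratio"].rank(ascending=False, method="min").astype(int)
    return SensitivityReport(table, per_rep)


def input_subset_search(
    matrix: pd.DataFrame,
    candidates=None,
    budget: int = 5000,
    spec: SplitSpec | None = None,
    seed: int = 0,
    sigma_grid=(0.1, 0.2, 0.4, 0.8, 1.6, 3.2),
) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Budgeted search for the input subset minimising verification MAE.

    Greedy forward growth (each step tries every remaining candidate at a
    small sigma grid) followed by random single-swap/add/drop moves until
    the evaluation budget is spent. One model evaluation = one (subset,
    sigma) verification scoring. Stands in for exhaustive architecture
    enumeration at desk scale.
    """
    candidates = list(candidates if candidates is not None else beta_columns(matrix))
    if budget <= 0:
        warnings.warn("budget 0: returning all candidate inputs")
        return tuple(candidates), pd.DataFrame()
    if len(candidates) == 1:
        return tuple(candidates), pd.DataFrame()
    spec = spec or SplitSpec(0.6, 0.2, 0.2, seed=seed)
    tr, ve, _ = make_split(matrix.index, spec)
    rng = np.random.default_rng(seed)
    evals = 0
    history = []

    train_all = matrix.loc[list(tr)]
    verify_all = matrix.loc[list(ve)]
    train_y = train_all["age"].to_numpy(dtype=float)
    verify_y = verify_all["age"].to_numpy(dtype=float)

    def score(subset) -> float:
        # one squared-distance matrix per subset, swept over the sigma grid
        # (same kernel average as grnn_predict, amortised for the search)
        nonlocal evals
        X = train_all[list(subset)].to_numpy(dtype=float)
        Q = verify_all[list(subset)].to_numpy(dtype=float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xs, Qs = (X - mean) / sd, (Q - mean) / sd
        d2 = (
            np.sum(Qs**2, axis=1)[:, None]
            - 2.0 * Qs @ Xs.T
            + np.sum(Xs**2, axis=1)[None, :]
        )
        np.maximum(d2, 0.0, out=d2)
        best = np.inf
        for s in sigma_grid:
            if evals >= budget:
                break
            evals += 1
            logw = -d2 / (2.0 * float(s) ** 2)
            logw -= logw.max(axis=1, keepdims=True)
            w = np.exp(logw)
            pred = (w @ train_y) / w.sum(axis=1)
            best = min(best, float(np.mean(np.abs(pred - verify_y))))
        return best

    current: list[str] = []
    current_score = np.inf
    improved = True
    while improved and evals < budget:
        improved = False
        best_add, best_score = None, current_score
        for cand in candidates:
            if cand in current or evals >= budget:
                continue
            s = score(current + [cand])
            if s < best_score - 1e-9:
                best_add, best_score = cand, s
        if best_add is not None:
            current.append(best_add)
            current_score = best_score
            improved = True
            history.append(dict(action="add", cpg=best_add, score=best_score,
                                evaluations=evals))
    # random refinement within the remaining budget
    while evals < budget and current:
        move = rng.choice(["swap", "drop", "add"])
        trial = list(current)
        outside = [c for c in candidates if c not in current]
        if move == "add" and outside:
            trial.append(outside[rng.integers(len(outside))])
        elif move == "drop" and len(trial) > 1:
            trial.pop(rng.integers(len(trial)))
        elif move == "swap" and outside:
            trial[rng.integers(len(trial))] = outside[rng.integers(len(outside))]
        else:
            continue
        s = score(sorted(trial))
        if s < current_score - 1e-9:
            current, current_score = sorted(trial), s
            history.append(dict(action=move, cpg=None, score=s, evaluations=evals))
    return tuple(sorted(current)), pd.DataFrame(history)
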